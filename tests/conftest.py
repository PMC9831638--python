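"""Shared fixtures: the scaled model, tasks, threshold tables, and traces.

Everything heavy is session-scoped and lazily built, so unit-test-only
runs stay fast while the closed-loop and statistics tests share one
dictionary, one table per task, and cached simulation traces.
"""

from __future__ import annotations

import numpy as np
import pytest

from adaptcode.pipeline import build_model
from adaptcode.profiles import SCALED
from adaptcode.simulate import prepare_run, run_closed_loop
from adaptcode.sparse import Dictionary, SparseConfig
from adaptcode.stimuli import PcaMap
from adaptcode.tasks import (
    build_detection_task,
    build_localization_task,
    build_orientation_task,
)
from adaptcode.thresholds import (
    OptimConfig,
    binary_belief_grid,
    build_threshold_table,
    position_belief_grid,
)

MODEL_SEED = 0
TASK_SEED = 1
TABLE_SEED = 2


@pytest.fixture(scope="session")
def model():
    """Scaled dictionary (W=16, d=N=128) learned on a dead-leaves corpus."""
    dct, images = build_model(SCALED, seed=MODEL_SEED, epochs=12, corpus_size=3000)
    return dct, images


@pytest.fixture(scope="session")
def dictionary(model):
    return model[0]


@pytest.fixture(scope="session")
def corpus_images(model):
    return model[1]


@pytest.fixture(scope="session")
def identity_dictionary():
    """Complete identity dictionary on 16x16 pixels (decode == pixels).

    Useful when a test needs exact image-space behavior without the
    learned-basis approximation.
    """
    W = 16
    pmap = PcaMap(mean=np.zeros(W * W), components=np.eye(W * W))
    return Dictionary(features=np.eye(W * W), pca=pmap, meta={})


@pytest.fixture(scope="session")
def optim_config():
    return OptimConfig(psi=4.0, n_mc=SCALED.n_mc_binary)


@pytest.fixture(scope="session")
def detection_task(dictionary):
    return build_detection_task(dictionary, SCALED.W, seed=TASK_SEED, n_train=500)


@pytest.fixture(scope="session")
def orientation_task(dictionary, corpus_images):
    return build_orientation_task(dictionary, corpus_images, seed=TASK_SEED, n_train=500)


@pytest.fixture(scope="session")
def localization_task(dictionary):
    return build_localization_task(
        dictionary, SCALED.W, seed=TASK_SEED, walk_sigma=2.4
    )


@pytest.fixture(scope="session")
def detection_table(detection_task, optim_config):
    return build_threshold_table(
        detection_task, binary_belief_grid(SCALED.k_bins), optim_config, seed=TABLE_SEED
    )


@pytest.fixture(scope="session")
def orientation_table(orientation_task, optim_config):
    return build_threshold_table(
        orientation_task, binary_belief_grid(SCALED.k_bins), optim_config, seed=TABLE_SEED
    )


@pytest.fixture(scope="session")
def localization_table(localization_task, optim_config):
    return build_threshold_table(
        localization_task,
        position_belief_grid(SCALED.grid_side, SCALED.W),
        optim_config,
        seed=TABLE_SEED,
    )


@pytest.fixture(scope="session")
def trace_factory(detection_task, orientation_task, localization_task,
                  detection_table, orientation_table, localization_table):
    """Cached closed-loop runs keyed by (task, mode, seed, T).

    A prepared run (stimuli + batch-encoded codes) is shared between the
    full and adaptive modes of the same seed.
    """
    tasks = {
        "detection": (detection_task, detection_table),
        "orientation": (orientation_task, orientation_table),
        "localization": (localization_task, localization_table),
    }
    prepared_cache: dict = {}
    trace_cache: dict = {}

    def get(name: str, mode: str, seed: int = 3, T: int = 4000):
        key = (name, mode, seed, T)
        if key not in trace_cache:
            task, table = tasks[name]
            pkey = (name, seed, T)
            if pkey not in prepared_cache:
                prepared_cache[pkey] = prepare_run(task, T, seed, _env_for(task))
            trace_cache[key] = run_closed_loop(
                task, T, seed=seed, mode=mode, table=table,
                prepared=prepared_cache[pkey],
            )
        return trace_cache[key]

    def _env_for(task):
        from adaptcode.simulate import EnvironmentSpec
        from adaptcode.tasks import LocalizationTask

        if isinstance(task, LocalizationTask):
            return EnvironmentSpec(mode="walk", walk_sigma=task.walk_sigma, W=task.W)
        return EnvironmentSpec(mode="telegraph", hazard=task.hazard, W=task.W)

    return get


@pytest.fixture(scope="session")
def toy_orthonormal_dictionary():
    """Small orthonormal dictionary (N = d = 16, 4x4 pixels) with identity PCA."""
    rng = np.random.default_rng(7)
    q, _ = np.linalg.qr(rng.standard_normal((16, 16)))
    pmap = PcaMap(mean=np.zeros(16), components=np.eye(16))
    return Dictionary(features=q, pca=pmap, meta={})


@pytest.fixture()
def sparse_cfg():
    return SparseConfig(lam=0.05, sigma2=0.5)
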