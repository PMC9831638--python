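"""Closed-loop simulation of adaptive coding in a dynamic environment.

Each time step follows the encode -> shrink -> measure -> update ->
select-thresholds cycle: the stimulus drawn from the current latent state
is sparse-coded, passed through the belief-selected shrinkage thresholds,
measured by the task observer, used to update the posterior, and the
predictive belief picks next step's thresholds from a precomputed table.
In ``full`` mode the thresholds are pinned at zero, reproducing standard
sparse coding.

The environment evolves independently of the observer, so stimuli and
sparse codes for a whole run are generated and batch-encoded up front;
only the cheap belief/nonlinearity loop is sequential.  Runs are
deterministic given their seed, and full and adaptive runs with the same
seed see identical stimuli and measurement-noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import observers as obs
from .shrinkage import DEFAULT_ALPHA, shrink
from .tasks import DetectionTask, LocalizationTask, OrientationTask
from .thresholds import ThresholdTable, select_thresholds

__all__ = [
    "EnvironmentSpec",
    "Trace",
    "gen_state_sequence",
    "gen_walk",
    "prepare_run",
    "run_closed_loop",
    "feedback_cost",
]


@dataclass(frozen=True)
class EnvironmentSpec:
    """Latent-state dynamics of a task environment.

    ``mode`` is ``"telegraph"`` (per-step flip with probability
    ``hazard``), ``"scripted"`` (deterministic cycles of
    ``cycle=(present, absent, present)`` samples), or ``"walk"`` (2-D
    Gaussian random walk with step std ``walk_sigma`` bounded to
    ``[1, W]``).
    """

    mode: str = "telegraph"
    hazard: float = 0.01
    cycle: tuple[int, int, int] = (50, 100, 50)
    walk_sigma: float = 1.2
    W: int = 32

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError("hazard outside [0, 1]")
        if any(c <= 0 for c in self.cycle):
            raise ValueError("cycle lengths must be positive")


def gen_state_sequence(spec: EnvironmentSpec, T: int, seed: int = 0) -> np.ndarray:
    """Binary latent-state series (1 = positive state: present / horizontal).

    Telegraph mode starts in the positive state and flips each step with
    probability ``hazard``; scripted mode tiles the
    present/absent/present cycle.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if spec.mode == "scripted":
        a, b, c = spec.cycle
        unit = np.concatenate([np.ones(a, int), np.zeros(b, int), np.ones(c, int)])
        reps = int(np.ceil(T / len(unit)))
        return np.tile(unit, reps)[:T]
    rng = np.random.default_rng(seed)
    flips = rng.random(T - 1) < spec.hazard if T > 1 else np.empty(0, bool)
    states = np.empty(T, dtype=int)
    states[0] = 1
    if T > 1:
        states[1:] = np.where(np.cumsum(flips) % 2 == 1, 0, 1)
    return states


def gen_walk(
    spec: EnvironmentSpec, T: int, seed: int = 0, start: tuple[float, float] | None = None
) -> np.ndarray:
    """Integer 2-D random-walk positions, rounded and bounded to [1, W].

    The walk evolves in continuous coordinates (clipped at the borders)
    and the reported series is its rounded projection, so interior
    per-step increments keep std close to ``walk_sigma``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.empty((T, 2))
    cur = np.asarray(start if start is not None else [(spec.W + 1) / 2.0] * 2, float)
    for t in range(T):
        pos[t] = cur
        cur = np.clip(cur + rng.normal(0.0, spec.walk_sigma, size=2), 1.0, spec.W)
    return np.clip(np.round(pos), 1, spec.W).astype(int)


@dataclass
class Trace:
    """Complete record of one closed-loop run."""

    task: str
    mode: str
    states: np.ndarray  # (T,) binary or (T, 2) positions
    S: np.ndarray  # sparse codes (T, N)
    Z: np.ndarray  # shrunk responses (T, N)
    xi: np.ndarray  # thresholds in effect at each step (T, N)
    belief: np.ndarray  # (T,) posterior p, or (T, 2) posterior means
    belief_pred: np.ndarray  # predictive belief used to pick xi_{t+1}
    m: np.ndarray  # measurements
    estimate: np.ndarray  # MAP / point estimates
    images: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return len(self.S)

    def activity(self) -> np.ndarray:
        """Summed response magnitude per time step."""
        return np.abs(self.Z).sum(axis=1)

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            for name in ("states", "S", "Z", "xi", "belief", "belief_pred", "m", "estimate"):
                f.create_dataset(name, data=getattr(self, name))
            if self.images is not None:
                f.create_dataset("images", data=self.images)
            f.attrs["task"] = self.task
            f.attrs["mode"] = self.mode
            for k, v in self.meta.items():
                f.attrs[k] = v


def feedback_cost(xi_history: np.ndarray) -> tuple[np.ndarray, float]:
    """Top-down signaling cost of a threshold trajectory.

    The per-step cost is the standard deviation of the threshold vector,
    charged only when the vector differs from the previous step (the
    initial vector is always charged).  Returns the per-step series and
    its total.
    """
    xi_history = np.atleast_2d(np.asarray(xi_history, dtype=float))
    T = len(xi_history)
    cost = np.zeros(T)
    cost[0] = xi_history[0].std()
    for t in range(1, T):
        if not np.array_equal(xi_history[t], xi_history[t - 1]):
            cost[t] = xi_history[t].std()
    return cost, float(cost.sum())


def prepare_run(task, T: int, seed: int, env: EnvironmentSpec):
    """Draw the environment and stimuli, and batch-encode the whole run.

    Returns ``(states, images, S, noise_seed)``.  The environment evolves
    independently of the observer, so a prepared run can be shared between
    a full-mode and an adaptive-mode simulation of the same seed (both
    then see identical stimuli and measurement noise).
    """
    root = np.random.default_rng(seed)
    env_seed, stim_seed, noise_seed = (int(root.integers(2**31)) for _ in range(3))
    stim_rng = np.random.default_rng(stim_seed)
    if isinstance(task, LocalizationTask):
        states = gen_walk(env, T, env_seed)
        images = task.sample_images(states, stim_rng, movie=True)
        S = task.encode_images(images)
    elif isinstance(task, DetectionTask):
        states = gen_state_sequence(env, T, env_seed)
        images = task.sample_images(states, stim_rng)
        S = task.encode_images(images)
    elif isinstance(task, OrientationTask):
        states = gen_state_sequence(env, T, env_seed)
        S = np.empty((T, task.n_neurons))
        images = np.empty((T, task.W, task.W))
        for label, val in (("H", 1), ("V", 0)):
            sel = np.flatnonzero(states == val)
            codes, imgs = task._draw(label, "eval", len(sel), stim_rng)
            S[sel] = codes
            images[sel] = imgs
    else:
        raise TypeError(f"unknown task type {type(task)!r}")
    return states, images, S, noise_seed


def run_closed_loop(
    task,
    T: int,
    seed: int = 0,
    mode: str = "adaptive",
    table: ThresholdTable | None = None,
    env: EnvironmentSpec | None = None,
    alpha: float = DEFAULT_ALPHA,
    store_images: bool = True,
    prepared: tuple | None = None,
) -> Trace:
    """Simulate ``T`` steps of perceptual inference with the adaptive code.

    ``mode="adaptive"`` requires a threshold table for the task;
    ``mode="full"`` keeps all thresholds at zero (standard sparse coding).
    """
    if mode not in ("adaptive", "full"):
        raise ValueError("mode must be 'adaptive' or 'full'")
    if mode == "adaptive" and table is None:
        raise ValueError("adaptive mode needs a threshold table")
    binary = not isinstance(task, LocalizationTask)
    if env is None:
        if isinstance(task, LocalizationTask):
            env = EnvironmentSpec(mode="walk", walk_sigma=task.walk_sigma, W=task.W)
        else:
            env = EnvironmentSpec(mode="telegraph", hazard=task.hazard, W=task.W)
    if prepared is None:
        prepared = prepare_run(task, T, seed, env)
    states, images, S, noise_seed = prepared
    noise_rng = np.random.default_rng(noise_seed)
    N = task.n_neurons
    Z = np.empty((T, N))
    XI = np.empty((T, N))
    if binary:
        belief = np.empty(T)
        belief_pred = np.empty(T)
        m_arr = np.empty(T)
        est = np.empty(T, dtype=int)
        prior = 0.5
    else:
        belief = np.empty((T, 2))
        belief_pred = np.empty((T, 2))
        m_arr = np.empty((T, 2))
        est = np.empty((T, 2))
        gb = obs.GaussBelief(
            mean=np.full(2, (task.W + 1) / 2.0), var=np.full(2, float(task.W) ** 2)
        )

    def lookup(b):
        if mode == "full":
            return np.zeros(N)
        return select_thresholds(table, b)

    xi = lookup(prior if binary else gb.mean)
    for t in range(T):
        XI[t] = xi
        Z[t] = shrink(S[t], xi, alpha)
        m = task.measure(Z[t], noise_rng)
        if binary:
            post, pred = task.update(prior, m)
            belief[t], belief_pred[t], m_arr[t] = post, pred, m
            est[t] = int(post >= 0.5)
            prior = pred
            xi = lookup(pred)
        else:
            gb = task.update(gb, m)
            belief[t] = gb.mean
            belief_pred[t] = gb.mean
            m_arr[t] = m
            est[t] = gb.mean
            xi = lookup(gb.mean)
    return Trace(
        task=task.name,
        mode=mode,
        states=states,
        S=S,
        Z=Z,
        xi=XI,
        belief=belief,
        belief_pred=belief_pred,
        m=m_arr,
        estimate=est,
        images=images if store_images else None,
        meta={"seed": seed, "T": T, "alpha": alpha},
    )
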