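"""Wiring of the three perceptual inference tasks.

Each task object bundles everything the optimizer and the closed-loop
simulator need: the dictionary, task stimuli, the measurement function and
its Gaussian class models, the Bayesian belief update, and a
``evaluator_for_belief`` factory that draws the belief-conditioned
Monte-Carlo training set used to optimize thresholds.

* :class:`DetectionTask` — telegraph present/absent state; stimuli are
  synthetic backgrounds (dead-leaves by default) with an object template
  mixed in at ``gamma = 0.2`` when present; measurement projects the
  decoded image on the template.
* :class:`LocalizationTask` — a 7x7 white cross random-walking over movie
  frames; measurement is the decoded image's cross-correlation peak.
* :class:`OrientationTask` — patches from unsupervised horizontal/vertical
  categories; measurement projects response magnitudes on a Fisher
  discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import observers as obs
from .sparse import Dictionary, SparseConfig, encode
from .stimuli import (
    Template,
    generate_movie,
    generate_patches,
    embed_object,
    make_templates,
    standardize,
    superimpose_target,
)
from .thresholds import BinaryCostEvaluator, LocalizationCostEvaluator

__all__ = [
    "DetectionTask",
    "LocalizationTask",
    "OrientationTask",
    "build_detection_task",
    "build_localization_task",
    "build_orientation_task",
]


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


# ---------------------------------------------------------------------------
# object detection
# ---------------------------------------------------------------------------

@dataclass
class DetectionTask:
    name: str
    dictionary: Dictionary
    obj: Template
    sparse_cfg: SparseConfig
    w: np.ndarray
    b: float
    model_pos: obs.ClassModel
    model_neg: obs.ClassModel
    gamma: float = 0.2
    hazard: float = 0.01
    sigma_m2: float = obs.SIGMA_M2_DETECTION
    spectral_exponent: float = 2.0
    patch_kind: str = "dead_leaves"
    approx_predictive: bool = False
    W: int = 32

    @property
    def n_neurons(self) -> int:
        return self.dictionary.N

    def encode_images(self, images: np.ndarray) -> np.ndarray:
        return np.atleast_2d(
            encode(self.dictionary.pca.reduce(images), self.dictionary, self.sparse_cfg)
        )

    def sample_images(self, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        backgrounds = generate_patches(
            len(states), self.W, self.spectral_exponent, _seed(rng), kind=self.patch_kind
        )
        images = backgrounds.copy()
        # every stimulus delivered to the population is standardized, so
        # object presence is carried by pattern correlation with the
        # template, not by a trivial image-variance cue
        for t in np.flatnonzero(states):
            images[t] = standardize(embed_object(backgrounds[t], self.obj, self.gamma))
        return images

    def evaluator_for_belief(self, p, n_mc, psi, alpha, rng) -> BinaryCostEvaluator:
        p = float(p)
        n_pos = int(round(p * n_mc))
        states = np.zeros(n_mc, dtype=int)
        states[:n_pos] = 1
        images = self.sample_images(states, rng)
        S = self.encode_images(images)
        noise = rng.normal(0.0, np.sqrt(self.sigma_m2), size=n_mc)
        return BinaryCostEvaluator(
            S, self.w, self.b, self.model_pos, self.model_neg, p, psi, alpha, noise,
            kl_weight=self.n_neurons,
        )

    def measure(self, z: np.ndarray, rng: np.random.Generator) -> float:
        return float(z @ self.w + self.b + rng.normal(0.0, np.sqrt(self.sigma_m2)))

    def update(self, prior_p: float, m: float) -> tuple[float, float]:
        return obs.update_binary_belief(
            prior_p,
            m,
            self.model_pos,
            self.model_neg,
            self.hazard,
            self.approx_predictive,
        )


def build_detection_task(
    dictionary: Dictionary,
    W: int,
    seed: int = 0,
    n_train: int = 1000,
    gamma: float = 0.2,
    hazard: float = 0.01,
    lam: float = 0.05,
    sigma2: float = 0.5,
    spectral_exponent: float = 2.0,
    patch_kind: str = "dead_leaves",
    approx_predictive: bool = False,
    object_contrast: float = 3.0,
) -> DetectionTask:
    """Assemble the detection task: templates, readout, and class models.

    Class models are fitted on ``n_train`` full-code measurements per
    state, with measurement noise included.  ``object_contrast`` scales
    the standardized object silhouette; the default puts the object on
    the same supra-threshold intensity scale as the white cross target.
    """
    rng = np.random.default_rng(seed)
    objt, _ = make_templates(W, _seed(rng))
    objt = Template(pixels=objt.pixels * object_contrast, kind="object")
    w, b = obs.detection_readout(dictionary, objt)
    cfg = SparseConfig(lam=lam, sigma2=sigma2)
    task = DetectionTask(
        name="detection",
        dictionary=dictionary,
        obj=objt,
        sparse_cfg=cfg,
        w=w,
        b=b,
        model_pos=obs.ClassModel(0.0, 1.0),
        model_neg=obs.ClassModel(0.0, 1.0),
        gamma=gamma,
        hazard=hazard,
        spectral_exponent=spectral_exponent,
        patch_kind=patch_kind,
        approx_predictive=approx_predictive,
        W=W,
    )
    states = np.concatenate([np.ones(n_train, int), np.zeros(n_train, int)])
    images = task.sample_images(states, rng)
    S = task.encode_images(images)
    m = S @ w + b + rng.normal(0.0, np.sqrt(task.sigma_m2), size=len(S))
    models = obs.fit_class_models({"P": m[states == 1], "A": m[states == 0]})
    task.model_pos, task.model_neg = models["P"], models["A"]
    return task


# ---------------------------------------------------------------------------
# target localization
# ---------------------------------------------------------------------------

@dataclass
class LocalizationTask:
    name: str
    dictionary: Dictionary
    cross: Template
    sparse_cfg: SparseConfig
    atom_corr: np.ndarray
    base_corr: np.ndarray
    walk_sigma: float = 1.2
    sigma_m2: float = obs.SIGMA_M2_LOCALIZATION
    spectral_exponent: float = 2.0
    patch_kind: str = "dead_leaves"
    drift: float = 1.0
    train_spread: float | None = None
    W: int = 32

    @property
    def n_neurons(self) -> int:
        return self.dictionary.N

    def encode_images(self, images: np.ndarray) -> np.ndarray:
        return np.atleast_2d(
            encode(self.dictionary.pca.reduce(images), self.dictionary, self.sparse_cfg)
        )

    def sample_images(
        self, positions: np.ndarray, rng: np.random.Generator, movie: bool = True
    ) -> np.ndarray:
        T = len(positions)
        if movie:
            frames = generate_movie(
                max(T, 2), self.W, self.drift, self.spectral_exponent, _seed(rng),
                kind=self.patch_kind,
            )[:T]
        else:
            frames = generate_patches(
                T, self.W, self.spectral_exponent, _seed(rng), kind=self.patch_kind
            )
        out = np.empty_like(frames)
        for t in range(T):
            out[t] = superimpose_target(frames[t], self.cross, tuple(positions[t]))
        return out

    def evaluator_for_belief(self, point, n_mc, psi, alpha, rng) -> LocalizationCostEvaluator:
        point = np.asarray(point, dtype=float)
        # target positions scattered around the belief point; the spread
        # covers the belief-grid selection cell (W/4 at the default 3x3
        # grid) so entries also protect positions between grid points
        spread = self.train_spread or max(self.walk_sigma, self.W / 4.0)
        pos = rng.normal(point[None, :], spread, size=(n_mc, 2))
        pos = np.clip(np.round(pos), 1, self.W)
        images = self.sample_images(pos, rng, movie=False)
        S = self.encode_images(images)
        noise = rng.normal(0.0, np.sqrt(self.sigma_m2), size=(n_mc, 2))
        prior_var = np.full(2, self.walk_sigma**2)
        return LocalizationCostEvaluator(
            S,
            self.atom_corr,
            self.base_corr,
            point,
            prior_var,
            self.sigma_m2,
            psi,
            self.W,
            alpha,
            noise,
        )

    def measure(self, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        peak = obs.measure_localization(z, self.dictionary, self.cross)
        return np.asarray(peak, dtype=float) + rng.normal(
            0.0, np.sqrt(self.sigma_m2), size=2
        )

    def update(self, belief: obs.GaussBelief, m: np.ndarray) -> obs.GaussBelief:
        return obs.update_position_belief(
            belief, m, self.sigma_m2, self.walk_sigma**2
        )


def build_localization_task(
    dictionary: Dictionary,
    W: int,
    seed: int = 0,
    walk_sigma: float = 1.2,
    lam: float = 0.1,
    sigma2: float = 0.5,
    drift: float = 1.0,
    spectral_exponent: float = 2.0,
    patch_kind: str = "dead_leaves",
) -> LocalizationTask:
    """Assemble the localization task, precomputing per-atom correlation maps."""
    rng = np.random.default_rng(seed)
    _, cross = make_templates(W, _seed(rng))
    basis = dictionary.pixel_basis()
    atom_corr = np.empty((dictionary.N, W * W))
    for n in range(dictionary.N):
        atom_corr[n] = obs.cross_correlation_map(basis[n].reshape(W, W), cross).ravel()
    base_corr = obs.cross_correlation_map(
        dictionary.pca.mean.reshape(W, W), cross
    ).ravel()
    return LocalizationTask(
        name="localization",
        dictionary=dictionary,
        cross=cross,
        sparse_cfg=SparseConfig(lam=lam, sigma2=sigma2),
        atom_corr=atom_corr,
        base_corr=base_corr,
        walk_sigma=walk_sigma,
        drift=drift,
        spectral_exponent=spectral_exponent,
        patch_kind=patch_kind,
        W=W,
    )


# ---------------------------------------------------------------------------
# orientation estimation
# ---------------------------------------------------------------------------

@dataclass
class OrientationTask:
    name: str
    dictionary: Dictionary
    sparse_cfg: SparseConfig
    disc: obs.Discriminant
    model_pos: obs.ClassModel  # horizontal
    model_neg: obs.ClassModel  # vertical
    pools: dict = field(default_factory=dict)  # train/eval images + codes per state
    hazard: float = 0.01
    sigma_m2: float = obs.SIGMA_M2_ORIENTATION
    approx_predictive: bool = False
    W: int = 32

    @property
    def n_neurons(self) -> int:
        return self.dictionary.N

    def _draw(self, state: str, split: str, n: int, rng: np.random.Generator):
        pool = self.pools[split][state]
        idx = rng.integers(len(pool["codes"]), size=n)
        return pool["codes"][idx], pool["images"][idx]

    def evaluator_for_belief(self, p, n_mc, psi, alpha, rng) -> BinaryCostEvaluator:
        p = float(p)
        n_h = int(round(p * n_mc))
        S_h, _ = self._draw("H", "train", n_h, rng)
        S_v, _ = self._draw("V", "train", n_mc - n_h, rng)
        S = np.vstack([S_h, S_v])
        noise = rng.normal(0.0, np.sqrt(self.sigma_m2), size=n_mc)
        # the measurement |z| . d is linear in the response magnitudes and
        # shrinkage commutes with the absolute value, so the evaluator can
        # run on |s| directly
        return BinaryCostEvaluator(
            np.abs(S), self.disc.w, 0.0, self.model_pos, self.model_neg, p, psi, alpha, noise,
            kl_weight=self.n_neurons,
        )

    def measure(self, z: np.ndarray, rng: np.random.Generator) -> float:
        return obs.measure_orientation(z, self.disc, self.sigma_m2, rng)

    def update(self, prior_p: float, m: float) -> tuple[float, float]:
        return obs.update_binary_belief(
            prior_p,
            m,
            self.model_pos,
            self.model_neg,
            self.hazard,
            self.approx_predictive,
        )


def build_orientation_task(
    dictionary: Dictionary,
    corpus_images: np.ndarray,
    seed: int = 0,
    n_train: int = 1000,
    hazard: float = 0.01,
    lam: float = 0.05,
    sigma2: float = 0.5,
    k_clusters: int = 9,
    manual_clusters: tuple[int, int] | None = None,
    ridge: float = 0.1,
) -> OrientationTask:
    """Assemble the orientation task from an unlabeled patch corpus.

    The corpus is sparse-coded, clustered into horizontally and vertically
    dominated categories, split 50/50 into threshold-training and
    simulation pools (so the discriminant is never evaluated on its own
    training patches), and the Fisher discriminant plus the measurement
    class models are fitted on the training halves.
    """
    rng = np.random.default_rng(seed)
    cfg = SparseConfig(lam=lam, sigma2=sigma2)
    S_corpus = np.atleast_2d(
        encode(dictionary.pca.reduce(corpus_images), dictionary, cfg)
    )
    cats = obs.learn_orientation_categories(
        S_corpus, dictionary, k=k_clusters, seed=_seed(rng), manual=manual_clusters
    )
    pools: dict = {"train": {}, "eval": {}}
    for state in ("H", "V"):
        idx = cats[state]
        if len(idx) < 4:
            raise ValueError(f"cluster {state} too small ({len(idx)} patches)")
        perm = rng.permutation(idx)
        half = len(perm) // 2
        for split, sel in (("train", perm[:half]), ("eval", perm[half:])):
            pools[split][state] = {
                "codes": S_corpus[sel],
                "images": corpus_images[sel],
                "indices": sel,
            }
    # heavy ridge: the pools are small relative to N, and an overfit
    # discriminant would separate the training halves but not fresh draws
    disc = obs.learn_discriminant(
        np.abs(pools["train"]["H"]["codes"]),
        np.abs(pools["train"]["V"]["codes"]),
        ridge=ridge,
    )
    task = OrientationTask(
        name="orientation",
        dictionary=dictionary,
        sparse_cfg=cfg,
        disc=disc,
        model_pos=obs.ClassModel(0.0, 1.0),
        model_neg=obs.ClassModel(0.0, 1.0),
        pools=pools,
        hazard=hazard,
        W=corpus_images.shape[1],
    )
    ms = {}
    for state in ("H", "V"):
        codes, _ = task._draw(state, "train", n_train, rng)
        ms[state] = np.abs(codes) @ disc.w + rng.normal(
            0.0, np.sqrt(task.sigma_m2), size=n_train
        )
    models = obs.fit_class_models(ms)
    task.model_pos, task.model_neg = models["H"], models["V"]
    task.categories = cats
    return task
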