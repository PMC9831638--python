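"""Task-specific measurements and Bayesian belief updates.

Three perceptual observers sit downstream of the sensory population:

* **Object detection** — project the linearly decoded image onto the
  object template; binary posterior over present/absent tracked through a
  telegraph-process prior.
* **Target localization** — take the peak of the 2-D cross-correlation
  between the decoded image and the cross template as a noisy position
  measurement; conjugate Gaussian posterior per spatial coordinate.
* **Orientation estimation** — project response magnitudes ``|z|`` onto a
  Fisher discriminant separating horizontally from vertically dominated
  patches (discovered by unsupervised clustering); binary posterior over
  H/V.

All binary updates run in log space and never produce NaNs; posterior
probabilities are clipped away from exactly 0/1 where divergences are
computed downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from sklearn.cluster import KMeans

from .sparse import Dictionary, decode
from .stimuli import Template

__all__ = [
    "ClassModel",
    "GaussBelief",
    "Discriminant",
    "measure_detection",
    "fit_class_models",
    "update_binary_belief",
    "measure_localization",
    "update_position_belief",
    "log_ratio_features",
    "learn_orientation_categories",
    "learn_discriminant",
    "measure_orientation",
]

# default measurement noise variances per task
SIGMA_M2_DETECTION = 0.01
SIGMA_M2_LOCALIZATION = 1e-10  # sigma_m = 1e-5: effectively noiseless
SIGMA_M2_ORIENTATION = 1e-4


@dataclass(frozen=True)
class ClassModel:
    """Gaussian measurement model for one latent class: ``m ~ N(mu, sigma^2)``."""

    mu: float
    sigma: float
    floored: bool = False

    def logpdf(self, m: np.ndarray | float) -> np.ndarray | float:
        z = (np.asarray(m, dtype=float) - self.mu) / self.sigma
        return -0.5 * z * z - np.log(self.sigma) - 0.5 * np.log(2.0 * np.pi)


@dataclass
class GaussBelief:
    """Independent Gaussian posterior per spatial coordinate (row, col)."""

    mean: np.ndarray  # length 2
    var: np.ndarray  # length 2

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.var <= 0):
            raise ValueError("belief variances must be positive")


@dataclass
class Discriminant:
    """Linear readout direction over response-magnitude features."""

    w: np.ndarray
    meta: dict

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump({"w": self.w.tolist(), "meta": self.meta}, f)

    @classmethod
    def load(cls, path: str) -> "Discriminant":
        with open(path) as f:
            blob = json.load(f)
        return cls(w=np.asarray(blob["w"]), meta=blob["meta"])


# ---------------------------------------------------------------------------
# object detection
# ---------------------------------------------------------------------------

def detection_readout(dictionary: Dictionary, obj: Template) -> tuple[np.ndarray, float]:
    """Linear form of the detection measurement.

    Because decoding is affine in the code, ``m = decode(z) . obj`` equals
    ``w . z + b``; returns ``(w, b)`` with ``w_n = (phi_n -> pixels) . obj``.
    """
    t = obj.pixels.ravel()
    w = dictionary.pixel_basis() @ t
    b = float(dictionary.pca.mean @ t)
    return w, b


def measure_detection(
    z: np.ndarray,
    dictionary: Dictionary,
    obj: Template,
    sigma_m2: float = SIGMA_M2_DETECTION,
    rng: np.random.Generator | None = None,
) -> float:
    """Noisy projection of the decoded image onto the object template."""
    xhat = decode(z, dictionary)
    m = float(xhat.ravel() @ obj.pixels.ravel())
    if sigma_m2 > 0 and rng is not None:
        m += rng.normal(0.0, np.sqrt(sigma_m2))
    return m


def fit_class_models(
    measurements_by_class: dict[str, np.ndarray], sigma_floor: float = 1e-6
) -> dict[str, ClassModel]:
    """Per-class sample mean and unbiased std of the measurement.

    A class with (numerically) zero spread gets its sigma floored and
    flagged rather than producing a degenerate likelihood.
    """
    out = {}
    for label, m in measurements_by_class.items():
        m = np.asarray(m, dtype=float)
        if m.size < 2:
            raise ValueError(f"class {label!r} needs at least 2 samples")
        mu = float(m.mean())
        sd = float(m.std(ddof=1))
        floored = sd < sigma_floor
        out[label] = ClassModel(mu=mu, sigma=max(sd, sigma_floor), floored=floored)
    return out


def update_binary_belief(
    prior_p: float,
    m: float,
    model_pos: ClassModel,
    model_neg: ClassModel,
    hazard: float = 0.01,
    approx_predictive: bool = False,
) -> tuple[float, float]:
    """One Bayes step for a telegraph-process binary state.

    Returns ``(posterior_p, predictive_p)`` where the posterior combines
    the Gaussian class likelihoods with ``prior_p`` (computed in log
    space), and the predictive propagates through the hazard:
    ``(1 - h) * post + h * (1 - post)``.  With ``approx_predictive=True``
    the low-hazard shortcut ``predictive = posterior`` is used instead.
    """
    if not 0.0 <= prior_p <= 1.0:
        raise ValueError("prior probability outside [0, 1]")
    if not 0.0 <= hazard <= 1.0:
        raise ValueError("hazard outside [0, 1]")
    lp = model_pos.logpdf(m)
    ln = model_neg.logpdf(m)
    with np.errstate(divide="ignore"):
        log_odds_prior = np.log(prior_p) - np.log1p(-prior_p) if 0 < prior_p < 1 else (
            np.inf if prior_p == 1.0 else -np.inf
        )
    log_odds = log_odds_prior + (lp - ln)
    if np.isposinf(log_odds):
        post = 1.0
    elif np.isneginf(log_odds):
        post = 0.0
    elif log_odds >= 0:
        post = 1.0 / (1.0 + np.exp(-log_odds))
    else:
        e = np.exp(log_odds)
        post = e / (1.0 + e)
    pred = post if approx_predictive else (1.0 - hazard) * post + hazard * (1.0 - post)
    return float(post), float(pred)


# ---------------------------------------------------------------------------
# target localization
# ---------------------------------------------------------------------------

def cross_correlation_map(image: np.ndarray, cross: Template) -> np.ndarray:
    """"Same"-size zero-padded 2-D cross-correlation with the cross template.

    Entry ``(i, j)`` scores the template centered at 1-based position
    ``(i+1, j+1)``.
    """
    kernel = cross.pixels[::-1, ::-1]
    return fftconvolve(image, kernel, mode="same")


def measure_localization(
    z: np.ndarray, dictionary: Dictionary, cross: Template
) -> tuple[int, int]:
    """Peak of the cross-correlation between the decoded image and the target.

    Returns 1-based integer ``(row, col)``; ties resolve to the smallest
    row, then the smallest column.
    """
    xhat = decode(z, dictionary)
    return correlation_peak(xhat, cross)


def correlation_peak(image: np.ndarray, cross: Template) -> tuple[int, int]:
    c = cross_correlation_map(np.asarray(image, dtype=float), cross)
    # argmax on the flattened row-major array is the lexicographic minimum
    idx = int(np.argmax(np.round(c, 9)))
    r, col = divmod(idx, c.shape[1])
    return r + 1, col + 1


def update_position_belief(
    belief: GaussBelief,
    m: tuple[float, float],
    sigma_m2: float = SIGMA_M2_LOCALIZATION,
    walk_var: float = 0.0,
) -> GaussBelief:
    """Conjugate Gaussian update per coordinate, then random-walk inflation.

    Posterior: ``mu' = (sigma_m^2 mu + sigma^2 m) / (sigma^2 + sigma_m^2)``,
    ``var' = sigma^2 sigma_m^2 / (sigma^2 + sigma_m^2)``.  The returned
    belief carries the *predicted measurement* variance ``var' + walk_var``
    so the next update already accounts for target motion.
    """
    m = np.asarray(m, dtype=float)
    v0 = belief.var
    if sigma_m2 == 0:
        mu, v = m.copy(), np.zeros(2)
    else:
        mu = (sigma_m2 * belief.mean + v0 * m) / (v0 + sigma_m2)
        v = v0 * sigma_m2 / (v0 + sigma_m2)
    return GaussBelief(mean=mu, var=v + walk_var + 1e-300)


# ---------------------------------------------------------------------------
# orientation estimation
# ---------------------------------------------------------------------------

def log_ratio_features(S: np.ndarray, eps_frac: float = 1e-6) -> np.ndarray:
    """Per-neuron log-ratio features ``r_{n,t} = log(|s_{n,t}| / <|s_n|>_t)``.

    Exact zeros (ubiquitous in l1-sparse codes) are floored at
    ``eps_frac * max|s|`` inside the logarithm so a silent neuron
    contributes a constant, finite feature.
    """
    A = np.abs(np.asarray(S, dtype=float))
    floor = eps_frac * max(A.max(), 1e-30)
    A = np.maximum(A, floor)
    return np.log(A / A.mean(axis=0, keepdims=True))


def atom_orientations(dictionary: Dictionary) -> np.ndarray:
    """Dominant Fourier orientation of each atom's pixel image, in [0, 180).

    Orientation is that of the image *stripes* (perpendicular to the
    dominant wave vector), matching the grating convention where 0 deg
    means horizontal stripes.
    """
    basis = dictionary.pixel_basis()
    W = int(np.sqrt(basis.shape[1]))
    fy = np.fft.fftfreq(W)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    out = np.empty(dictionary.N)
    for n in range(dictionary.N):
        P = np.abs(np.fft.fft2(basis[n].reshape(W, W))) ** 2
        P[0, 0] = 0.0
        idx = np.unravel_index(int(np.argmax(P)), P.shape)
        ky, kx = float(fy[idx[0], 0]), float(fx[0, idx[1]])
        # wave vector (ky, kx); stripes run perpendicular to it.  With
        # u = cos(t)*row + sin(t)*col, a grating of orientation t has wave
        # vector (cos t, sin t), so t = atan2(kx, ky) ... orientation of
        # stripes = angle of the wave vector in (row, col) frame.
        ang = np.rad2deg(np.arctan2(kx, ky)) % 180.0
        out[n] = ang
    return out


def atom_centroids(dictionary: Dictionary) -> np.ndarray:
    """Energy centroid (1-based row, col) of each atom's pixel image."""
    basis = dictionary.pixel_basis()
    W = int(np.sqrt(basis.shape[1]))
    yy, xx = np.mgrid[1 : W + 1, 1 : W + 1].astype(float)
    out = np.empty((dictionary.N, 2))
    for n in range(dictionary.N):
        e = basis[n].reshape(W, W) ** 2
        tot = e.sum()
        out[n] = [(e * yy).sum() / tot, (e * xx).sum() / tot]
    return out


def learn_orientation_categories(
    S: np.ndarray,
    dictionary: Dictionary,
    k: int = 9,
    seed: int = 0,
    n_retries: int = 5,
    manual: tuple[int, int] | None = None,
) -> dict:
    """Discover horizontally and vertically dominated patch categories.

    Sparse codes of a patch corpus are mapped to log-ratio features and
    clustered with (seeded) k-means, ``k = 9``.  Two clusters are then
    selected automatically: for each cluster, the orientations of atoms
    whose mean feature exceeds 0 (more active than their baseline) are
    averaged on the doubled-angle circle; the cluster closest to 0 deg
    becomes H and the one closest to 90 deg becomes V.  ``manual`` forces
    specific cluster indices instead.

    Returns a dict with keys ``H`` and ``V`` (member patch indices),
    ``labels``, ``features``, and ``cluster_orientation``.
    """
    R = log_ratio_features(S)
    orients = atom_orientations(dictionary)
    for attempt in range(n_retries):
        km = KMeans(n_clusters=k, n_init=4, random_state=seed + attempt)
        labels = km.fit_predict(R)
        if len(np.unique(labels)) == k:
            break
    else:
        raise RuntimeError("k-means failed to produce k non-empty clusters")
    cluster_orient = np.full(k, np.nan)
    h_score = np.full(k, np.inf)
    v_score = np.full(k, np.inf)
    corpus_mean = R.mean(axis=0)
    for c in range(k):
        # neurons more active in this cluster than their corpus baseline
        excess = R[labels == c].mean(axis=0) - corpus_mean
        active = excess > 0
        if not active.any():
            continue
        th = np.deg2rad(orients[active]) * 2.0
        wts = excess[active]
        ang = np.rad2deg(np.angle(np.sum(wts * np.exp(1j * th)))) / 2.0 % 180.0
        cluster_orient[c] = ang
        h_score[c] = min(ang, 180.0 - ang)  # distance to horizontal
        v_score[c] = abs(ang - 90.0)
    if manual is not None:
        h_idx, v_idx = manual
    else:
        h_idx = int(np.argmin(h_score))
        v_idx = int(np.argmin(v_score))
        if h_idx == v_idx:  # degenerate: pick next best vertical
            order = np.argsort(v_score)
            v_idx = int(order[1])
    return {
        "H": np.flatnonzero(labels == h_idx),
        "V": np.flatnonzero(labels == v_idx),
        "labels": labels,
        "features": R,
        "cluster_orientation": cluster_orient,
        "h_idx": h_idx,
        "v_idx": v_idx,
    }


def learn_discriminant(
    R_pos: np.ndarray, R_neg: np.ndarray, ridge: float = 1e-6
) -> Discriminant:
    """Fisher linear discriminant between two feature clouds.

    Uses the pooled within-class covariance with a ridge proportional to
    its mean diagonal; flagged in metadata when the raw covariance is
    singular.
    """
    R_pos = np.atleast_2d(R_pos)
    R_neg = np.atleast_2d(R_neg)
    if len(R_pos) == 0 or len(R_neg) == 0:
        raise ValueError("both classes must be non-empty")
    mu_p, mu_n = R_pos.mean(axis=0), R_neg.mean(axis=0)
    Sw = np.cov(R_pos, rowvar=False) * (len(R_pos) - 1) + np.cov(
        R_neg, rowvar=False
    ) * (len(R_neg) - 1)
    Sw /= max(len(R_pos) + len(R_neg) - 2, 1)
    scale = max(float(np.trace(Sw)) / Sw.shape[0], 1e-12)
    singular = not np.all(np.linalg.eigvalsh(Sw) > 1e-12 * scale)
    w = np.linalg.solve(Sw + ridge * scale * np.eye(Sw.shape[0]), mu_p - mu_n)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        w = mu_p - mu_n
        nrm = np.linalg.norm(w) or 1.0
    return Discriminant(w=w / nrm, meta={"singular_cov": bool(singular)})


def measure_orientation(
    z: np.ndarray,
    disc: Discriminant,
    sigma_m2: float = SIGMA_M2_ORIENTATION,
    rng: np.random.Generator | None = None,
) -> float:
    """Noisy projection of response magnitudes on the discriminant."""
    m = float(np.abs(np.asarray(z, dtype=float)) @ disc.w)
    if sigma_m2 > 0 and rng is not None:
        m += rng.normal(0.0, np.sqrt(sigma_m2))
    return m
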