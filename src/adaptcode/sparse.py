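"""Sparse coding of image patches: inference, decoding, and dictionary learning.

A population of ``N`` model neurons represents a patch ``x`` (in a reduced
PCA space of dimension ``d``) through activations ``s`` minimizing

    E(s) = sum_i (xhat_i - x_i)^2 / (2 sigma^2) + lambda * sum_n |s_n|,

with linear decoding ``xhat = Phi^T s`` and unit-norm feature rows
``phi_n``.  Coefficients are found with FISTA on the exact l1 objective;
features are learned by alternating batched inference with gradient steps
on the reconstruction term, renormalizing rows after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .stimuli import PcaMap

__all__ = ["SparseConfig", "Dictionary", "encode", "decode", "energy", "learn_dictionary"]


@dataclass(frozen=True)
class SparseConfig:
    """Inference settings.

    ``lam`` is the sparsity weight (1.0 during learning; tasks use softer
    values such as 0.05 or 0.1) and ``sigma2`` the reconstruction noise
    level (0.5 throughout).
    """

    lam: float = 1.0
    sigma2: float = 0.5
    tol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


@dataclass
class Dictionary:
    """Learned features ``phi_n`` (rows of ``features``, N x d) plus the PCA map."""

    features: np.ndarray
    pca: PcaMap
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def pixel_basis(self) -> np.ndarray:
        """Back-projected features in pixel space, one flattened image per row.

        These are the neurons' receptive-field images (without the PCA mean,
        which is an additive constant of the decoder, not a feature).
        """
        return self.features @ self.pca.components

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.features)
            f.create_dataset("pca_mean", data=self.pca.mean)
            f.create_dataset("pca_components", data=self.pca.components)
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str) -> "Dictionary":
        with h5py.File(path, "r") as f:
            feats = f["features"][...]
            pmap = PcaMap(mean=f["pca_mean"][...], components=f["pca_components"][...])
            meta = dict(f.attrs)
        return cls(features=feats, pca=pmap, meta=meta)


def decode(s: np.ndarray, dictionary: Dictionary, *, pixel: bool = True) -> np.ndarray:
    """Linear decoding ``xhat = sum_n phi_n s_n``.

    With ``pixel=True`` (default) the reconstruction is returned as a
    ``(W, W)`` image (PCA mean added back); otherwise as reduced-space
    coordinates.  Accepts a single code or a stack ``(B, N)``.
    """
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    S = np.atleast_2d(s)
    if S.shape[1] != dictionary.N:
        raise ValueError("code length does not match dictionary size")
    red = S @ dictionary.features
    if not pixel:
        return red[0] if single else red
    flat = dictionary.pca.expand(red)
    W = int(np.sqrt(flat.shape[1]))
    imgs = flat.reshape(-1, W, W)
    return imgs[0] if single else imgs


def energy(
    x_red: np.ndarray, s: np.ndarray, dictionary: Dictionary, cfg: SparseConfig
) -> float | np.ndarray:
    """Sparse-coding energy of code ``s`` for reduced-space input ``x_red``."""
    x_red = np.atleast_2d(np.asarray(x_red, dtype=float))
    S = np.atleast_2d(np.asarray(s, dtype=float))
    resid = S @ dictionary.features - x_red
    e = (resid**2).sum(axis=1) / (2.0 * cfg.sigma2) + cfg.lam * np.abs(S).sum(axis=1)
    return float(e[0]) if e.shape[0] == 1 else e


def _soft(u: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(u) * np.maximum(np.abs(u) - thr, 0.0)


def encode(
    x_red: np.ndarray, dictionary: Dictionary, cfg: SparseConfig
) -> np.ndarray:
    """Infer sparse coefficients by FISTA on the l1 objective.

    ``x_red`` may be a single reduced-space vector ``(d,)`` or a batch
    ``(B, d)``; codes are returned with matching leading shape.  The
    problem is convex, so the result is within solver tolerance of the
    global optimum.
    """
    x_red = np.asarray(x_red, dtype=float)
    single = x_red.ndim == 1
    Y = np.atleast_2d(x_red)
    Phi = dictionary.features  # (N, d)
    G = Phi @ Phi.T  # Gram, (N, N)
    # Lipschitz constant of the smooth part's gradient
    L = float(np.linalg.eigvalsh(G)[-1]) / cfg.sigma2
    if L <= 0:
        raise ValueError("degenerate dictionary")
    PhiY = Y @ Phi.T  # (B, N)
    S = np.zeros_like(PhiY)
    Z = S.copy()
    t = 1.0
    e_prev = np.inf
    for it in range(cfg.max_iter):
        grad = (Z @ G - PhiY) / cfg.sigma2
        S_new = _soft(Z - grad / L, cfg.lam / L)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Z = S_new + ((t - 1.0) / t_new) * (S_new - S)
        S, t = S_new, t_new
        if it % 10 == 9:
            e = float(np.sum(energy(Y, S, dictionary, cfg)))
            if abs(e_prev - e) <= cfg.tol * max(1.0, abs(e)):
                break
            e_prev = e
    return S[0] if single else S


def learn_dictionary(
    coords: np.ndarray,
    N: int,
    cfg: SparseConfig | None = None,
    epochs: int = 10,
    batch_size: int = 250,
    lr0: float = 1.0,
    seed: int = 0,
) -> tuple[Dictionary, list[float]]:
    """SparseNet-style alternating minimization on a PCA-reduced corpus.

    Each epoch shuffles the corpus, and for each mini-batch infers codes
    (FISTA) then takes a gradient step on the reconstruction error with
    respect to the features, renormalizing every row to unit norm.  The
    learning rate decays as ``lr0 / sqrt(epoch)``.

    Returns the learned dictionary (without a PCA map attached; see
    :func:`attach_pca`) and the per-epoch mean energy trace.

    Notes
    -----
    ``coords`` must be the corpus in reduced space (``n`` x ``d``) with
    nonzero variance; the mean energy is non-increasing across epochs up
    to mini-batch noise.
    """
    cfg = cfg or SparseConfig()
    coords = np.asarray(coords, dtype=float)
    if coords.std() == 0:
        raise ValueError("degenerate corpus (zero variance)")
    n, d = coords.shape
    rng = np.random.default_rng(seed)
    Phi = rng.standard_normal((N, d))
    Phi /= np.linalg.norm(Phi, axis=1, keepdims=True)
    dct = Dictionary(features=Phi, pca=_identity_pca(d), meta={})
    trace: list[float] = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        lr = lr0 / np.sqrt(epoch)
        batch_energies = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Y = coords[idx]
            S = encode(Y, dct, cfg)
            resid = S @ dct.features - Y  # (B, d)
            grad = S.T @ resid / (cfg.sigma2 * len(idx))
            dct.features -= lr * grad
            norms = np.linalg.norm(dct.features, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            dct.features /= norms
            batch_energies.append(float(np.mean(energy(Y, S, dct, cfg))))
        trace.append(float(np.mean(batch_energies)))
    dct.meta.update({"lam": cfg.lam, "sigma2": cfg.sigma2, "N": N, "seed": seed})
    return dct, trace


def _identity_pca(d: int) -> PcaMap:
    return PcaMap(mean=np.zeros(d), components=np.eye(d))


def attach_pca(dictionary: Dictionary, pmap: PcaMap) -> Dictionary:
    """Return a copy of ``dictionary`` with a pixel-space PCA map attached."""
    if pmap.d != dictionary.d:
        raise ValueError("PCA dimensionality does not match the dictionary")
    return Dictionary(
        features=dictionary.features.copy(), pca=pmap, meta=dict(dictionary.meta)
    )
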