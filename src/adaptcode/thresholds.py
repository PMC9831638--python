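"""Belief-conditioned threshold optimization for the sensory population.

The perceptual observer sets every neuron's shrinkage threshold ``xi_n`` to
minimize, in expectation over the stimuli it predicts for its current
belief, the cost

    C(xi) = < D_KL_sym[ p(theta | z(xi)) || p(theta | z(0)) ] >
            + psi * sum_n <|z_n(xi_n)|>,

i.e. the inference error that thresholding introduces relative to the full
sparse code, plus an attentional resource constraint ``psi`` on neural
activity.  The expectation is a Monte-Carlo average over a sample set
drawn once per optimization (common random numbers, shared between the
compressed and full branches), which makes the cost deterministic within a
run and exactly zero at ``xi = 0``.

Minimization follows the resilient-backpropagation scheme with a
numerically estimated gradient: thresholds are reparametrized as
``xi_n = a_n^2`` with ``a`` real-valued, the gradient comes from central
finite differences (cheap, because the sparse codes are fixed and only the
pointwise nonlinearity and the observer arithmetic are re-evaluated per
perturbed coordinate), and steps that increase the cost are rejected with
a step-size shrink, so the accepted cost trace is non-increasing.

Per-belief optima are precomputed offline into a :class:`ThresholdTable`
over a discretized belief grid and looked up during closed-loop
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .observers import ClassModel
from .shrinkage import DEFAULT_ALPHA, shrink
from .sparse import Dictionary

__all__ = [
    "OptimConfig",
    "ThresholdTable",
    "BinaryCostEvaluator",
    "LocalizationCostEvaluator",
    "RoiCostEvaluator",
    "bernoulli_sym_kl",
    "gaussian_sym_kl",
    "optimize_thresholds",
    "build_threshold_table",
    "select_thresholds",
    "roi_compress",
]

_P_CLIP = 1e-12


@dataclass(frozen=True)
class OptimConfig:
    """Settings of the Rprop threshold search.

    ``psi`` is the attentional resource constraint (default 4, the value
    used for all dynamic tasks); ``n_mc`` the Monte-Carlo training-set
    size per belief point.
    """

    psi: float = 4.0
    n_mc: int = 300
    step_init: float = 0.1
    step_min: float = 1e-6
    step_max: float = 1.0
    eta_up: float = 1.2
    eta_down: float = 0.5
    max_iter: int = 200
    fd_step: float = 1e-3
    rel_tol: float = 1e-6
    tol_window: int = 15
    init_scale: float = 0.1
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError("psi must be >= 0")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")


@dataclass
class ThresholdTable:
    """Optimal threshold vectors indexed by a discretized belief grid.

    ``grid`` holds the belief points — shape ``(k,)`` of probabilities for
    the binary tasks, ``(k, 2)`` of positions for localization — and
    ``xi`` the matching ``(k, N)`` threshold vectors.
    """

    task: str
    grid: np.ndarray
    xi: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("grid", data=self.grid)
            f.create_dataset("xi", data=self.xi)
            f.create_dataset("valid", data=self.valid.astype(np.int8))
            f.attrs["task"] = self.task
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str) -> "ThresholdTable":
        with h5py.File(path, "r") as f:
            attrs = dict(f.attrs)
            task = str(attrs.pop("task"))
            return cls(
                task=task,
                grid=f["grid"][...],
                xi=f["xi"][...],
                valid=f["valid"][...].astype(bool),
                meta=attrs,
            )


# ---------------------------------------------------------------------------
# divergences
# ---------------------------------------------------------------------------

def bernoulli_sym_kl(p: np.ndarray | float, q: np.ndarray | float) -> np.ndarray | float:
    """Symmetrized KL divergence between Bernoulli(p) and Bernoulli(q).

    Equal to ``(p - q) * (logit(p) - logit(q))``; probabilities are clipped
    to ``[1e-12, 1 - 1e-12]`` so the result is always finite.
    """
    p = np.clip(np.asarray(p, dtype=float), _P_CLIP, 1.0 - _P_CLIP)
    q = np.clip(np.asarray(q, dtype=float), _P_CLIP, 1.0 - _P_CLIP)
    out = (p - q) * (np.log(p / (1.0 - p)) - np.log(q / (1.0 - q)))
    return float(out) if out.ndim == 0 else out


def gaussian_sym_kl(
    mu1: np.ndarray, v1: np.ndarray, mu2: np.ndarray, v2: np.ndarray
) -> np.ndarray:
    """Closed-form symmetrized KL between two univariate Gaussians."""
    mu1, v1 = np.asarray(mu1, dtype=float), np.asarray(v1, dtype=float)
    mu2, v2 = np.asarray(mu2, dtype=float), np.asarray(v2, dtype=float)
    return 0.5 * (v1 / v2 + v2 / v1 - 2.0) + 0.5 * (mu1 - mu2) ** 2 * (
        1.0 / v1 + 1.0 / v2
    )


# ---------------------------------------------------------------------------
# cost evaluators
# ---------------------------------------------------------------------------

class BinaryCostEvaluator:
    """Cost of a threshold vector for a binary-state task (detection, H/V).

    Works on a fixed set of sparse codes ``S`` (``n_mc`` x ``N``) drawn from
    the belief's predicted stimulus distribution.  The measurement is
    affine in the response, ``m = z . w + b + noise``, so per-coordinate
    threshold perturbations update the measurement incrementally and the
    full numerical gradient costs O(N * n_mc).

    ``kl_weight`` calibrates the inference-error term against the summed
    activity cost.  A binary posterior divergence is O(1) per sample while
    the population activity is O(N), so the divergence is weighted by the
    population size (the task builders pass ``kl_weight = N``); this keeps
    the two objectives commensurate at ``psi`` of order one and yields the
    belief-dependent partial suppression the framework is about, rather
    than an all-or-nothing code.
    """

    def __init__(
        self,
        S: np.ndarray,
        w: np.ndarray,
        b: float,
        model_pos: ClassModel,
        model_neg: ClassModel,
        prior_p: float,
        psi: float,
        alpha: float = DEFAULT_ALPHA,
        noise: np.ndarray | None = None,
        kl_weight: float = 1.0,
    ):
        self.S = np.asarray(S, dtype=float)
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)
        self.model_pos = model_pos
        self.model_neg = model_neg
        # training beliefs at the ends of the grid are kept barely
        # uncertain so the Bayes update stays responsive
        self.prior_p = float(np.clip(prior_p, 1e-3, 1.0 - 1e-3))
        self._prior_logit = np.log(self.prior_p / (1.0 - self.prior_p))
        self.psi = float(psi)
        self.alpha = float(alpha)
        self.noise = np.zeros(len(self.S)) if noise is None else np.asarray(noise)
        self.kl_weight = float(kl_weight)
        self._m0 = self.S @ self.w + self.b + self.noise
        self._post0 = self._posterior(self._m0)

    @property
    def n_params(self) -> int:
        return self.S.shape[1]

    def _posterior(self, m: np.ndarray) -> np.ndarray:
        dll = self.model_pos.logpdf(m) - self.model_neg.logpdf(m)
        x = self._prior_logit + dll
        # numerically stable sigmoid
        out = np.empty_like(np.asarray(x, dtype=float))
        x = np.asarray(x, dtype=float)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    def _measurements(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.w + self.b + self.noise

    def kl_term(self, Z: np.ndarray) -> float:
        post = self._posterior(self._measurements(Z))
        return float(np.mean(bernoulli_sym_kl(post, self._post0)))

    def activity_term(self, Z: np.ndarray) -> float:
        return float(np.abs(Z).mean(axis=0).sum())

    def cost(self, xi: np.ndarray) -> float:
        Z = shrink(self.S, xi[None, :], self.alpha)
        return self.kl_weight * self.kl_term(Z) + self.psi * self.activity_term(Z)

    def perturbed_costs(self, xi: np.ndarray, xi_alt: np.ndarray) -> np.ndarray:
        """Cost with coordinate ``n`` moved to ``xi_alt[n]``, for every n at once."""
        Z = shrink(self.S, xi[None, :], self.alpha)
        Za = shrink(self.S, xi_alt[None, :], self.alpha)
        m_base = self._measurements(Z)
        dM = (Za - Z) * self.w[None, :]  # (n_mc, N)
        post = self._posterior(m_base[:, None] + dM)
        kl = bernoulli_sym_kl(post, self._post0[:, None]).mean(axis=0)
        act_base = np.abs(Z).mean(axis=0)
        act = act_base.sum() - act_base + np.abs(Za).mean(axis=0)
        return self.kl_weight * kl + self.psi * act


class LocalizationCostEvaluator:
    """Cost evaluator for the spatial-tracking task.

    The measurement is the (1-based) peak of the cross-correlation between
    the decoded image and the target template.  Because decoding is affine
    in the response, the correlation map is ``c0 + sum_n z_n * C_n`` with
    per-atom maps ``C_n`` precomputed once; per-coordinate perturbations
    update the map incrementally.  The inference error is the per-
    coordinate Gaussian symmetrized KL between the one-step posteriors of
    the thresholded and full branches, summed over x and y.
    """

    def __init__(
        self,
        S: np.ndarray,
        atom_corr: np.ndarray,  # (N, W*W) correlation map per atom
        base_corr: np.ndarray,  # (W*W,) map of the PCA mean
        prior_mean: np.ndarray,  # (2,) belief grid point
        prior_var: np.ndarray,  # (2,)
        sigma_m2: float,
        psi: float,
        W: int,
        alpha: float = DEFAULT_ALPHA,
        noise: np.ndarray | None = None,  # (n_mc, 2)
    ):
        self.S = np.asarray(S, dtype=float)
        self.atom_corr = atom_corr
        self.base_corr = base_corr
        self.prior_mean = np.asarray(prior_mean, dtype=float)
        self.prior_var = np.asarray(prior_var, dtype=float)
        self.sigma_m2 = float(sigma_m2)
        self.psi = float(psi)
        self.W = int(W)
        self.alpha = float(alpha)
        self.noise = (
            np.zeros((len(self.S), 2)) if noise is None else np.asarray(noise)
        )
        self._mu0, self._v = self._posterior(self._peaks(self._maps(self.S)))

    @property
    def n_params(self) -> int:
        return self.S.shape[1]

    def _maps(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.atom_corr + self.base_corr[None, :]

    def _peaks(self, maps: np.ndarray) -> np.ndarray:
        idx = np.argmax(np.round(maps, 9), axis=-1)
        r, c = np.divmod(idx, self.W)
        return np.stack([r + 1, c + 1], axis=-1).astype(float) + self.noise

    def _posterior(self, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v0 = self.prior_var
        mu = (self.sigma_m2 * self.prior_mean + v0 * m) / (v0 + self.sigma_m2)
        v = v0 * self.sigma_m2 / (v0 + self.sigma_m2)
        return mu, v

    def kl_of_means(self, mu: np.ndarray) -> np.ndarray:
        # both branches share the posterior variance, so the symmetrized
        # KL reduces to the squared mean gap over the variance, per axis
        return ((mu - self._mu0) ** 2 / self._v).sum(axis=-1)

    def cost(self, xi: np.ndarray) -> float:
        Z = shrink(self.S, xi[None, :], self.alpha)
        mu, _ = self._posterior(self._peaks(self._maps(Z)))
        kl = float(self.kl_of_means(mu).mean())
        return kl + self.psi * float(np.abs(Z).mean(axis=0).sum())

    def perturbed_costs(self, xi: np.ndarray, xi_alt: np.ndarray) -> np.ndarray:
        Z = shrink(self.S, xi[None, :], self.alpha)
        Za = shrink(self.S, xi_alt[None, :], self.alpha)
        maps = self._maps(Z)
        act_base = np.abs(Z).mean(axis=0)
        act_alt = np.abs(Za).mean(axis=0)
        out = np.empty(self.n_params)
        for n in range(self.n_params):
            pert = maps + (Za[:, n] - Z[:, n])[:, None] * self.atom_corr[n][None, :]
            mu, _ = self._posterior(self._peaks(pert))
            kl = float(self.kl_of_means(mu).mean())
            out[n] = kl + self.psi * (
                act_base.sum() - act_base[n] + act_alt[n]
            )
        return out


class RoiCostEvaluator:
    """Static region-of-interest compression objective.

    The static specialization of the inference-error cost: the divergence
    of the compressed reconstruction from the *full-code* reconstruction,
    summed over the ROI pixels and weighted like the sparse-coding
    reconstruction term (``1 / (2 sigma2)``), plus ``psi`` times the
    summed response magnitude.  At ``psi = 0`` the unique optimum is the
    unmodified sparse code, exactly as the dynamic cost is zero at
    ``xi = 0``.
    """

    def __init__(
        self,
        s: np.ndarray,
        roi_mask: np.ndarray,
        dictionary: Dictionary,
        psi: float,
        alpha: float = DEFAULT_ALPHA,
        sigma2: float = 0.5,
    ):
        self.s = np.asarray(s, dtype=float)
        mask = np.asarray(roi_mask, dtype=bool).ravel()
        if not mask.any():
            raise ValueError("ROI mask is empty")
        self.roi = np.flatnonzero(mask)
        self.basis_roi = dictionary.pixel_basis()[:, self.roi]  # (N, |roi|)
        self.psi = float(psi)
        self.alpha = float(alpha)
        self.sigma2 = float(sigma2)

    @property
    def n_params(self) -> int:
        return self.s.size

    def _err(self, z: np.ndarray) -> float:
        diff = (z - self.s) @ self.basis_roi
        return float(diff @ diff) / (2.0 * self.sigma2)

    def cost(self, xi: np.ndarray) -> float:
        z = shrink(self.s, xi, self.alpha)
        return self._err(z) + self.psi * float(np.abs(z).sum())

    def perturbed_costs(self, xi: np.ndarray, xi_alt: np.ndarray) -> np.ndarray:
        z = shrink(self.s, xi, self.alpha)
        za = shrink(self.s, xi_alt, self.alpha)
        base = (z - self.s) @ self.basis_roi
        resid = base[None, :] + (za - z)[:, None] * self.basis_roi
        err = (resid**2).sum(axis=1) / (2.0 * self.sigma2)
        act = np.abs(z).sum() - np.abs(z) + np.abs(za)
        return err + self.psi * act


# ---------------------------------------------------------------------------
# convenience wrappers over the evaluators
# ---------------------------------------------------------------------------

def symmetrized_kl_posteriors(xi: np.ndarray, evaluator) -> float:
    """Mean symmetrized KL between posteriors under ``z(xi)`` and ``z(0)``."""
    Z = shrink(evaluator.S, np.asarray(xi, dtype=float)[None, :], evaluator.alpha)
    if isinstance(evaluator, LocalizationCostEvaluator):
        mu, _ = evaluator._posterior(evaluator._peaks(evaluator._maps(Z)))
        return float(evaluator.kl_of_means(mu).mean())
    return evaluator.kl_term(Z)


def total_cost(xi: np.ndarray, evaluator) -> float:
    """Full cost: inference error plus ``psi`` times the expected activity."""
    return evaluator.cost(np.asarray(xi, dtype=float))


# ---------------------------------------------------------------------------
# Rprop optimization
# ---------------------------------------------------------------------------

def _numeric_gradient(evaluator, a: np.ndarray, delta: float) -> np.ndarray:
    """Central-difference gradient of the cost with respect to ``a`` (xi = a^2)."""
    xi = a * a
    cp = evaluator.perturbed_costs(xi, (a + delta) ** 2)
    cm = evaluator.perturbed_costs(xi, (a - delta) ** 2)
    return (cp - cm) / (2.0 * delta)


def optimize_thresholds(
    evaluator,
    cfg: OptimConfig,
    rng: np.random.Generator,
    a0: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Rprop search for the cost-minimizing threshold vector.

    Thresholds are optimized through the auxiliary variables ``a``
    (``xi = a^2``, so non-negativity is automatic) initialized with
    Gaussian noise.  Steps follow the sign of the numerical gradient with
    multiplicatively adapted per-coordinate step sizes; a candidate that
    raises the cost (or makes it non-finite) is rejected and the step
    sizes shrink, so the accepted cost trace is non-increasing.

    Returns ``(xi_star, cost_trace)``.
    """
    n = evaluator.n_params
    a = rng.normal(0.0, cfg.init_scale, size=n) if a0 is None else np.asarray(a0, float).copy()
    step = np.full(n, cfg.step_init)
    prev_grad = np.zeros(n)
    cost = evaluator.cost(a * a)
    trace = [cost]
    since_improve = 0
    for _ in range(cfg.max_iter):
        grad = _numeric_gradient(evaluator, a, cfg.fd_step)
        agree = grad * prev_grad
        step = np.where(agree > 0, np.minimum(step * cfg.eta_up, cfg.step_max), step)
        step = np.where(agree < 0, np.maximum(step * cfg.eta_down, cfg.step_min), step)
        grad_eff = np.where(agree < 0, 0.0, grad)  # iRprop-: skip after sign flip
        cand = a - np.sign(grad_eff) * step
        c_new = evaluator.cost(cand * cand)
        if not (np.isfinite(c_new) and c_new <= cost):
            # the joint step raised the cost.  Inference-error terms built
            # from discrete statistics (e.g. a correlation peak) have
            # cliffs invisible to local finite differences, so identify
            # the harmful coordinates by their exact single-coordinate
            # cost change and revert just those, shrinking their steps.
            marginal = evaluator.perturbed_costs(a * a, cand * cand)
            harmful = ~np.isfinite(marginal) | (marginal > cost)
            cand[harmful] = a[harmful]
            step[harmful] = np.maximum(step[harmful] * cfg.eta_down, cfg.step_min)
            prev_grad = np.where(harmful, 0.0, grad_eff)
            c_new = evaluator.cost(cand * cand)
            if not (np.isfinite(c_new) and c_new <= cost):
                # residual interactions: revert entirely and shrink
                moved = cand != a
                step[moved] = np.maximum(step[moved] * cfg.eta_down, cfg.step_min)
                cand = a.copy()
                c_new = cost
                prev_grad = np.zeros(n)
        else:
            prev_grad = grad_eff
        # absolute improvement test: a large constant divergence floor
        # (e.g. one unrecoverable training sample) must not mask real
        # progress on the activity term
        if cost - c_new > cfg.rel_tol:
            since_improve = 0
        else:
            since_improve += 1
        a = cand
        cost = c_new
        trace.append(cost)
        # rejected steps leave the cost flat, so convergence counts
        # iterations without material improvement, not raw flatness
        if since_improve >= cfg.tol_window:
            break
    xi = a * a
    # polish: zero out any threshold that does not pay its way.  This
    # collapses residual micro-thresholds exactly to 0 (in particular the
    # whole vector when psi = 0, where xi = 0 is the known optimum).
    for _ in range(2):
        marginal = evaluator.perturbed_costs(xi, np.zeros_like(xi))
        drop = (xi > 0) & (marginal <= cost + 1e-12)
        if not drop.any():
            break
        cand = np.where(drop, 0.0, xi)
        c_new = evaluator.cost(cand)
        if np.isfinite(c_new) and c_new <= cost:
            xi = cand
            cost = c_new
            trace.append(cost)
        else:
            break
    # the untouched sparse code is always a feasible solution; prefer it
    # on ties (restricted objectives can have whole valleys of
    # mutually-cancelling thresholds at the same cost)
    c_zero = evaluator.cost(np.zeros_like(xi))
    if np.isfinite(c_zero) and c_zero <= cost:
        xi = np.zeros_like(xi)
        trace.append(c_zero)
    return xi, trace


# ---------------------------------------------------------------------------
# threshold tables
# ---------------------------------------------------------------------------

def binary_belief_grid(k: int) -> np.ndarray:
    """``k`` linearly spaced belief values ``{1/k, 2/k, ..., 1}``."""
    return np.linspace(1.0 / k, 1.0, k)


def position_belief_grid(k_side: int, W: int) -> np.ndarray:
    """``k_side**2`` positions on a square grid linearly spaced in [1, W]."""
    axis = np.linspace(1.0, float(W), k_side)
    rr, cc = np.meshgrid(axis, axis, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def build_threshold_table(
    task,
    grid: np.ndarray,
    cfg: OptimConfig,
    seed: int = 0,
) -> ThresholdTable:
    """Optimize one threshold vector per belief-grid point.

    ``task`` must provide ``name``, ``n_neurons`` and
    ``evaluator_for_belief(point, n_mc, psi, alpha, rng)``, which draws the
    point's Monte-Carlo training set (mixture proportions for the binary
    tasks, Gaussian-scattered target positions for localization) and wraps
    it in a cost evaluator.  A failed per-point optimization marks the
    point invalid instead of aborting the table.
    """
    grid = np.asarray(grid, dtype=float)
    k = grid.shape[0]
    xi = np.zeros((k, task.n_neurons))
    valid = np.ones(k, dtype=bool)
    root = np.random.default_rng(seed)
    for i in range(k):
        rng = np.random.default_rng(root.integers(2**31))
        try:
            ev = task.evaluator_for_belief(grid[i], cfg.n_mc, cfg.psi, cfg.alpha, rng)
            xi[i], _ = optimize_thresholds(ev, cfg, rng)
        except Exception:
            valid[i] = False
    return ThresholdTable(
        task=task.name,
        grid=grid,
        xi=xi,
        valid=valid,
        meta={"psi": cfg.psi, "seed": seed, "n_mc": cfg.n_mc},
    )


def select_thresholds(table: ThresholdTable, belief) -> np.ndarray:
    """Look up the table entry closest to the current belief.

    Binary tasks: nearest grid probability by squared distance;
    localization: nearest grid position by squared Euclidean distance.
    Ties resolve to the lower index.
    """
    if table.grid.size == 0:
        raise ValueError("empty threshold table")
    if table.grid.ndim == 1:
        d = (table.grid - float(belief)) ** 2
    else:
        d = ((table.grid - np.asarray(belief, dtype=float)[None, :]) ** 2).sum(axis=1)
    return table.xi[int(np.argmin(d))]


# ---------------------------------------------------------------------------
# static ROI demonstration
# ---------------------------------------------------------------------------

def roi_compress(
    image: np.ndarray,
    roi_mask: np.ndarray,
    psi_list,
    dictionary: Dictionary,
    sparse_cfg,
    cfg: OptimConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """Sweep the resource constraint on a static region-of-interest task.

    For each ``psi``, optimizes the thresholds to reconstruct only the ROI
    pixels at minimal activity and reports the compressed code, its
    activity, and reconstruction SNRs inside and outside the ROI.  At
    ``psi = 0`` the optimum is the unmodified sparse code.
    """
    from .analysis import snr_db  # local import to avoid a cycle
    from .sparse import encode

    cfg = cfg or OptimConfig()
    flat_img = np.asarray(image, dtype=float)
    x_red = dictionary.pca.reduce(flat_img)
    s = encode(x_red, dictionary, sparse_cfg)
    results = []
    root = np.random.default_rng(seed)
    for psi in psi_list:
        rng = np.random.default_rng(root.integers(2**31))
        ev = RoiCostEvaluator(
            s, roi_mask, dictionary, psi, cfg.alpha, sparse_cfg.sigma2
        )
        xi, trace = optimize_thresholds(ev, cfg, rng)
        z = shrink(s, xi, cfg.alpha)
        from .sparse import decode

        recon = decode(z, dictionary)
        mask = np.asarray(roi_mask, dtype=bool)
        results.append(
            {
                "psi": float(psi),
                "xi": xi,
                "z": z,
                "recon": recon,
                "activity": float(np.abs(z).sum()),
                "snr_roi_db": snr_db(flat_img, recon, mask),
                "snr_full_db": snr_db(flat_img, recon),
                "snr_outside_db": snr_db(flat_img, recon, ~mask),
                "cost_trace": trace,
            }
        )
    return results
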