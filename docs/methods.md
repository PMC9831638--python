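# Methods

## Model overview

`adaptcode` couples two classical normative ingredients: a sparse coding
model of V1 and Bayesian online inference over a latent environmental
state. A population of `N` neurons with unit-norm features `φ_n`
(learned by SparseNet-style alternating minimization of reconstruction
error `Σ_i (x̂_i − x_i)² / (2σ²)` plus an `λ Σ|s_n|` activity penalty)
encodes standardized image patches. All encoding and decoding happens in
a PCA-reduced space of dimension `d`; pixel space is reached only through
the stored PCA map. Coefficients are inferred with FISTA on the exact ℓ1
objective (tolerance 1e-8 relative energy change or 500 iterations); the
problem is convex, so the code is the global optimum up to solver
tolerance.

Each activation passes through a smooth shrinkage nonlinearity with
per-neuron threshold `ξ_n ≥ 0` and smoothness `α = 10`. At `ξ = 0` the
map is the identity (enforced exactly in code); for large inputs it
approaches the soft-threshold asymptote `|s| − ξ`; raising `ξ` lowers the
neuron's effective gain (slope of a least-squares line through the I/O
curve over `s ∈ [0, 3]`, intercept unconstrained). Evaluation is
overflow-safe through a shifted log-sum-exp.

A perceptual observer infers the latent state from a scalar (or 2-D)
measurement of the response vector and sets the thresholds to minimize,
in expectation over the stimuli it predicts under its current belief,

    C(ξ) = κ · ⟨ D_KL^sym[ p(θ|z(ξ)) ‖ p(θ|z(0)) ] ⟩ + ψ · Σ_n ⟨|z_n(ξ_n)|⟩ ,

with attentional resource constraint `ψ = 4` throughout.

### Calibration of the inference-error term

The binary-task posterior divergence is a per-sample quantity of order
one (and bounded once posteriors are clipped to `[1e-12, 1 − 1e-12]`),
while the summed population activity is of order `N`. With `κ = 1` the
cost is dominated by the activity term at `ψ = 4` under every condition
we examined, and its global optimum is *total* suppression at every
belief — which destroys closed-loop inference and none of the framework's
phenomena survive. The package therefore weights the binary-task
divergence by the population size, `κ = N`, i.e. the inference error
competes against the population-*mean* activity. Under this calibration
`ψ = 4` produces the intended regime: strong but partial suppression,
deepest at confident beliefs and weakest at maximal uncertainty, with
closed-loop inference intact. The localization task needs no weight
(`κ = 1`): its Gaussian divergence with measurement noise σ_m = 1e-5 is
effectively a hard constraint on the decoded correlation peak, already
dominating the activity term whenever a peak moves. The static ROI
objective is naturally commensurate because its error term sums over ROI
pixels.

### Threshold optimization

Thresholds are optimized through real auxiliary variables `a` with
`ξ = a²` (non-negativity for free), initialized from `N(0, 0.1²)` — a
small initialization matters for the localization cost, where a larger
one already displaces marginal correlation peaks at iteration zero.
The gradient is estimated by central finite differences (step 1e-3 in
`a`); because the sparse codes are fixed during an optimization, a
single-coordinate perturbation only requires re-evaluating the pointwise
nonlinearity and the observer arithmetic, so a full gradient costs
O(N·n_mc) for the binary tasks and O(N·n_mc·W²) for localization (with
per-atom correlation maps precomputed once).

Steps follow resilient backpropagation (step factors 1.2 / 0.5, step
range [1e-6, 1], sign-flip gradient zeroing). Two departures from
textbook Rprop are load-bearing:

* **Per-coordinate backtracking.** The localization inference error is
  piecewise constant (the measurement is an argmax), so cost cliffs are
  invisible to finite differences and a single bad coordinate would
  poison every joint step. When a joint candidate raises the cost, the
  exact single-coordinate marginal costs identify the harmful
  coordinates; only those are reverted (and their steps shrunk). The
  accepted cost trace is non-increasing by construction.
* **Absolute convergence tolerance.** One unrecoverable training sample
  puts a large constant floor under the localization cost; a relative
  tolerance would then read genuine activity progress as convergence.
  Optimization stops after 15 iterations without an absolute improvement
  above 1e-6, or at 200 iterations.

A final polish pass zeroes any threshold whose removal does not raise
the cost and falls back to the untouched sparse code on ties — restricted
objectives can have whole valleys of mutually-cancelling thresholds at
equal cost, and the full code is the canonical representative (this also
makes the `ψ = 0` optimum exactly `ξ = 0`).

Monte-Carlo training sets are drawn once per belief point (common random
numbers, measurement-noise draws shared between the `z(ξ)` and `z(0)`
branches), so the cost is deterministic within an optimization and
exactly zero at `ξ = 0`.

### Belief grids and tables

Binary tasks discretize the belief into `k` linearly spaced values
`{1/k, …, 1}`; training priors are clipped to `[1e-3, 1 − 1e-3]` so the
endpoint entries stay responsive. Belief-point training sets mix the two
stimulus classes in proportion `p : (1 − p)`. Localization uses a square
position grid over `[1, W]`; each entry trains on backgrounds with the
cross scattered around the grid point with spread
`max(walk σ, W/4)` — the second term covers the grid's selection cell,
which at the scaled 3×3 grid is wider than the walk step. Online, the
entry nearest the current belief (squared distance, ties to the lower
index) is applied at the next step. The exact telegraph predictive
`(1 − h)·post + h·(1 − post)` is the default; the low-hazard shortcut
`predictive = posterior` is available behind a flag (at `h = 0.01` the
two differ by < 0.02).

## Tasks

* **Object detection** — latent state flips with hazard `h = 0.01`;
  present-state stimuli mix a procedural tree silhouette into the
  background at `γ = 0.2` and are re-standardized, so presence is carried
  by pattern correlation rather than an image-variance cue (this also
  keeps full-code activity flat across states). The silhouette is scaled
  ×3 on the standardized intensity scale — the same supra-threshold
  contrast as the cross target — giving measurement discriminability
  d′ ≈ 3–4; at unit contrast d′ ≈ 1 and single measurements carry almost
  no usable evidence. The measurement projects the decoded image on the
  template (noise variance 0.01); Gaussian class models are fitted on
  1,000 full-code measurements per state.
* **Target localization** — a 7×7 white cross (value +3) random-walks
  (σ = 1.2 or 2.4, reflected into `[1, W]`) over drifting movie frames;
  the measurement is the peak of the cross-correlation between the
  decoded image and the cross ("same"-size, zero padding, 1-based peak
  coordinates, lexicographic tie-break), with σ_m = 1e-5. The posterior
  is conjugate Gaussian per coordinate; the predicted measurement
  variance adds the walk variance.
* **Orientation estimation** — categories are discovered by k-means
  (k = 9) on log-ratio features `r_{n,t} = log(|s_{n,t}| / ⟨|s_n|⟩_t)`
  (zeros floored at 1e-6 of the maximum activation). Clusters are scored
  by the circular mean orientation (dominant Fourier angle per atom) of
  the neurons more active in the cluster than their corpus baseline; the
  clusters nearest 0° and 90° become H and V (manual override
  available). A Fisher discriminant on `|s|` features with ridge 0.1
  (the pools are small relative to `N`; a weakly regularized direction
  separates the training halves but collapses to chance on fresh draws)
  defines the measurement `m = |z|·d + ζ`, ζ of variance 1e-4. The
  corpus members of each category are split 50/50 into
  threshold-training and simulation pools to avoid leakage.

## Synthetic stimuli

The natural-image corpus is emulated by two generator families, both
standardized per patch to zero mean, unit variance:

* **Spectral** — Gaussian random fields with isotropic power spectrum
  `∝ f^{−2}` (exponent configurable). These match natural second-order
  statistics but are Gaussian: sparse coding on them converges to
  global, Fourier-like features with no spatial localization.
* **Dead leaves** (default for the pipeline) — occluding random disks
  with a power-law radius distribution. These carry the sparse edge and
  occlusion structure of natural scenes, and dictionary learning on them
  yields localized, oriented receptive fields (energy centroids spread
  across the patch, ~90% of atom energy in a quarter of the pixels) —
  the property the spatial-attention analyses rely on.

Movies are a single texture drifting on a torus (adjacent-frame
correlation > 0.5 at one pixel per frame). What passing tests on these
surrogates do *not* show: behavior under the full higher-order statistics
of natural movies (textures, shadows, object co-occurrence), chromatic
structure, or retinal preprocessing.

## Problem sizes

The default *scaled* profile runs the identical pipeline at 16×16
patches, `d = N = 128`, 8 belief bins / 3×3 position grid, and 300
Monte-Carlo images per belief point; the full-scale profile (32×32,
`d = N = 512`, 32 bins / 5×5 grid, 10⁴/10³ training images) is available
through `adaptcode.profiles.FULL`. The scaled geometry is harsher in
one respect: the 7×7 cross spans 44% of the patch width, so target
positions near the border clip most of the template and the correlation
peak becomes ambiguous there. Localization tracking is therefore
excellent in the typical case (median squared error 0) but shows rare
border excursions that dominate the *mean* error in both full and
adaptive modes; the high-uncertainty walk (σ = 2.4) is the default
simulation scenario. For the same reason the orientation-task gain
ensembles at this scale retain too few simultaneously active neurons for
the grating-mixture population fits and the Δ-preferred-orientation
noise-correlation flattening to be resolvable under simulated gains;
the analysis implementations are exercised on the full code and on
synthetic tuning-aligned gain fields instead.

## Numerical conventions

* Decoding SNR: `10·log10(Σ x² / Σ (x − x̂)²)` over the evaluated pixels
  (a power ratio); perfect reconstruction and zero signal return ±inf
  sentinels.
* Kurtosis: Pearson convention (Gaussian = 3); zero-variance pools give
  NaN.
* A neuron is *active* at `t` if `|z_{n,t}|` exceeds 1% of its own
  maximum over the trace; the same 1%-of-maximum rule (on mean activity)
  selects neurons for the gain-dynamics and grating-noise-correlation
  analyses.
* Uncertainty is the binary entropy of the prior in effect at each step;
  the uncertainty–activity association is reported as the Spearman
  correlation between the per-step decile index and the per-step summed
  activity (decile-aggregated means would amplify arbitrarily small
  systematic differences into large rank correlations).
* Correlations of zero-variance series are defined as 0 and flagged.
* Grating-mixture fits use Gaussians of fixed width σ = 0.35 on the
  orientation axis in radians (~20° tuning width), circular on the 180°
  ring; the component weights are solved by linear least squares.
* Probabilities entering divergences are clipped to
  `[1e-12, 1 − 1e-12]`; binary updates run in log space and never
  produce NaNs.

## Known limitations

* The `κ = N` calibration of the inference-error weight is a modeling
  choice, not a derived quantity; the qualitative regime is insensitive
  to factors of ~2 around it but not to orders of magnitude.
* Corner entries of the localization threshold table can degenerate to
  the full code (the clipped cross makes every suppression harmful).
* No spiking, transmission delays, or biophysical circuit model; the
  feedback cost (std of the threshold vector, charged on switches) is a
  proxy, not a mechanistic quantity.
* Threshold tables are precomputed per belief grid; there is no online
  per-step re-optimization.
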