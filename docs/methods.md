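# Methods

This note documents the statistical machinery in `windforay`: the
models and their assumptions, the estimator surrogates and their
numerical choices, what the synthetic generator does and does not
emulate, and the problem sizes the test-suite and acceptance script
use.

## Movement-type definitions

A GPS *fix* is one timestamped location of one tagged individual.
Fixes inside the individual's 95% home-range isopleth are short-range
movements (SRM). Contiguous runs of fixes outside the isopleth form
*excursion tracks*; complete tracks (flanked by inside fixes on both
sides) are clustered into medium-range (MRM) and long-range (LRM)
types, and their fixes inherit the track label. Labels therefore
partition all fixes — the bookkeeping identity `SRM + MRM + LRM =
total` is asserted on every run.

## Screening

Two rules, applied before home-range estimation: fixes lying outside
the coastline polygon **and** strictly more than 5 km from it are
removed (solar tags emit implausible offshore positions); individuals
whose tracking span is under 300 days are dropped so each retained bird
covers a full seasonal cycle. Duplicate (individual, timestamp) rows
collapse to the first occurrence, with counts logged. Both screens are
idempotent and never reorder fixes.

## Home range: autocorrelation-aware weighted KDE

Continuous-time movement-model kernel estimators (AKDE/wAKDE) are the
reference approach for tracking data; this package deliberately
implements a simplified, analytically testable surrogate that keeps the
two corrections those estimators exist for:

* **Serial autocorrelation.** The position autocorrelation timescale
  τ is estimated from the empirical ACF of the coordinate series over
  hourly lag bins up to 24 h, and the kernel bandwidth uses the
  effective sample size `n_eff = span / τ̂` (clamped to `[1, n]`)
  in the bivariate-Gaussian reference rule `h = sd · n_eff^(−1/6)`.
* **Irregular, daytime-only sampling.** Fixes carry trapezoid-in-time
  quadrature weights (half the gap to each temporal neighbour, capped
  at twice the median so overnight gaps cannot dominate), normalised to
  sum to one.

Two robustness choices matter in the excursion-contaminated mixture
that real (and simulated) data are:

* the ACF is computed from positions winsorised at 3 robust SDs, and
  the exponential fit profiles out a long-lag floor,
  `ρ(Δ) = (1−c)·e^(−Δ/τ) + c` with `c ∈ [0, 0.95]`. Excursion episodes
  induce long-lag correlation that otherwise inflates τ̂ several-fold;
* the bandwidth scale is the MAD-based robust SD rather than the plain
  SD, for the same reason. For Gaussian data both choices are
  equivalent to the textbook rule, which is what the closed-form
  checks exercise: on 10⁵ draws from N(0, σ²I) the 95% isopleth is a
  circle of radius `σ·√(2 ln 20) ≈ 2.448σ` and the estimated area is
  required to match `π(2.448σ)²` within 5%.

The density is evaluated by binning weighted fixes on a 0.5-km grid and
convolving with the Gaussian kernel; the isopleth threshold is the
largest density whose superlevel set holds ≥ 95% of mass, contoured by
marching squares (grid padded with zeros so contours close). If the ACF
carries no signal (independent positions), τ̂ falls back to the median
sampling interval with a warning — mirroring the weighted-estimator
convergence fallback such analyses report. Multiple isopleth patches
are allowed (two colonies); the pipeline additionally drops patches
holding under 5% of UD mass, because kernel contamination can sprout
sliver "islands" along repeatedly used excursion corridors that would
otherwise chop long excursions into fragments.

## Excursion metrics

Steps are consecutive-fix displacement vectors, prepended with the
virtual entry step from the last inside fix when one exists. The five
metrics: median step length (km); mean heading (degrees clockwise from
North; the circular mean is used because the circular median needs an
arbitrary tie-break — a circular-median option is available); maximum
Euclidean distance from the home-range polygon (zero on the boundary);
duration as elapsed clock time between first and last outside fix
(boundary crossings are not interpolated; at ~1-h fix intervals the
half-gap correction is sub-hour); and straightness = max distance /
total path length, clipped to (0, 1]. Tracks truncated by the data's
start or end are excluded from clustering (censored durations would
bias the duration-based split); their fixes are labelled by
nearest-cluster metrics when the track has ≥ 2 fixes, else SRM.

## PAM clustering

Features: z-scored {median step, max distance, duration, straightness}
plus heading encoded as (sin φ, cos φ)/√2, Euclidean dissimilarity.
The k-medoids search is BUILD (greedy cost-minimising medoid addition)
followed by steepest-descent SWAP, then deterministic perturbation
restarts: the descent is restarted from single-swap neighbours of the
incumbent (all of them for small n, the cost-ordered best four
otherwise) and from pair-swap neighbours for n ≤ 14, keeping the best
solution. Plain BUILD+SWAP stalls on a few percent of small
unstructured instances; with restarts the search matched exhaustive
enumeration on 5,000 random instances (n ≤ 10, k ≤ 3). Everything is
deterministic given the row order, with ties resolved to the lowest
index.

k = 2 is the pipeline default; diagnostics (total cost per k, mean
silhouette, and the Tibshirani gap statistic with uniform-over-range
reference sets and the usual one-standard-error rule) are computed for
k ∈ 2…8. The longer-median-duration cluster is LRM (ties break on
median max distance).

## Weather annotation

The weather grid is ERA5-like: hourly `u100`/`v100` wind components
(m/s at 100 m) and surface downward short-wave radiation flux (W/m²) on
a ~10-km lattice. Fixes join their nearest cell and nearest hour (ties
to the earlier hour); no interpolation, matching extraction at the
native scale. Speed converts to km/h for Beaufort-scale thresholds;
direction is the meteorological from-bearing. Calm air (u = v = 0) maps
to ψ = 0 with a flag — the choice is inert because the tensor smooth is
direction-inert at W = 0. Fixes outside grid coverage are flagged and
excluded from modeling, with counts logged.

## Ordered-categorical additive model

With y ∈ {SRM=1 < MRM=2 < LRM=3},

    P(y ≤ k | x) = σ(θ_k − η(x)),   θ₁ < θ₂,

a latent-logistic cumulative-logit model. η is additive: cyclic cubic
B-spline smooths (period 360° for wind direction, 365.25 d for day of
year and elapsed time since release — folded B-spline bases whose value
and first two derivatives match at the period seam), cubic regression
splines with exact second-derivative (curvature) penalties for
radiation, wind strength and age (curvature-penalized cubic splines
stand in for thin-plate splines; in one dimension the two are
near-equivalent and the B-spline basis is exactly reproducible),
a row-wise-Kronecker tensor product for direction × strength with one
smoothing parameter per margin, optional per-level smooths via `by=`
factors (the per-sex age effect), parametric factors, and per-individual
random intercepts as a ridge-penalized indicator block. Every smooth is
sum-to-zero constrained by a Householder null-space reparametrisation.

Identification: θ₁ ≡ −1 with a free intercept in η (any anchored cut
point is equivalent up to shift); θ₂ is estimated with the order
constraint enforced by step halving. Estimation is penalized Newton on
(β, θ₂) with analytic gradient and Hessian (verified against finite
differences in the tests), step-halving so the penalized log-likelihood
never decreases, convergence at relative change < 10⁻⁸ or 200
iterations. Smoothing parameters are selected by coordinate-wise grid
search on AIC = −2ℓ̂ + 2(EDF + 1), where per-term EDF is the trace of
the corresponding block of `(XᵀWX + P)⁻¹XᵀWX`; the default grid is 15
points on log₁₀λ ∈ [−3, 4] with one local refinement pass (the pipeline
uses a shorter 6-point grid for speed). The fit accepts frequency
weights, so the intercept-only calibration identity — fitted category
probabilities equal the empirical proportions, exactly the empirical
CDF MLE — can be checked on the published class counts
(157,770 / 7,408 / 3,024) with three weighted rows.

Prediction surfaces put other covariates at medians/modes and random
effects at zero; standard errors are delta-method on the probability
scale from the penalized observed information. Model comparison uses
AIC and LRTs for nested pairs with EDF-difference degrees of freedom;
under the null with an unpenalised 1-df term the LRT p-values are
uniform (checked by simulation).

## Gamma mixed model for LRM duration

One record per complete LRM track: duration (h), the median radiation
over the track's fixes and the age at track start (both z-scored with
table-level statistics stored for back-transformation), and release
cohort. The model is `duration ~ Gamma(shape ν, mean μ)`,
`log μ = xᵀβ + b_i`, `b_i ~ N(0, σ_b²)`, fitted by Laplace-approximated
ML: inner per-group Newton for the random-effect modes (independent
across groups, vectorised), outer Nelder–Mead with BFGS polish over
(β, log ν, log σ_b), initialised from the package's own Gamma-GLM
Newton fit. The σ_b → 0 boundary reproduces the fixed-effects GLM (and
that GLM matches the standard IRLS solution to ~10⁻⁶, cross-checked
against an independent implementation in the tests); an intercept-only
model recovers the sample mean exactly, the score identity of the
Gamma log link. The log link is chosen as the standard positive-support
link, consistent with a multiplicative radiation effect.

Stepwise-forward selection starts from the intercept, adds at each step
the term with the smallest LRT p-value below α = 0.05 (χ² df = number
of added parameters; df 1 for the random intercept, ignoring the
boundary correction, as is conventional), and considers the
radiation × age interaction only once both main effects are present.
With four candidate terms each gated at α = 0.05, the family-wise
probability of stopping at the intercept under the null is ≈ 0.95⁴ ≈
0.81; the per-candidate type-I rate is the controlled 5%, and that is
what the tests assert.

## Synthetic generator

The generator defines the study conditions for every recovery
experiment.

* **Routine movement**: exact-discretisation Ornstein–Uhlenbeck around
  the individual's colony (`τ = 2 h`, `σ = 8 km`; two colonies 25 km
  apart, birds alternating). Fixes are daytime-only (06:00–18:00) with
  intervals from a two-component normal mixture (means 60 and 117 min,
  weight 0.72 on the short component), reproducing solar-tag duty
  cycling; a bird in routine state at dusk resumes next morning from a
  colony-centred stationary draw.
* **Weather**: regime-switching mean flow between from-NW (315°,
  Mistral) and from-SE (135°, Sirocco) regimes with ~3-day Markov dwell
  times, AR(1) regime-wide speed (mean 4 m/s) plus spatially smoothed
  AR(1) local noise (SD 1.2 m/s; the smoothing attenuation is
  calibrated per grid so the target SD is grid-size independent);
  radiation is a clear-sky diurnal half-sine (peak 800 W/m²) times a
  clipped AR(1) cloud factor in [0, 1], zero at night.
* **Excursions**: initiated per routine fix with
  `logit p = a₀ + a₁g(ψ) + a₂h(W) + a₃R_norm`, where g has von Mises
  bumps at 315°/135°, h peaks at 1, 11 and 45 km/h and collapses above
  50 km/h, and R_norm is radiation scaled by the clear-sky peak
  (defaults a₀ = −6.8, a₁ = a₂ = 1.3, a₃ = 1). An excursion becomes
  long-range with probability increasing as radiation falls, provided
  enough daylight remains for a sustained outbound leg (starts after
  14:00 stay medium-range); LRM durations are Gamma with
  `mean = 30·e^(−0.5·R_norm)` h, so the ratio of mean durations between
  clear and dark initiation is exactly e^(−0.5). Outbound headings are
  downwind (ψ + 180°) with wide von Mises scatter (κ = 1.5 — wide
  rather than the sharply bimodal alternative, which would hand the
  clusterer a spurious direction split unrelated to movement type);
  transit speeds are 25 km/h (LRM) and 14 km/h (MRM), flight happens
  only in the daytime window, and seaward movement deflects along the
  north–south coastline instead of crossing it. Ground-truth labels
  mark excursion fixes beyond the 3σ generative core; transit fixes
  within the core stay SRM.

Defaults were calibrated once so the generated regime matches the study
structure: ~97% SRM fixes, medium-range tracks short and near the
boundary (a paper-like one-to-two labelled fixes per MRM track),
long-range tracks 15–25% of excursions with multi-day durations and
>100 km displacements. The 95% isopleth can only delimit the routine
core when routine fixes hold more than 95% of UD mass — an arithmetic
constraint of the isopleth definition worth remembering when comparing
with field data, where the SRM share was 93.8%.

**What the generator does not emulate**: altitude and uplift physics,
social attraction between birds, GPS measurement error, seasonal
radiation amplitude, habitat heterogeneity, multi-day storm systems
(cloud persistence is ~1–2 days, so within-track median radiation is
dominated by diurnal composition — longer tracks cover more middays —
and the pipeline-level duration-vs-radiation slope need not reproduce
the initiation-level effect), and tag-failure gaps longer than one
night. Passing recovery tests therefore show that the
estimators recover the encoded structure under these idealised
conditions, not that the field estimates themselves are correct.

A second, lighter generator (`simulate_ordinal_labels`) draws per-fix
labels *directly* from the cumulative-logit model whose latent
predictor is the generator's own effect surface, with covariates read
off the simulated weather grid. It exists because the full movement
simulation assigns one label to a whole excursion, so fix-level
weather–label association is diluted by everything that happens after
initiation — the same phenomenon that makes the field model's confusion
matrix collapse to the dominant class. Surface-shape and
radiation-effect recovery are therefore measured on direct draws
(conditionally independent labels, recoverable by construction), while
clustering recovery runs on the full movement simulation.

## Problem sizes

Unit and property tests run on 10²–10⁴-point examples (seconds).  The
recovery experiments use: clustering ARI — 10 seeds × 20 individuals ×
6 months (≈ 700–900 tracks per seed), asserting the 10-seed median ≥
0.8; weather-surface and radiation recovery — 10 seeds × 5,000 direct
label draws, asserting median peak offsets ≤ 30° and median partial-
effect correlation ≥ 0.9; duration-model recovery — 100 simulations at
n = 500 tracks for slope coverage and selection rates. The whole
acceptance script completes in roughly ten minutes on one CPU.

## Known limitations

* The home-range surrogate is not a continuous-time movement model; its
  τ̂ enters only through the bandwidth, and confidence intervals on
  home-range area are out of scope.
* EDF-based LRT p-values for penalized smooths are approximate;
  exact calibration is only claimed (and tested) for unpenalised terms.
* The Laplace approximation for the Gamma GLMM is accurate for the
  group sizes used here (tens of tracks per individual) but untested
  for single-observation groups.
* Modal-class prediction under heavy imbalance collapses to SRM; the
  ordinal model is informative through its probability surfaces, not
  through classification accuracy — by design, and consistent with the
  phenomenon it models.
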