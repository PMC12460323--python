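# Methods

`spatioepi` implements the analytical chain commonly applied to state-level
disease-incidence panels: global spatial autocorrelation, local hot-spot
detection, variance-partition factor analysis (GeoDetector), and a neural
spatiotemporal weighted regression (GTNNWR). This note records the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic benchmarks do and do not demonstrate.

## Data model

The panel is long-format: one record per (unit, year) with an incidence
outcome (age-standardized, per 10,000), a fixed set of continuous
covariates, and optional planar coordinates. Invariants enforced at
construction: unique (unit, year) pairs, finite outcomes, contiguous years
per unit, numeric complete covariates (missing covariate cells are rejected
rather than imputed — the analyses below have no principled way to absorb
imputation error). Temporal aggregation follows the five-year-interval
convention: a 30-year panel yields six window means per unit; whole-period
burden is exposed as both the sum and the mean of yearly values (sum is the
default "cumulative" operator). Years are calendar integers; the regression
time coordinate is the offset from the panel minimum, since only differences
enter any computation.

Spatial weights are binary contiguity (GAL neighbor lists, or queen/rook
contiguity derived from GeoJSON polygons with shapely; queen links any
shared boundary point, rook requires a shared edge, so queen is always a
superset). Row standardization rescales each unit's weights to sum to one;
islands keep zero rows with a warning rather than being dropped.

## Global Moran's I

    I = (N / S0) * Σ_ij w_ij (x_i - x̄)(x_j - x̄) / Σ_i (x_i - x̄)²

Inference uses the randomization-assumption variance by default (the
normality variance is available via `variance="normality"`), with
E[I] = −1/(N−1). Row-standardized weights are the default convention: they
make the spatial lag a neighbor average, and the perfect-checkerboard
identity I = −1 exact on a regular lattice. The significance rule flags
clustering when z > 2.58 (99% confidence), matching the reporting convention
of the studies this pipeline mirrors. A conditional permutation test
(pseudo-p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm)) provides
distribution-free inference; under iid null fields its 5% rejection rate is
calibrated within [0.03, 0.07] in the test suite.

## Getis-Ord Gi*

The self-inclusive local statistic: for each unit, the neighborhood sum
(w_ii = 1) is compared with its expectation under the global mean,

    z_i = (Σ_j w_ij x_j − x̄ W_i) / (S · sqrt[(N Σ_j w_ij² − W_i²)/(N−1)]),

with S the population standard deviation of x. Units are binned at the
two-sided thresholds 1.645 / 1.960 / 2.576 into 90/95/99% hot (z > 0) or
cold (z < 0) classes; no multiple-testing correction is applied by default
because the raw confidence classes are the reported semantics (an FDR
option would be a straightforward extension but changes the meaning of the
maps). Persistence across time windows is summarized by counting, per unit,
the windows classified hot or cold at each confidence level or better.

## GeoDetector

The factor detector measures spatial stratified heterogeneity:
q = 1 − SSW/SST, the share of outcome variance explained by a categorical
stratification (population variances; the ratio is invariant to the
convention, which a test asserts). Significance follows the canonical
noncentral-F test: F = [(N−L)/(L−1)]·q/(1−q) against F(L−1, N−L; λ) with
λ = [Σ_h ȳ_h² − (Σ_h √N_h ȳ_h)²/N]/σ². Null calibration (random strata) is
verified to reject at ≤ α + 2% for α ∈ {0.01, 0.05}.

Continuous covariates are discretized by four methods — equal interval,
geometric interval (edges in geometric progression; non-positive ranges are
shifted by 1 − min(x) before edge construction), natural breaks (an exact
Fisher dynamic program minimizing within-class squared deviation), and
quantile. The optimal (method, class count) pair maximizes q over a default
class range of 3–8; ties break deterministically toward fewer classes, then
by the method order above.

Interactions overlay two stratifications (cross-classification of observed
label pairs) and compare q12 with q1, q2: q12 > q1+q2 nonlinear
enhancement; q12 > max bilinear enhancement; q12 < min nonlinear weakening;
between min and max unilateral weakening. Exact equality q12 = q1 + q2
("independent") never holds in floating point, so |q12 − (q1+q2)| ≤ 0.01 is
classified independent, checked before the inequality rules. Note a
mathematical consequence of the overlay: the full cross-classification
refines both inputs, so q12 ≥ max(q1, q2) always (asserted on 200 random
pairs); weakening categories can only arise through the independence
tolerance or degenerate cell structures. Genuinely independent additive
drivers sit exactly on the q12 = q1 + q2 boundary; bilinear enhancement is
the signature of *correlated* drivers that share explanatory content.

The sensitivity analysis perturbs each covariate multiplicatively,
x′ = x·(1 + u), u ~ Uniform(−f, +f) with f = 0.10 by default, re-fits the
winning discretization's edges on the perturbed values (so classification
sensitivity propagates), and averages |q′ − q|/q over replicates (default
20). The result is compared with the 10% stability threshold conventional
in such assessments. Both the noise form (multiplicative vs additive) and
edge re-fitting are configurable, since descriptions of this procedure in the applied literature rarely pin them down.

## GTNNWR

Global OLS coefficients β^OLS are fitted on the training split only. For an
estimation point p_i (a unit-year record), spatial distances d_s (planar
Euclidean) and temporal distances d_t (absolute year offset) to every
training sample are min-max scaled by the training-vs-training bounds
(applied unchanged to validation/test: no leakage, scaled values may exceed
[0, 1]). The STPNN (2 → [3] → 1, leaky rectifier) fuses each (d_s, d_t)
pair into a learned proximity d_st; the SWNN maps the length-n_train vector
d_st(i, ·) to a weight vector w_i ∈ R^(p+1), one entry per coefficient
including the intercept (per-coefficient weights, so each covariate's
effect is modulated individually); the prediction is
ŷ_i = Σ_k w_ik β_k^OLS x_ik and the local coefficient surface is
β_ik = w_ik β_k^OLS.

Training minimizes NMSE = Σ(ŷ−y)² / (N·c²) with normalizer c = the training
outcome range by default (configurable to the mean or an explicit value;
NMSE/NRMSE normalization conventions vary across the literature and are rarely stated, so the
choice is exposed rather than asserted). Optimization is full-batch
Adadelta (lr 1.0, ρ 0.9) with MultiStepLR decay γ = 0.8 at epochs
{1000, 2000, 3000, 4000}, dropout 0.4 and batch normalization on SWNN
hidden layers, leaky-rectifier activations, He initialization. Validation
NMSE is monitored every epoch and the best-validation snapshot is restored
after training (hold-out early stopping; no k-fold). All randomness (split,
initialization, dropout) is seeded; runs are bit-reproducible on one
platform.

Two deliberate design choices matter for optimization quality:

* **Identity output initialization.** The SWNN output layer starts at
  zero weights and unit bias, so the untrained model *is* the global OLS
  model (w ≡ 1) and training learns departures from stationarity. Starting
  from random weights instead leaves Adadelta far from any useful basin and
  wastes most of the epoch budget recovering the stationary fit.
* **Desk-scale benchmark configuration.** The full-scale configuration is
  SWNN [512, 256, 64] with 15000 epochs; it remains the package default.
  The synthetic recovery benchmark, the demo pipeline, and the acceptance
  script use `GTNNWRConfig.desk_scale()` — SWNN [128, 64], 3000 epochs
  (the LR schedule is fully exercised by epoch 4000) — because the 48-unit
  × 30-year recovery problem does not need the full capacity and the
  narrower network trains in a few minutes on one CPU with no loss of
  recovery quality.

Metrics follow the usual suite: R², RMSE, MAE, MBE (mean bias), NRMSE and
NMAE (RMSE and MAE over the same normalizer c), and the NMSE loss itself,
reported per split.

## Synthetic generators

The generators define ground truth for every estimator:

* `make_grid_weights` — rook/queen lattice contiguity; the default 6×8
  lattice (48 units) × 30 years mirrors a contiguous-US state panel.
* `simulate_sar_field` — y = (I − ρW)⁻¹ε on row-standardized weights;
  ρ = 0 is exactly iid (null calibration), ρ near 1 gives strong clustering.
* `simulate_stratified_covariate` — constructs an outcome whose realized
  SSW/SST equals 1 − q exactly (residuals centered per stratum and rescaled
  against the between-stratum sum of squares), closing the loop with the
  q estimator to 1e-10. q = 1 forces zero residuals; requesting q = 1 with
  nonzero within-stratum noise is rejected as contradictory.
* `simulate_nonstationary_panel` — covariates iid standard Normal (a
  correlation option exists; benchmarks use the identity to isolate
  coefficient recovery), coefficient surfaces over (x, y, t), Gaussian
  noise. The benchmark surfaces are smooth linear ramps — intercept
  2 + 0.5·y/nrows − 0.3·t/T, slope β₁ = 1 + 0.5·x/ncols + 0.3·t/T, slope
  β₂ = 1 − 0.5·t/T — with noise sd 0.5.

What these emulate: spatially autocorrelated areal fields, stratified
heterogeneity with known explanatory power, smoothly drifting regression
relationships. What they do not: realistic covariate marginals or
cross-correlations, age-standardization artifacts, measurement error,
reporting discontinuities, or irregular state geometries. Passing the
benchmarks therefore demonstrates the estimators are implemented correctly
and can recover known structure at realistic problem sizes — not that any
particular substantive finding on real surveillance data would replicate.

## Numerical choices and degenerate inputs

* Zero-variance outcome fields are hard errors everywhere (Moran, Gi*, q).
* Single-stratum q is 0 by convention with a warning; zero SST is an error.
* Islands: retained with zero weight rows and a warning; Gi* computes their
  z from the self-term alone.
* Moran permutation p uses the +1 convention in both numerator and
  denominator (never exactly zero).
* Discretization drops empty classes and relabels; constant covariates are
  errors; Jenks falls back to the number of distinct values when fewer than
  the requested classes exist.
* Panel CSV IO uses 17-significant-digit formatting and round-trip float
  parsing so write → read is exact.
* Networks run in float32; reductions to OLS (w ≡ 1) are exact to float64
  rounding because forced weights bypass the network arithmetic.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo calibrations use 1000 replicates (Moran null mean, noncentral-F
rejection), 500 for generator clustering checks, 200 random pairs for
overlay monotonicity, 20 replicates for sensitivity averages. The recovery
benchmark is the full 6×8×30 panel (1440 records, 75/10/15 split with seed
48, 3000 epochs desk-scale). These sizes were chosen so each property is
measured with comfortable statistical margin while the whole chain remains
a desk-scale computation.

## Known limitations

* Coordinates are planar; great-circle distances are out of scope (users of
  real geographies should supply projected centroids).
* The GTNNWR weight surface is only identified up to the product
  w_ik β_k^OLS; coefficients for covariates whose OLS coefficient is near
  zero are correspondingly unstable.
* The noncentral-F significance test assumes the discretization was chosen
  independently of y; the optimal-discretization search optimizes q, so
  p-values after the search are optimistic (shared by standard GeoDetector
  practice).
* Full-batch training bounds the practical problem size to a few thousand
  records; mini-batching is not implemented.
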