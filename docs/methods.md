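# Methods

This note documents the models behind `stinterp`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices that matter for reproducing results.

## Data model and conventions

All methods consume an `STSeries`: a complete (gap-free) station × month
matrix of strictly positive concentrations in µg/m³ on a `StationGrid`.
Stations on a regular lon/lat lattice are numbered 1-based, row-major from
the north-west corner (on a 7×10 grid the corners are stations 1, 10, 61,
70; 5, 30, 31, 65 sit on edges).  Inputs that arrive on the kg/m³ scale
(values around 1e-8–1e-7) are converted by 1e9 with a logged warning.

Distances default to great-circle km (haversine, R = 6371 km) because the
study regions of interest span several degrees, where a degree of longitude
is materially shorter than a degree of latitude; plain Euclidean distance in
degree space is selectable for parity with projected workflows.  Time is an
integer month index 1..T with no calendar arithmetic; T is data-driven.

Validation design throughout is *station-omission LOOCV*: a station's whole
T-month series is withheld and re-predicted from the other n−1 stations.
This measures the question the methods exist to answer — skill at an
unobserved location — rather than one-step-ahead accuracy.

## IDW

ẑ(x₀) = Σ z(xᵢ)dᵢ⁻ᵝ / Σ dᵢ⁻ᵝ over all n−1 remaining stations (no
k-nearest cutoff; no neighborhood rule is imposed).  Spatial weights are
shared across time steps, so a station's full series is predicted in one
matrix product.  If a target coincides with a station, that station's value
is returned exactly (the β→limit of the formula; no epsilon hack).  β is
selected from the integer grid 1..10 by **pooled** LOOCV RMSE over all
stations × months (per-station metrics are reported separately); ties break
toward the smaller, smoother β.  Predictions are convex combinations:
weights are non-negative and sum to one, so predictions are bounded by the
neighbor range, and β→∞ recovers nearest-neighbor interpolation — all
asserted as properties in the test suite.

## Boundary-buffered spline smoothing (BSS)

Two interpolants are provided.  On a complete rectangular grid,
`interp_grid_bicubic` is the classical Hermite-form bicubic: per cell a
polynomial P(x,y) = Σᵢⱼ aᵢⱼxⁱyʲ (i,j ≤ 3), with node derivatives estimated
by centered finite differences (one-sided at the boundary), C¹ across cell
edges, exact at nodes, with the 16 monomial coefficients of any cell
recoverable through a fixed linear map (tested).  During LOOCV the retained
stations no longer form a complete grid, so scattered-data interpolation is
needed; `interp_scattered_cubic` uses the Clough–Tocher C¹ piecewise-cubic
on the Delaunay triangulation — the same smoothness class as the
triangulation-based bicubic schemes traditionally used for this task, but
fully specified and reproducible.  This substitution is deliberate: exact
reproduction of legacy patch polynomials is a non-goal; equivalence is at
the smoothness-class level.

Node gradients for the scattered interpolant are estimated **locally**
(Akima-style least-squares plane fits over each node's Delaunay neighbors)
rather than by the global smoothness functional, and the fits at real
stations ignore buffer nodes whenever three or more real neighbors give a
well-posed system.  This keeps the interpolant linear-precise in the grid
interior: off-plane buffer values cannot leak inward through the gradient
estimation, and a planar field is reproduced to rounding error at all
non-edge stations.

The buffer itself: one ring of synthetic points on the lattice extended by
one row/column per side (a 7×10 grid gains (9×12 − 70) = 38 points), offset
one grid spacing beyond the extent by default (configurable).  Each buffer
value is the arithmetic mean of its k nearest real stations, k = 3 by
default so that corner buffers draw on the three adjacent real stations;
nearest-neighbor ties break by station id.  Buffer values are recomputed
per time step and per LOOCV fold — the left-out station never contributes
to buffer means, which prevents information leakage from the validation
target into the training surface.  Buffer values are means of real values
and hence lie within the observed range; every real station is strictly
interior to the hull of real ∪ buffer points, which is precisely what
eliminates the corner/edge missing-value failures of unbuffered scattered
interpolation.

Because buffer means of a planar field do not lie on the plane, edge and
corner predictions carry a finite buffer-induced bias even for noise-free
planar data; interior stations are exact.  This asymmetry is intrinsic to
the mean-valued buffer and is visible in all reported error tables.

## Trend removal and the kriging pipeline (STK)

Kriging assumes a stationary, approximately Gaussian residual field, which
raw concentration data violate (strong right skew, outliers, seasonal and
spatial trend).  The pipeline escalates: test normality (pooled K–S against
a normal with sample moments) and homoscedasticity (slope of |residual| on
fitted values) → log₁₀ transform → linear-surface detrend → tensor-spline
detrend, applying each level only when the previous one fails at α = 0.05.
The K–S p-values here use estimated parameters and are therefore
anti-conservative (Lilliefors effect); they serve as a screening device,
consistent with common practice in this workflow.

The smooth trend Y(lon, lat, t) is a tensor-product penalized regression
spline: cubic B-spline marginals in lon, lat (k_space = 5 each) and time,
second-difference penalties per margin, two smoothing parameters (spatial,
temporal) selected by GCV on a log grid {1e-2, 1, 1e2, 1e4}.  The default
temporal basis uses a knot spacing of about 1.5 months (k_time ≈ 2T/3): a
monthly series with a 6-month seasonal cycle needs ≥4 knots per period, and
coarser bases (e.g. 20 functions over 88 months) cannot represent the cycle
at all, defeating the purpose of detrending.  An optional ridge-penalized
per-station intercept absorbs station-level offsets — a deliberately
light-weight stand-in for a mixed-model random intercept; full
variance-component inference is a non-goal.  In LOOCV the smoothing
parameters are selected once on the full data and the coefficients are
refit per fold via a rank-update of the normal equations (the estimator is
identical to a direct refit at fixed smoothing; tested).  The basis support
is pinned to the full grid extent so a fold's model can predict at its
held-out station.

Residuals are kriged under the separable space–time variogram

  γ_sep(h, τ) = sill · (γ̄ₛ(h) + γ̄ₜ(τ) − γ̄ₛ(h)·γ̄ₜ(τ)),

whose companion covariance factorizes, C(h, τ) = sill·ρₛ(h)·ρₜ(τ).  Each
standardized marginal γ̄ = n + (1−n)·g(lag/range) carries its own nugget
fraction; families are exponential, spherical, Gaussian and Matérn (ν fixed
at 1.5 by default; the correlation is (1+u)e^{−u} with u = lag/range).

The empirical space–time variogram bins ½(z(sᵢ,t) − z(sⱼ,t+τ))² by spatial
distance (8 bins to 75% of the maximum separation by default) and integer
temporal lag (0..6 months); same-station pairs populate the zero-distance
column, and the (0,0) cell is excluded.  Fitting is bounded multi-start
least squares over (sill, ranges, nuggets): range starts at {¼, ½, 1} × the
maximum lag (paired spatial/temporal starts), deterministic best-of-three.
Weights default to the Cressie/gstat form — pair counts divided by the
squared empirical semivariance — which stabilizes range estimation against
the noisy long-lag bins; plain pair-count and equal weighting are
selectable.  At the reference recovery experiment (exponential×exponential
GP on 7×10×88, ranges 200 km and 3 months) this fit recovers both ranges
within 30% and the sill within 25% in 8 of 10 seeds; single-realization
fluctuations of the empirical variogram, not optimizer failures, account
for the misses.

Prediction is ordinary kriging with the neighborhood "all stations × the
k_t = 5 nearest months": the weights solve [C 1; 1ᵀ 0][w; λ] = [c₀; 1] and
the variance is sill − wᵀc₀ − λ.  On a regular time grid the weight vector
depends only on the pattern of relative time offsets and is cached across
target months, which reduces a fold to a handful of ≤346² solves.  Singular
systems receive one diagonal jitter of 1e-10·sill, then error.  The
matrix diagonal is set to the full sill (zero separation of the same
observation), so kriging is exact at data points when nuggets are zero —
asserted to 1e-8 in the tests together with weight normalization and
non-negative variances.

Every spatial × temporal family pair (16 by default) is carried through the
whole LOOCV and the pair with the lowest pooled MSE on the log scale wins;
variogram-curve fit MSE is reported alongside.  Back-transformation
multiplies 10^(prediction) by the bias-correction factor 10^(σ²/2).  σ² is
the **prediction-error (kriging) variance** of the fold's kriged log
predictions, averaged over the fold (per-fold scope by default, global
selectable).  The alternative reading — the sample variance of the
predicted log *series* — is available as `sigma2_scope="series_fold"`, but
it inflates even noise-free predictions by the seasonal log-variance
(≈1.4% at the default amplitudes), so it is not the default.  The
conventional factor 10^(σ²/2) is used verbatim; the exact base-10 lognormal
mean correction 10^(ln10·σ²/2) sits behind `exact_correction=True`.

## Metrics and comparison

MAE, RMSE and MAPE (percent, 0–100 scale) plus NSE, KGE (with r, α, β
components; Pearson r and standard deviations use n−1 normalization) and
Willmott's dIndex are computed per station and aggregated as min / max /
average rows.  NaNs in inputs are errors, never dropped — the data contract
is gap-free.

Method comparison uses the Friedman rank test with stations as blocks (ties
averaged, standard tie correction; degenerate all-tied input returns
statistic 0, p = 1) and Nemenyi pairwise post-hoc p-values via the
studentized-range approximation with infinite degrees of freedom; exact
small-sample tables are out of scope.  Mean-error reductions between
methods are reported as 100·(mean_A − mean_B)/mean_A on per-station means.
Spatial autocorrelation of per-station mean LOOCV residuals uses Moran's I
and Geary's C with inverse-distance row-standardized weights (binary
k-nearest selectable) and two-sided permutation p-values (999 permutations,
seeded); under the permutation null E[I] = −1/(n−1) and C ≈ 1.

## Synthetic generator

`generate` produces value(s,t) = 10^(log₁₀ trend + GP) · outlier factor with
trend = base + gradient·(lon−lon̄, lat−lat̄) + amplitude·cos(2πt/period) and
GP a zero-mean Gaussian field with separable exponential space–time
correlation simulated exactly by Kronecker factorization of the space and
time Cholesky factors (O(n³+T³)).  The lognormal construction guarantees
positivity and the positive skew characteristic of concentration data;
outliers are injected multiplicatively on the raw scale.

Defaults (7×10 stations at 0.625°×0.5° spacing, 88 months): base 70 µg/m³,
gradient (3, 4) µg/m³/degree, seasonal amplitude 25 µg/m³ with a 6-month
period, log₁₀ variance 0.01 with spatial range 200 km, temporal range 1.5
months, nugget fraction 0.1, 1% outliers at ×1.3, seed 20240225.  These
were calibrated once so that per-station means (all 70) and skewness (67 of
70) fall inside the reference ranges for monthly PM2.5 station series
(means 36.49–119.36 µg/m³, skew 0.07–1.17) at the default seed.

Two named fixtures serve specific experiments.  `smooth_gradient_spec`
(strong (7,9) µg/m³/degree gradient, log-variance 0.002, 400 km range, no
nugget or outliers) is the regime where boundary handling decides skill:
deterministic structure dominates unpredictable noise, and the buffered
spline beats tuned IDW at mean, edge and corner stations.
`trend_recovery_spec` (default trend and total variance, nugget 0.9, ranges
60 km / 0.75 months) makes the noise predominantly iid so the trend is
identifiable; trend recovery is assessed there because spatially and
temporally smooth noise is statistically indistinguishable from trend and
is partly absorbed by *any* smoother — with the default smooth noise no
estimator reaches correlation 0.95 with the true trend, and reporting
recovery on an unidentifiable fixture would test the noise, not the code.

What the generator does not emulate: aerosol chemistry, dust-event
dynamics, non-separable or anisotropic covariance, trends in the seasonal
amplitude, and the spatial smoothness of true reanalysis output (which is
smoother than an exponential-correlation field).  Consequently, passing
tests demonstrate algorithmic correctness and the direction of
methodological effects — not the error magnitudes to expect on real
reanalysis extracts.  In particular, on the default synthetic field the
rough exponential noise at log-variance 0.01 favors the averaging methods:
RMSE-tuned IDW posts a slightly lower mean MAE than the exact-interpolating
buffered spline there, whereas on smooth fields (and on real reanalysis
data) the ordering reverses at the boundary, as the smooth-gradient fixture
shows.

## Numerical choices and degenerate inputs

- Lattice detection requires exact row/column structure to 1e-9 degrees;
  irregular layouts are accepted but flagged, and grid-dependent methods
  (buffering) refuse them.
- Constant series: skew/kurtosis reported as NaN; KGE/NSE/dIndex raise on
  their documented degenerate denominators; the Friedman test returns
  (0, 1) on all-tied blocks instead of raising.
- B-spline evaluation clamps query coordinates to the basis domain (the
  domain always covers the full grid, so this only guards rounding).
- All stochastic operations take explicit seeds; LOOCV, fitting and kriging
  are deterministic given their inputs.  Benchmark reports are
  byte-reproducible for a fixed seed.
- Problem sizes in the test and acceptance runs — 70×88 for full-workflow
  checks, 4×5×24 to 5×6×36 for pipeline unit tests, 10 seeds for variogram
  recovery, 50 seeds for the residual-normality screen — were chosen as the
  smallest sizes at which the corresponding statistical properties are
  stable.

## Known limitations

- Only the separable covariance class is implemented; product-sum, metric
  and sum-metric classes, anisotropy, and Bayesian variogram selection are
  out of scope.
- The buffer uses unweighted k-nearest means; distance-weighted or
  trend-informed buffer values are noted as refinements, not implemented.
- The per-station random intercept is ridge shrinkage, not a mixed model:
  no variance-component standard errors or nested random slopes.
- The K–S normality screen with estimated parameters overstates p-values;
  treat it as a gate, not a test with calibrated size.
- MAPE requires strictly positive observations (guaranteed by the data
  contract).
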