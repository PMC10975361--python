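# stinterp

Spatio-temporal interpolation of monthly pollutant-concentration series
observed on a regular station grid — with a honest answer to the question
every such workflow faces: *how well would we have predicted a station we
never observed?*

The package is built around station-omission leave-one-out cross-validation
(LOOCV): each station's **entire** monthly series is removed in turn and
re-predicted from the remaining stations.  Three interpolation methods are
implemented and compared on equal footing:

- **IDW** — inverse distance weighting,
  ẑ(x₀) = Σᵢ z(xᵢ) dᵢ⁻ᵝ / Σᵢ dᵢ⁻ᵝ, with the power parameter β selected on a
  grid (default 1…10) by pooled LOOCV RMSE.
- **BSS** — bicubic spline smoothing with a **boundary buffer**: scattered
  C¹ piecewise-cubic (Clough–Tocher) interpolation fails at grid corners
  during LOOCV because the left-out corner falls outside the convex hull of
  the rest.  One ring of synthetic perimeter points, valued by the mean of
  their k nearest real stations, converts that extrapolation into
  interpolation and yields finite predictions at all stations.
- **STK** — spatio-temporal ordinary kriging of detrended log₁₀ residuals
  under the separable variogram
  γ(h, τ) = sill · (γ̄ₛ(h) + γ̄ₜ(τ) − γ̄ₛ(h)·γ̄ₜ(τ)),
  with exponential / spherical / Gaussian / Matérn marginals fitted by
  weighted least squares, family pairs selected by lowest pooled LOOCV MSE,
  and predictions returned to concentration units with the lognormal bias
  correction 10^(σ²/2).

Around the methods sit the full evaluation harness — MAE/RMSE/MAPE,
Nash–Sutcliffe (NSE), Kling–Gupta (KGE) and Willmott's index of agreement
(dIndex) per station with min/max/average summaries; Friedman + Nemenyi
rank tests across methods; Moran's I and Geary's C on LOOCV residuals —
and a calibrated synthetic-field generator, so the whole toolkit runs and
tests without any external data download.

## Worked example

```python
from stinterp import SyntheticSpec, generate, optimize_beta

series = generate(SyntheticSpec())   # 70 stations x 88 months, µg/m³
result = optimize_beta(series)
print(result.table.round(3))
print("optimal beta =", result.beta)
```

prints (pooled LOOCV errors over all 70 × 88 predictions):

```
         mae    rmse    mape
beta
1     10.576  13.768  15.229
2      9.057  11.896  12.851
3      8.390  11.130  11.746
4      8.226  10.964  11.444
5      8.223  10.984  11.407
...
optimal beta = 4
```

RMSE is the selection criterion: β=4 gives the lowest pooled RMSE
(10.96 µg/m³, i.e. roughly 11% MAPE on this field), a sharper distance
decay than the classical inverse-squared-distance β=2.  The full
three-method comparison on the same field (`examples/05_method_comparison.py`)
adds Friedman/Nemenyi significance tests and residual autocorrelation
checks:

```
 idw: mean MAE 8.10  RMSE 10.62  MAPE 11.62%
 bss: mean MAE 8.66  RMSE 11.42  MAPE 12.30%
 stk: mean MAE 8.67  RMSE 11.34  MAPE 12.54%
Friedman p (MAE) = 0.000591
   idw: Moran's I = -0.045 (p=0.680, E[I]=-0.034) ...
```

Moran's I near its null expectation −1/(n−1) and Geary's C near 1 say the
LOOCV residuals carry no spatial structure — the errors reflect the methods,
not a spatial pattern left in the data.

Each script in `examples/` is a short, self-contained walk through one
capability (simulation + EDA, β search, boundary buffering, the kriging
pipeline, the statistical comparison).  A thin command-line interface mirrors
the library (`stinterp simulate | eda | idw | bss | stk | benchmark`); run
`stinterp --help` after installing.

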