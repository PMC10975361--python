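"""Spatio-temporal kriging of detrended log residuals.

The observed log10 field decomposes as Z(s, t) = Y(s, t) + ε(s, t): a smooth
deterministic trend plus a stationary stochastic residual.  The residual is
kriged under a *separable* space–time variogram

    γ_sep(h, τ) = sill · ( γ̄_s(h) + γ̄_t(τ) − γ̄_s(h) · γ̄_t(τ) ),

where γ̄_s and γ̄_t are standardized (unit-sill) marginal variograms with
their own nugget fractions, so the companion covariance factorizes as
C(h, τ) = sill · ρ_s(h) · ρ_t(τ).  Four marginal families are available
(exponential, spherical, Gaussian, Matérn); every spatial × temporal family
pair is fitted to the empirical space–time variogram by pair-count-weighted
least squares and the pair with the lowest pooled LOOCV MSE on the log scale
is kept.

Predictions at a left-out station are ordinary-kriging combinations of the
residuals at the remaining stations over the nearest time slices; the trend
is added back and the result is returned to concentration units with the
lognormal bias correction 10^(σ²/2), σ² being the variance of the predicted
log series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn, kv

from .core import (
    GREAT_CIRCLE,
    DistanceConvention,
    FoldResult,
    STSeries,
    pairwise_distance,
)
from .trend import TensorTrendFolds, TrendModel, data_domain, fit_trend, log10_transform

FAMILIES = ("exponential", "spherical", "gaussian", "matern")


# ---------------------------------------------------------------------------
# Variogram models
# ---------------------------------------------------------------------------

def _structure(family: str, u: np.ndarray, nu: float) -> np.ndarray:
    """Unit-sill, nugget-free variogram structure g(u), u = lag / range."""
    u = np.asarray(u, float)
    if family == "exponential":
        return 1.0 - np.exp(-u)
    if family == "gaussian":
        return 1.0 - np.exp(-(u**2))
    if family == "spherical":
        uc = np.minimum(u, 1.0)
        return 1.5 * uc - 0.5 * uc**3
    if family == "matern":
        out = np.ones_like(u)
        pos = u > 0
        up = u[pos]
        rho = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * (up**nu) * kv(nu, up)
        out[pos] = 1.0 - rho
        out[~pos] = 0.0
        return np.clip(out, 0.0, 1.0)
    raise ValueError(f"unknown variogram family {family!r}")


@dataclass(frozen=True)
class MarginalVariogram:
    """Standardized marginal variogram: γ̄(lag) = n + (1−n)·g(lag/range),
    rising from the nugget fraction at zero lag to 1 at infinity."""

    family: str
    range_: float
    nugget_fraction: float = 0.0
    nu: float = 1.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.range_ <= 0:
            raise ValueError("range must be positive")
        if not 0.0 <= self.nugget_fraction < 1.0:
            raise ValueError("nugget fraction must lie in [0, 1)")

    def gamma_bar(self, lag) -> np.ndarray:
        lag = np.asarray(lag, float)
        if (lag < 0).any():
            raise ValueError("negative lag")
        return self.nugget_fraction + (1.0 - self.nugget_fraction) * _structure(
            self.family, lag / self.range_, self.nu
        )

    def correlation(self, lag) -> np.ndarray:
        """ρ(lag) = 1 − γ̄(lag); note ρ(0) = 1 − nugget_fraction."""
        return 1.0 - self.gamma_bar(lag)


@dataclass(frozen=True)
class SeparableVariogram:
    sill: float
    spatial: MarginalVariogram
    temporal: MarginalVariogram

    def gamma(self, h, tau) -> np.ndarray:
        gs = self.spatial.gamma_bar(h)
        gt = self.temporal.gamma_bar(tau)
        return self.sill * (gs + gt - gs * gt)

    def covariance(self, h, tau) -> np.ndarray:
        """C(h, τ) = sill − γ_sep(h, τ) = sill·ρ_s(h)·ρ_t(τ)."""
        return self.sill - self.gamma(h, tau)


def eval_separable(model: SeparableVariogram, h, tau) -> np.ndarray:
    return model.gamma(h, tau)


# ---------------------------------------------------------------------------
# Empirical space-time variogram
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalSTVariogram:
    """Binned semivariances γ̂(h_bin, τ).  Row 0 is the zero-distance bin
    (same-station pairs at temporal lags), so cell (0, 0) is excluded."""

    bin_centers: np.ndarray  # (n_bins,), bin 0 = zero spatial distance
    bin_edges: np.ndarray
    tlags: np.ndarray
    gamma: np.ndarray  # (n_bins, n_tlags); NaN where a bin is empty
    counts: np.ndarray

    @property
    def max_h(self) -> float:
        return float(self.bin_edges[-1])

    @property
    def max_tlag(self) -> int:
        return int(self.tlags[-1])


def empirical_st_variogram(
    residuals: STSeries,
    n_spatial_bins: int = 8,
    max_h: float | None = None,
    max_tlag: int = 6,
    convention: DistanceConvention = GREAT_CIRCLE,
) -> EmpiricalSTVariogram:
    """γ̂(h, τ) = mean of ½(z(sᵢ, t) − z(sⱼ, t+τ))² over station pairs in the
    distance bin and all valid months; pair counts are reported and later
    serve as weights in model fitting."""
    Z = residuals.values
    n, T = Z.shape
    if n < 2 or T < 2:
        raise ValueError("need at least 2 stations and 2 time steps")
    D = pairwise_distance(residuals.grid, convention)
    offdiag = ~np.eye(n, dtype=bool)
    if max_h is None:
        max_h = 0.75 * D[offdiag].max()
    edges = np.linspace(0.0, max_h, n_spatial_bins + 1)
    # spatial bin index per ordered station pair; bin 0 reserved for i == j
    idx = np.searchsorted(edges, D, side="right")  # 1..n_bins for d <= max_h
    idx[~offdiag] = 0
    idx[D > max_h] = -1  # beyond max distance: discarded
    max_tlag = min(max_tlag, T - 1)
    tlags = np.arange(max_tlag + 1)
    n_bins = n_spatial_bins + 1
    gsum = np.zeros((n_bins, tlags.size))
    gcnt = np.zeros((n_bins, tlags.size))
    for tl in tlags:
        m = T - tl
        A = Z[:, : T - tl] if tl else Z
        B = Z[:, tl:] if tl else Z
        # G[i, j] = mean_t (z_i,t − z_j,t+tl)² / 2 over ordered pairs
        G = 0.5 * (
            (A**2).mean(axis=1)[:, None]
            + (B**2).mean(axis=1)[None, :]
            - 2.0 * (A @ B.T) / m
        )
        for b in range(n_bins):
            sel = idx == b
            if tl == 0 and b == 0:
                continue  # (0, 0) excluded
            if tl == 0:
                sel = sel & offdiag
            if sel.any():
                gsum[b, tl] += G[sel].sum() * m
                gcnt[b, tl] += sel.sum() * m
    with np.errstate(invalid="ignore"):
        gam = np.where(gcnt > 0, gsum / np.maximum(gcnt, 1), np.nan)
    centers = np.r_[0.0, 0.5 * (edges[:-1] + edges[1:])]
    return EmpiricalSTVariogram(centers, edges, tlags, gam, gcnt)


# ---------------------------------------------------------------------------
# Separable model fitting
# ---------------------------------------------------------------------------

@dataclass
class SeparableFit:
    model: SeparableVariogram
    mse: float  # pair-count-weighted fit MSE against the empirical surface


def fit_separable(
    emp: EmpiricalSTVariogram,
    spatial_family: str = "exponential",
    temporal_family: str = "exponential",
    nu: float = 1.5,
    weights: str = "cressie",
    range_starts=(0.25, 0.5, 1.0),
) -> SeparableFit:
    """Weighted least-squares fit of (sill, ranges, nuggets) to the empirical
    space–time variogram.

    ``weights``: "cressie" (default; pair counts divided by the squared
    empirical semivariance, the gstat-style approximation to the sampling
    variance of each bin), "pair_counts", or "equal".  Multi-start bounded
    optimization: spatial and temporal range starts at {¼, ½, 1} × the
    maximum lag; the best weighted-MSE solution is kept, so the result is
    deterministic.
    """
    valid = np.isfinite(emp.gamma) & (emp.counts > 0)
    if valid.sum() < 4:
        raise ValueError("need at least 4 non-empty variogram bins")
    H = np.broadcast_to(emp.bin_centers[:, None], emp.gamma.shape)[valid]
    TAU = np.broadcast_to(emp.tlags[None, :], emp.gamma.shape)[valid].astype(float)
    G = emp.gamma[valid]
    if weights == "cressie":
        W = emp.counts[valid] / np.maximum(G, 1e-12) ** 2
    elif weights == "pair_counts":
        W = emp.counts[valid]
    elif weights == "equal":
        W = np.ones(G.size)
    else:
        raise ValueError(f"unknown weights mode {weights!r}")
    W = W / W.sum()
    sw = np.sqrt(W)
    max_h = max(emp.max_h, 1e-9)
    max_t = max(float(emp.max_tlag), 1.0)
    sill0 = float(np.average(G, weights=W))

    def resid(theta):
        sill, rs, rt, ns, nt = theta
        m = SeparableVariogram(
            sill,
            MarginalVariogram(spatial_family, rs, ns, nu),
            MarginalVariogram(temporal_family, rt, nt, nu),
        )
        return sw * (m.gamma(H, TAU) - G)

    lb = [1e-12, 1e-4 * max_h, 1e-4 * max_t, 0.0, 0.0]
    ub = [np.inf, 20.0 * max_h, 20.0 * max_t, 0.95, 0.95]
    best = None
    for cs in range_starts:
        x0 = [max(sill0, 1e-10), cs * max_h, cs * max_t, 0.05, 0.05]
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-10)
        except Exception:
            continue
        mse = float(np.sum(sol.fun**2))
        if best is None or mse < best[0]:
            best = (mse, sol.x)
    if best is None:
        raise RuntimeError("separable variogram fit failed to converge from all starts")
    mse, (sill, rs, rt, ns, nt) = best
    model = SeparableVariogram(
        float(sill),
        MarginalVariogram(spatial_family, float(rs), float(ns), nu),
        MarginalVariogram(temporal_family, float(rt), float(nt), nu),
    )
    return SeparableFit(model, mse)


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

def _solve_ok(C: np.ndarray, c0: np.ndarray, sill: float):
    m = C.shape[0]
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = C
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    b = np.r_[c0, 1.0]
    try:
        sol = np.linalg.solve(A, b)
        if not np.isfinite(sol).all():
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        A[:m, :m] += np.eye(m) * (1e-10 * sill)
        sol = np.linalg.solve(A, b)
        if not np.isfinite(sol).all():
            raise
    return sol[:m], sol[m]


def krige(
    residuals: STSeries,
    model: SeparableVariogram,
    target_lon: float,
    target_lat: float,
    times: np.ndarray | None = None,
    k_t: int = 5,
    convention: DistanceConvention = GREAT_CIRCLE,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging of the residual field at one location.

    The neighborhood is all data stations × the ``k_t`` nearest time slices
    of each target time.  Weights solve [C 1; 1ᵀ 0][w; λ] = [c0; 1] with C
    the separable covariance; the prediction is wᵀz and the kriging variance
    sill − wᵀc0 − λ.  Because the time grid is regular, the weight vector
    depends only on the pattern of relative time offsets and is cached
    across target times.
    """
    Z = residuals.values
    n, T = Z.shape
    if times is None:
        times = residuals.time_index
    times = np.atleast_1d(np.asarray(times))
    tpos = np.searchsorted(residuals.time_index, times)
    if (tpos >= residuals.time_index.size).any() or not np.array_equal(
        residuals.time_index[np.minimum(tpos, residuals.time_index.size - 1)], times
    ):
        raise ValueError("target times must lie on the data time grid")
    k_t = min(k_t, T)
    d0 = convention.pairwise([target_lon], [target_lat],
                             residuals.grid.lon, residuals.grid.lat)[0]
    D = pairwise_distance(residuals.grid, convention)
    sill = model.sill
    Rs = model.spatial.correlation(D)
    np.fill_diagonal(Rs, 1.0)  # zero separation of the same station
    rs0 = model.spatial.correlation(d0)

    preds = np.empty(times.size)
    variances = np.empty(times.size)
    cache: dict = {}
    tgrid = residuals.time_index.astype(float)
    # relative-offset caching is only valid on an equally spaced time grid
    regular_t = tgrid.size < 2 or np.ptp(np.diff(tgrid)) < 1e-12
    for out_i, tp in enumerate(tpos):
        # k_t nearest time slices (ties toward earlier months)
        order = np.lexsort((tgrid, np.abs(tgrid - tgrid[tp])))
        window = np.sort(order[:k_t])
        offsets = window - tp
        key = tuple(offsets.tolist()) if regular_t else (int(tp), tuple(window.tolist()))
        if key not in cache:
            dt = np.abs(tgrid[window][:, None] - tgrid[window][None, :])
            Rt = model.temporal.correlation(dt)
            np.fill_diagonal(Rt, 1.0)
            rt0 = model.temporal.correlation(np.abs(tgrid[window] - tgrid[tp]))
            C = sill * np.kron(Rs, Rt)
            c0 = sill * np.kron(rs0, rt0)
            w, lam = _solve_ok(C, c0, sill)
            cache[key] = (w, lam, c0)
        w, lam, c0 = cache[key]
        z = Z[:, window].ravel()
        preds[out_i] = w @ z
        variances[out_i] = sill - w @ c0 - lam
    return preds, variances


# ---------------------------------------------------------------------------
# Back-transformation
# ---------------------------------------------------------------------------

def back_transform(pred_log: np.ndarray, sigma2: float, exact: bool = False) -> np.ndarray:
    """Return log10-scale predictions to concentration units with the
    lognormal bias correction 10^(σ²/2).

    ``exact=True`` uses the exact base-10 lognormal mean correction
    10^(ln(10)·σ²/2) instead of the conventional 10^(σ²/2).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    exponent = (np.log(10.0) * sigma2 / 2.0) if exact else (sigma2 / 2.0)
    return 10.0 ** np.asarray(pred_log, float) * 10.0**exponent


# ---------------------------------------------------------------------------
# Full LOOCV pipeline
# ---------------------------------------------------------------------------

@dataclass
class STKResult:
    folds: list[FoldResult]  # concentration scale, winning family pair
    folds_log: list[FoldResult]  # log10 scale
    selected_pair: tuple[str, str]
    selection_table: pd.DataFrame  # pooled log-scale LOOCV MSE per family pair
    variogram_fits: list  # per-fold SeparableFit of the winning pair
    trend_kind: str


def stk_loocv(
    series: STSeries,
    families=FAMILIES,
    trend_kind: str = "tensor_spline",
    trend_options: dict | None = None,
    k_t: int = 5,
    n_spatial_bins: int = 8,
    max_tlag: int = 6,
    convention: DistanceConvention = GREAT_CIRCLE,
    refit_trend: bool = True,
    sigma2_scope: str = "fold",
    exact_correction: bool = False,
    family_pairs: list[tuple[str, str]] | None = None,
) -> STKResult:
    """Station-omission LOOCV for spatio-temporal kriging.

    Per fold: log10 → trend fit on the n−1 retained stations → empirical
    variogram of their residuals → separable fit for every candidate
    spatial × temporal family pair → kriging of residuals at the left-out
    station → trend added back → bias-corrected back-transform.  The family
    pair with the lowest pooled LOOCV MSE on the log scale is selected.

    Smoothing parameters of the tensor-spline trend are chosen once by GCV
    on the full data and held fixed while coefficients are refit per fold
    (``refit_trend=False`` reuses the full-data fit outright).
    """
    if series.n_stations < 5:
        raise ValueError("LOOCV needs at least 5 stations")
    trend_options = dict(trend_options or {})
    if family_pairs is None:
        family_pairs = [(sf, tf) for sf in families for tf in families]
    slog = log10_transform(series)
    domain = data_domain(slog)
    trend_options.setdefault("domain", domain)

    folds_engine = None
    full_fit = None
    if trend_kind == "tensor_spline":
        if refit_trend:
            folds_engine = TensorTrendFolds(
                slog,
                k_space=trend_options.get("k_space", 5),
                k_time=trend_options.get("k_time"),
                lambdas=trend_options.get("lambdas"),
                domain=domain,
            )
        else:
            full_fit = fit_trend(slog, kind="tensor_spline", **trend_options)

    n = series.n_stations
    pred_log = {pair: np.empty((n, series.n_times)) for pair in family_pairs}
    pred_var = {pair: np.empty((n, series.n_times)) for pair in family_pairs}
    fold_fits: dict = {pair: [] for pair in family_pairs}
    fit_mse_sum = {pair: 0.0 for pair in family_pairs}

    for k in range(n):
        rest = slog.drop_station(k)
        mask = np.arange(n) != k
        if trend_kind == "tensor_spline" and not refit_trend:
            model_k = full_fit
            resid_values = rest.values - full_fit.fitted[mask]
        elif trend_kind == "tensor_spline":
            model_k = folds_engine.fold(k)
            resid_values = model_k.residual
        else:
            model_k = fit_trend(rest, kind=trend_kind, domain=domain)
            resid_values = model_k.residual
        resid_rest = STSeries(rest.grid, resid_values, slog.time_index)
        emp = empirical_st_variogram(
            resid_rest, n_spatial_bins=n_spatial_bins, max_tlag=max_tlag,
            convention=convention,
        )
        trend_at_k = model_k.predict(
            series.grid.lon[k], series.grid.lat[k], slog.time_index
        )
        for pair in family_pairs:
            fit = fit_separable(emp, pair[0], pair[1])
            kr, kv = krige(
                resid_rest, fit.model,
                series.grid.lon[k], series.grid.lat[k],
                k_t=k_t, convention=convention,
            )
            pred_log[pair][k] = trend_at_k + kr
            pred_var[pair][k] = kv
            fold_fits[pair].append(fit)
            fit_mse_sum[pair] += fit.mse

    rows = []
    for pair in family_pairs:
        mse = float(np.mean((pred_log[pair] - slog.values) ** 2))
        rows.append(
            {
                "spatial_family": pair[0],
                "temporal_family": pair[1],
                "loocv_mse_log": mse,
                "variogram_fit_mse": fit_mse_sum[pair] / n,
            }
        )
    table = pd.DataFrame(rows).sort_values("loocv_mse_log").reset_index(drop=True)
    winner = (table.loc[0, "spatial_family"], table.loc[0, "temporal_family"])

    folds, folds_log = [], []
    for k in range(n):
        plog = pred_log[winner][k]
        if sigma2_scope == "fold":
            # prediction-error variance of the kriged log field, per fold
            sigma2 = float(np.mean(np.maximum(pred_var[winner][k], 0.0)))
        elif sigma2_scope == "global":
            sigma2 = float(np.mean(np.maximum(pred_var[winner], 0.0)))
        elif sigma2_scope == "series_fold":
            # sample variance of the predicted log series (alternative
            # reading of "variance of the log10-transformed predictions")
            sigma2 = float(np.var(plog))
        else:
            raise ValueError("sigma2_scope must be 'fold', 'global' or 'series_fold'")
        final = back_transform(plog, sigma2, exact=exact_correction)
        sid = int(series.grid.station_id[k])
        folds.append(FoldResult(sid, series.values[k], final))
        folds_log.append(FoldResult(sid, slog.values[k], plog))
    return STKResult(
        folds=folds,
        folds_log=folds_log,
        selected_pair=winner,
        selection_table=table,
        variogram_fits=fold_fits[winner],
        trend_kind=trend_kind,
    )
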