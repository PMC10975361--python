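"""Cross-method comparison and residual spatial-autocorrelation diagnostics.

With stations as blocks, the Friedman rank test asks whether the three
interpolation methods differ in per-station error (MAE, RMSE, MAPE); the
Nemenyi post-hoc test (studentized-range approximation) localizes which
pairs differ.  Moran's I and Geary's C, with permutation p-values, check the
per-station mean LOOCV residuals for spatial autocorrelation — values near
E[I] = −1/(n−1) and C = 1 indicate none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GREAT_CIRCLE, DistanceConvention, STSeries, pairwise_distance
from .metrics import aggregate, metrics_table
from . import idw as idw_mod
from . import bss as bss_mod
from . import stk as stk_mod


# ---------------------------------------------------------------------------
# Friedman / Nemenyi
# ---------------------------------------------------------------------------

@dataclass
class MethodComparison:
    methods: list
    friedman_stat: dict  # metric -> chi-square
    friedman_p: dict
    nemenyi_p: dict  # metric -> DataFrame (methods × methods)
    mean_reduction_pct: dict  # metric -> DataFrame; [A, B] = 100·(mean_A−mean_B)/mean_A
    avg_ranks: dict


def friedman_test(matrix: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Friedman chi-square on a blocks × treatments matrix (ties averaged,
    with the standard tie correction).  Returns (stat, p, average ranks).

    Degenerate all-tied data yields statistic 0 and p = 1 rather than an
    error.
    """
    matrix = np.asarray(matrix, float)
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    avg_ranks = ranks.mean(axis=0)
    if np.allclose(matrix, matrix[:, [0]]):
        return 0.0, 1.0, avg_ranks
    stat = 12.0 * n / (k * (k + 1)) * np.sum((avg_ranks - (k + 1) / 2.0) ** 2)
    # tie correction
    tie_term = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom > 0:
        stat /= denom
    p = float(stats.chi2.sf(stat, k - 1))
    return float(stat), p, avg_ranks


def nemenyi_pairwise(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Nemenyi p-values from within-block average ranks using the
    studentized-range distribution (infinite df)."""
    matrix = np.asarray(matrix, float)
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    avg = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(avg[i] - avg[j]) / se
            p = float(stats.studentized_range.sf(q, k, np.inf))
            P[i, j] = P[j, i] = min(1.0, p)
    return P


def friedman_nemenyi(metric_matrices: dict[str, pd.DataFrame]) -> MethodComparison:
    """Run Friedman + Nemenyi for each metric's stations × methods matrix and
    compute pairwise mean-error reduction percentages."""
    first = next(iter(metric_matrices.values()))
    methods = list(first.columns)
    fs, fp, nem, red, ar = {}, {}, {}, {}, {}
    for metric, df in metric_matrices.items():
        m = df[methods].to_numpy()
        stat, p, ranks = friedman_test(m)
        fs[metric], fp[metric] = stat, p
        ar[metric] = dict(zip(methods, ranks))
        nem[metric] = pd.DataFrame(nemenyi_pairwise(m), index=methods, columns=methods)
        means = m.mean(axis=0)
        R = 100.0 * (means[:, None] - means[None, :]) / means[:, None]
        red[metric] = pd.DataFrame(R, index=methods, columns=methods)
    return MethodComparison(methods, fs, fp, nem, red, ar)


# ---------------------------------------------------------------------------
# Spatial autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class SpatialAutocorr:
    morans_i: float
    morans_p: float
    gearys_c: float
    gearys_p: float
    n_permutations: int
    weights_descriptor: str = ""
    expected_i: float = 0.0


def inverse_distance_weights(grid, convention: DistanceConvention = GREAT_CIRCLE,
                             row_standardize: bool = True) -> np.ndarray:
    """Inverse-distance spatial weight matrix with zero diagonal."""
    D = pairwise_distance(grid, convention)
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    np.fill_diagonal(W, 0.0)
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return W


def knn_weights(grid, k: int = 4, convention: DistanceConvention = GREAT_CIRCLE,
                row_standardize: bool = True) -> np.ndarray:
    """Binary k-nearest-neighbor weights (asymmetric in general)."""
    D = pairwise_distance(grid, convention)
    n = D.shape[0]
    W = np.zeros_like(D)
    for i in range(n):
        order = np.argsort(D[i])
        W[i, order[1 : k + 1]] = 1.0
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return W


def _morans_stat(z: np.ndarray, W: np.ndarray, s0: float) -> float:
    return z.size / s0 * (z @ W @ z) / (z @ z)


def _gearys_stat(z: np.ndarray, W: np.ndarray, s0: float) -> float:
    diff2 = (z[:, None] - z[None, :]) ** 2
    return (z.size - 1) / (2.0 * s0) * np.sum(W * diff2) / (z @ z)


def _permutation_p(stat_fn, values, W, s0, observed, n_permutations, seed):
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    v = values.copy()
    for b in range(n_permutations):
        rng.shuffle(v)
        z = v - v.mean()
        perms[b] = stat_fn(z, W, s0)
    # two-sided permutation p: how extreme is the observed deviation
    dev = np.abs(observed - perms.mean())
    p = (1.0 + np.sum(np.abs(perms - perms.mean()) >= dev - 1e-15)) / (n_permutations + 1.0)
    return float(min(1.0, p))


def morans_i(values, W, n_permutations: int = 999, seed: int = 0) -> tuple[float, float]:
    """Moran's I with a two-sided permutation p-value.

    I = (n/S0) Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ² with z the centered values; under the
    permutation null E[I] = −1/(n−1).
    """
    values = np.asarray(values, float)
    W = np.asarray(W, float)
    if np.ptp(values) == 0:
        raise ValueError("Moran's I undefined for constant values")
    if np.diag(W).any():
        raise ValueError("weight matrix must have a zero diagonal")
    s0 = W.sum()
    z = values - values.mean()
    obs = _morans_stat(z, W, s0)
    p = _permutation_p(_morans_stat, values, W, s0, obs, n_permutations, seed)
    return float(obs), p


def gearys_c(values, W, n_permutations: int = 999, seed: int = 0) -> tuple[float, float]:
    """Geary's C with a two-sided permutation p-value.

    C = ((n−1)/2S0) Σᵢⱼ wᵢⱼ (zᵢ−zⱼ)² / Σᵢ zᵢ²; C ≈ 1 under no
    autocorrelation, C < 1 for positive autocorrelation.
    """
    values = np.asarray(values, float)
    W = np.asarray(W, float)
    if np.ptp(values) == 0:
        raise ValueError("Geary's C undefined for constant values")
    if np.diag(W).any():
        raise ValueError("weight matrix must have a zero diagonal")
    s0 = W.sum()
    z = values - values.mean()
    obs = _gearys_stat(z, W, s0)
    p = _permutation_p(_gearys_stat, values, W, s0, obs, n_permutations, seed)
    return float(obs), p


def spatial_autocorr(values, W, n_permutations: int = 999, seed: int = 0,
                     descriptor: str = "inverse_distance_row_standardized") -> SpatialAutocorr:
    i, ip = morans_i(values, W, n_permutations, seed)
    c, cp = gearys_c(values, W, n_permutations, seed + 1)
    return SpatialAutocorr(i, ip, c, cp, n_permutations, descriptor,
                           expected_i=-1.0 / (np.asarray(values).size - 1))


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    methods: list
    metric_tables: dict  # method -> per-station metrics DataFrame
    aggregates: dict  # method -> min/max/average DataFrame
    comparison: MethodComparison | None
    autocorr: dict  # method -> SpatialAutocorr on per-station mean residuals
    idw_beta: float | None = None
    stk_selected_pair: tuple | None = None
    folds: dict = field(default_factory=dict, repr=False)


def benchmark(
    series: STSeries,
    methods=("idw", "bss", "stk"),
    seed: int = 0,
    convention: DistanceConvention = GREAT_CIRCLE,
    idw_betas=idw_mod.DEFAULT_BETA_GRID,
    bss_k_nearest: int = 3,
    bss_offset: float | None = None,
    stk_options: dict | None = None,
    n_permutations: int = 999,
) -> BenchmarkReport:
    """Run every method's station-omission LOOCV on one series and assemble
    the full comparison report.

    Deterministic for fixed (series, options, seed): the only randomness is
    in the permutation p-values, which use the seed.
    """
    methods = list(methods)
    folds: dict = {}
    report = BenchmarkReport(methods, {}, {}, None, {}, folds=folds)
    for m in methods:
        if m == "idw":
            res = idw_mod.optimize_beta(series, idw_betas, convention)
            report.idw_beta = res.beta
            folds[m] = res.folds
        elif m == "bss":
            folds[m] = bss_mod.bss_loocv(series, k_nearest=bss_k_nearest, offset=bss_offset)
        elif m == "stk":
            res = stk_mod.stk_loocv(series, convention=convention, **(stk_options or {}))
            report.stk_selected_pair = res.selected_pair
            folds[m] = res.folds
        else:
            raise ValueError(f"unknown method {m!r}")
        table = metrics_table(folds[m])
        report.metric_tables[m] = table
        report.aggregates[m] = aggregate(table)

    if len(methods) >= 2:
        mats = {
            metric: pd.DataFrame(
                {m: report.metric_tables[m][metric] for m in methods}
            )
            for metric in ("mae", "rmse", "mape")
        }
        report.comparison = friedman_nemenyi(mats)

    W = inverse_distance_weights(series.grid, convention)
    for m in methods:
        mean_resid = np.array(
            [np.mean(f.observed - f.predicted) for f in folds[m]]
        )
        report.autocorr[m] = spatial_autocorr(
            mean_resid, W, n_permutations=n_permutations, seed=seed
        )
    return report
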