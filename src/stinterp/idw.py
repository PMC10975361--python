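"""Inverse distance weighting with whole-series station-omission LOOCV.

The predictor at an unsampled site x0 is the convex combination

    ẑ(x0) = Σᵢ z(xᵢ) dᵢ^(−β) / Σᵢ dᵢ^(−β),

where dᵢ is the distance from x0 to station xᵢ and β > 0 the power
parameter (β = 2 is the classical inverse-squared-distance interpolator).
β is selected on a grid (default integers 1..10) by leaving each station's
entire time series out in turn, predicting it from the remaining stations,
and minimizing the pooled RMSE over all stations and months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GREAT_CIRCLE,
    DistanceConvention,
    FoldResult,
    STSeries,
    pairwise_distance,
)
from .metrics import error_metrics

DEFAULT_BETA_GRID = tuple(range(1, 11))


@dataclass
class IDWModel:
    beta: float = 2.0
    convention: DistanceConvention = GREAT_CIRCLE

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be positive")


def idw_weights(distances: np.ndarray, beta: float) -> np.ndarray:
    """Normalized IDW weights for one target; exact-hit stations get all
    the weight (the zero-distance limit of the formula)."""
    d = np.asarray(distances, float)
    if d.size == 0:
        raise ValueError("empty neighbor set")
    hits = d == 0.0
    if hits.any():
        w = hits.astype(float)
        return w / w.sum()
    w = d ** (-beta)
    return w / w.sum()


def idw_predict(model: IDWModel, neighbor_lon, neighbor_lat, neighbor_values,
                target_lon: float, target_lat: float) -> np.ndarray | float:
    """Predict at one target location from neighbor stations.

    ``neighbor_values`` may be (n,) for one time step or (n, T) for a whole
    series; the same spatial weights apply at every time step.
    """
    d = model.convention.pairwise(
        [target_lon], [target_lat], neighbor_lon, neighbor_lat
    )[0]
    w = idw_weights(d, model.beta)
    values = np.asarray(neighbor_values, float)
    out = w @ values
    return float(out) if values.ndim == 1 else out


def idw_loocv(series: STSeries, beta: float,
              convention: DistanceConvention = GREAT_CIRCLE) -> list[FoldResult]:
    """Leave each station's entire series out and predict it from the rest.

    All n−1 remaining stations serve as neighbors at every time step.
    """
    if series.n_stations < 3:
        raise ValueError("LOOCV needs at least 3 stations")
    dist = pairwise_distance(series.grid, convention)
    folds = []
    for k in range(series.n_stations):
        mask = np.ones(series.n_stations, bool)
        mask[k] = False
        w = idw_weights(dist[k, mask], beta)
        folds.append(
            FoldResult(
                station_id=int(series.grid.station_id[k]),
                observed=series.values[k],
                predicted=w @ series.values[mask],
            )
        )
    return folds


@dataclass
class BetaSearchResult:
    beta: float
    table: pd.DataFrame  # one row per candidate beta: mae, rmse, mape
    folds: list[FoldResult] = field(repr=False, default_factory=list)


def optimize_beta(series: STSeries, betas=DEFAULT_BETA_GRID,
                  convention: DistanceConvention = GREAT_CIRCLE) -> BetaSearchResult:
    """Grid-search the power parameter by pooled LOOCV RMSE.

    Ties are broken toward the smaller (smoother) β.  The returned table
    reports pooled MAE, RMSE and MAPE for every candidate.
    """
    betas = list(betas)
    if not betas:
        raise ValueError("empty beta grid")
    rows = []
    best = None
    for b in betas:
        folds = idw_loocv(series, b, convention)
        obs = np.concatenate([f.observed for f in folds])
        sim = np.concatenate([f.predicted for f in folds])
        mae, rmse, mape = error_metrics(obs, sim)
        if not np.isfinite(rmse):
            raise ValueError(f"non-finite RMSE at beta={b}")
        rows.append({"beta": b, "mae": mae, "rmse": rmse, "mape": mape})
        if best is None or rmse < best[0] - 1e-15:
            best = (rmse, b, folds)
    table = pd.DataFrame(rows).set_index("beta")
    return BetaSearchResult(beta=best[1], table=table, folds=best[2])
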