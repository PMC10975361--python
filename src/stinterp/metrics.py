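"""Error and efficiency metrics for predicted vs observed station series.

Six scores are computed per station and then aggregated (min / max / average
across stations): MAE, RMSE and MAPE (%) measure error magnitude; the
Nash–Sutcliffe efficiency (NSE), Kling–Gupta efficiency (KGE, with its
correlation r, variability ratio α and bias ratio β components) and
Willmott's index of agreement (dIndex) measure model skill, all three equal
to 1 for a perfect prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FoldResult

METRIC_COLUMNS = [
    "mae", "rmse", "mape", "nse", "kge", "kge_r", "kge_alpha", "kge_beta", "dindex",
]


def _check(obs, sim):
    obs = np.asarray(obs, float)
    sim = np.asarray(sim, float)
    if obs.shape != sim.shape or obs.ndim != 1 or obs.size < 1:
        raise ValueError("obs and sim must be equal-length 1-D arrays")
    if np.isnan(obs).any() or np.isnan(sim).any():
        raise ValueError("NaN in metric inputs; series are gap-free by contract")
    return obs, sim


def error_metrics(obs, sim) -> tuple[float, float, float]:
    """(MAE, RMSE, MAPE%) of a prediction. MAPE requires nonzero observations."""
    obs, sim = _check(obs, sim)
    err = obs - sim
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if (obs == 0).any():
        raise ValueError("MAPE undefined: zero observation present")
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(obs)))
    return mae, rmse, mape


def nse(obs, sim) -> float:
    """Nash–Sutcliffe efficiency: 1 − Σ(o−s)² / Σ(o−ō)².

    1 is a perfect match; 0 means the prediction is only as accurate as the
    observed mean.
    """
    obs, sim = _check(obs, sim)
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0:
        raise ValueError("NSE undefined for constant observations")
    return float(1.0 - np.sum((obs - sim) ** 2) / denom)


def kge(obs, sim) -> tuple[float, float, float, float]:
    """Kling–Gupta efficiency and its (r, α, β) components.

    KGE = 1 − sqrt((r−1)² + (α−1)² + (β−1)²), with r the Pearson correlation,
    α = sd(sim)/sd(obs) and β = mean(sim)/mean(obs).  Standard deviations use
    the (n−1) normalization.
    """
    obs, sim = _check(obs, sim)
    if obs.size < 2:
        raise ValueError("KGE needs at least two points")
    so, ss = obs.std(ddof=1), sim.std(ddof=1)
    if so == 0 or ss == 0:
        raise ValueError("KGE undefined: constant obs or sim")
    if obs.mean() == 0:
        raise ValueError("KGE undefined: zero observed mean")
    r = float(np.corrcoef(obs, sim)[0, 1])
    alpha = float(ss / so)
    beta = float(sim.mean() / obs.mean())
    k = float(1.0 - np.sqrt((r - 1) ** 2 + (alpha - 1) ** 2 + (beta - 1) ** 2))
    return k, r, alpha, beta


def d_index(obs, sim) -> float:
    """Willmott's index of agreement:
    1 − Σ(o−s)² / Σ(|s−ō| + |o−ō|)², in [0, 1]."""
    obs, sim = _check(obs, sim)
    om = obs.mean()
    denom = np.sum((np.abs(sim - om) + np.abs(obs - om)) ** 2)
    if denom == 0:
        raise ValueError("dIndex undefined: obs and sim both constant at the observed mean")
    return float(1.0 - np.sum((obs - sim) ** 2) / denom)


def station_metrics(fold: FoldResult) -> dict:
    """All metric columns for one station's predicted vs observed series."""
    mae, rmse, mape = error_metrics(fold.observed, fold.predicted)
    k, r, a, b = kge(fold.observed, fold.predicted)
    return {
        "station_id": fold.station_id,
        "mae": mae,
        "rmse": rmse,
        "mape": mape,
        "nse": nse(fold.observed, fold.predicted),
        "kge": k,
        "kge_r": r,
        "kge_alpha": a,
        "kge_beta": b,
        "dindex": d_index(fold.observed, fold.predicted),
    }


def metrics_table(folds: list[FoldResult]) -> pd.DataFrame:
    """Per-station metrics, one row per left-out station."""
    if not folds:
        raise ValueError("no folds")
    df = pd.DataFrame([station_metrics(f) for f in folds])
    return df.set_index("station_id")


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """min / max / average rows across stations, matching the reporting layout
    used for per-station LOOCV tables."""
    cols = [c for c in METRIC_COLUMNS if c in table.columns]
    return pd.DataFrame(
        {
            "min": table[cols].min(),
            "max": table[cols].max(),
            "average": table[cols].mean(),
        }
    ).T


def write_metrics_csv(table: pd.DataFrame, path) -> None:
    """Metrics CSV: one row per station plus min/max/average footer rows."""
    agg = aggregate(table)
    out = pd.concat([table, agg.rename_axis("station_id")])
    out.to_csv(path)
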