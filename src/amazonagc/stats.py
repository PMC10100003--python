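"""Trend estimation, model-observation comparison and aggregation.

Per-cell trends use the Theil-Sen estimator (median of all pairwise slopes)
with significance from the two-sided Mann-Kendall test at the 95% level
(tie-corrected normal approximation with continuity correction).  Model and
observation trend fields are compared over cells with less than 90%
old-growth cover via Pearson's r, mean absolute deviation and the fraction
of cells agreeing on trend sign.  Uncertainties combine by root sum of
squares (an annual-summation alternative is exposed).  Region totals use
per-cell membership weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fluxes import REFERENCE_OG_FRACTION

__all__ = [
    "TrendResult",
    "ComparisonStats",
    "mann_kendall",
    "theil_sen",
    "trend_field",
    "compare_trend_fields",
    "propagate_uncertainty",
    "aggregate_region",
]


@dataclass(frozen=True)
class TrendResult:
    slope: float              # per-year units of the input
    intercept: float
    p_value: float            # Mann-Kendall two-sided p (NaN if n < 4)
    significant: bool         # p < 0.05 at n >= 4, else False
    n_years: int


@dataclass(frozen=True)
class ComparisonStats:
    pearson_r: float
    r_squared: float
    mad: float
    n_cells: int
    agreement_fraction: float


def mann_kendall(values: np.ndarray) -> tuple[float, float]:
    """Mann-Kendall S statistic and two-sided p-value for monotone trend.

    Uses the tie-corrected variance and a continuity correction; returns
    (S, p).  Requires n >= 4 for the normal approximation to be meaningful.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    diff = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        return s, 1.0
    z = (s - np.sign(s)) / np.sqrt(var_s)
    p = 2.0 * sps.norm.sf(abs(z))
    return s, float(p)


def theil_sen(years: np.ndarray, values: np.ndarray) -> TrendResult:
    """Robust trend: median pairwise slope + Mann-Kendall significance.

    Needs >= 3 points for the slope and >= 4 for the significance test
    (below 4 the test is undefined and ``significant`` is False).
    Duplicate years are rejected.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate years in trend input")
    if len(t) < 3:
        raise ValueError("Theil-Sen needs at least 3 points")
    slope, intercept, *_ = sps.theilslopes(y, t)
    order = np.argsort(t)
    if len(t) >= 4:
        _, p = mann_kendall(y[order])
        significant = bool(p < 0.05)
    else:
        p, significant = float("nan"), False
    return TrendResult(slope=float(slope), intercept=float(intercept),
                       p_value=p, significant=significant, n_years=len(t))


def trend_field(series: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Per-cell Theil-Sen trends of a (cell_id, year, value) table."""
    rows = []
    for cell_id, sub in series.dropna(subset=[value_col]).groupby("cell_id"):
        if len(sub) < 3:
            continue
        r = theil_sen(sub["year"].to_numpy(), sub[value_col].to_numpy())
        rows.append({"cell_id": cell_id, "slope": r.slope, "p_value": r.p_value,
                     "significant": r.significant, "n_years": r.n_years})
    return pd.DataFrame(rows)


def _sign_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of strict-sign matches; zero agrees only with zero."""
    return float(np.mean(np.sign(a) == np.sign(b)))


def compare_trend_fields(modeled: pd.DataFrame, lvod: pd.DataFrame,
                         f_oldgrowth: pd.DataFrame,
                         mode: str = "slope") -> ComparisonStats:
    """Model-vs-observation agreement over mixed (<90% old-growth) cells.

    ``modeled``/``lvod`` carry per-cell values: Theil-Sen slopes
    (``mode="slope"``, column ``slope``) or total-period changes
    (``mode="total"``, column ``total_change``); ``f_oldgrowth`` holds the
    final-year cover fraction per cell.  Pearson's r, r^2, MAD and the
    same-sign fraction are computed over eligible cells present in both.
    """
    col = {"slope": "slope", "total": "total_change"}[mode]
    eligible = f_oldgrowth.loc[f_oldgrowth["f_oldgrowth"] < REFERENCE_OG_FRACTION,
                               "cell_id"]
    merged = (modeled[["cell_id", col]].rename(columns={col: "m"})
              .merge(lvod[["cell_id", col]].rename(columns={col: "l"}), on="cell_id")
              .merge(eligible, on="cell_id"))
    merged = merged.dropna()
    if len(merged) < 3:
        raise ValueError("fewer than 3 eligible cells for comparison")
    m, l = merged["m"].to_numpy(), merged["l"].to_numpy()
    r = float(sps.pearsonr(m, l).statistic)
    return ComparisonStats(
        pearson_r=r, r_squared=r * r,
        mad=float(np.mean(np.abs(m - l))),
        n_cells=len(merged),
        agreement_fraction=_sign_agreement(m, l),
    )


def propagate_uncertainty(sigmas, method: str = "rss") -> float:
    """Combine 1-SD uncertainties: root sum of squares, or plain summation."""
    s = np.asarray(sigmas, dtype=float)
    if (s < 0).any():
        raise ValueError("sigmas must be non-negative")
    if method == "rss":
        return float(np.sqrt(np.sum(s**2)))
    if method == "sum":
        return float(np.sum(s))
    raise ValueError(f"unknown method {method!r}")


def aggregate_region(flux_table: pd.DataFrame,
                     region_weights: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-region, per-process totals from cell-membership weights.

    ``region_weights`` maps region name -> per-cell weight in [0, 1] (index
    = cell_id); weights may overlap cells but must sum to <= 1 per cell.
    Adds per-region gross loss (deforestation + both degradation terms) and
    the degradation share of gross loss.
    """
    weights = {k: np.asarray(v, dtype=float).ravel() for k, v in region_weights.items()}
    stacked = np.vstack(list(weights.values()))
    if (stacked < 0).any() or (stacked > 1).any():
        raise ValueError("region weights must lie in [0, 1]")
    if (stacked.sum(axis=0) > 1 + 1e-9).any():
        raise ValueError("per-cell region weights must sum to <= 1")

    rows = []
    for region, w in weights.items():
        wmap = pd.Series(w, index=np.arange(len(w)))
        sub = flux_table.copy()
        sub["weighted"] = sub["delta_agc"] * sub["cell_id"].map(wmap)
        totals = sub.groupby("process")["weighted"].sum()
        loss_terms = ["deforestation", "edge_degradation", "nonedge_degradation"]
        gross_loss = float(totals.reindex(loss_terms).fillna(0.0).sum())
        degradation = float(totals.reindex(
            ["edge_degradation", "nonedge_degradation"]).fillna(0.0).sum())
        for process, value in totals.items():
            rows.append({"region": region, "process": process,
                         "delta_agc": float(value)})
        rows.append({"region": region, "process": "gross_loss",
                     "delta_agc": gross_loss})
        share = degradation / gross_loss if gross_loss != 0 else float("nan")
        rows.append({"region": region, "process": "degradation_share",
                     "delta_agc": share})
    return pd.DataFrame(rows)
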