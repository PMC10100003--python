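"""VOD-to-AGC calibration against a reference biomass map.

Each of the three annual indices is calibrated independently against the
reference-year biomass map (aggregated to the coarse grid) by fitting the
four-parameter saturating curve with multi-start nonlinear least squares.
Annual indices are then converted to carbon density per method; the mean of
the three estimates is the working AGC value and their standard deviation
enters the uncertainty budget.  Cells showing a year-over-year increase
greater than 20 Mg C ha-1 -- far above the plausible biome accumulation rate
of up to 6 Mg C ha-1 yr-1 -- are masked as retrieval anomalies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .curves import OVERFLOW_SENTINEL, CalibrationCurve, _logistic
from .grids import GridSpec
from .lvod import INDEX_METHODS

__all__ = [
    "FitError",
    "fit_vod_agc_curve",
    "vod_to_agc",
    "build_agc_series",
    "mask_anomalous_cells",
    "aggregate_reference_map",
    "ANOMALY_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Year-over-year density increase above which a cell is masked (Mg C ha-1).
ANOMALY_THRESHOLD = 20.0


class FitError(RuntimeError):
    """Calibration fit failed to converge from any start."""


def _model(v, a, b, c, d):
    out = np.asarray(_logistic(v, a, b, c, d), dtype=float)
    out[~np.isfinite(out)] = OVERFLOW_SENTINEL
    return out


def _starts(v: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float, float]]:
    """Eight deterministic starting points spanning the data range."""
    ylo, yhi = float(np.min(y)), float(np.max(y))
    spread = max(yhi - ylo, 1.0)
    q25, q50, q75 = np.quantile(v, [0.25, 0.5, 0.75])
    vspan = max(float(np.ptp(v)), 1e-3)
    starts = []
    for b0 in (2.0 / vspan, 8.0 / vspan):
        for c0 in (q25, q75):
            for margin in (0.05, 0.5):
                starts.append((yhi + margin * spread, b0, float(c0),
                               max(ylo - margin * spread, 0.0)))
    return starts


def fit_vod_agc_curve(index_values: np.ndarray,
                      reference_agc: np.ndarray,
                      index_method: str = "",
                      min_cells: int = 20) -> CalibrationCurve:
    """Fit the four-parameter VOD-AGC curve to (index, reference) pairs.

    Non-finite curve evaluations are replaced by the overflow sentinel
    during fitting; standard errors come from the fit covariance; the best
    of eight deterministic starts (by residual sum of squares) is returned.
    """
    v = np.asarray(index_values, dtype=float)
    y = np.asarray(reference_agc, dtype=float)
    ok = np.isfinite(v) & np.isfinite(y)
    v, y = v[ok], y[ok]
    if len(v) < min_cells:
        raise ValueError(f"calibration needs >= {min_cells} cells, got {len(v)}")
    if np.ptp(v) == 0:
        raise ValueError("degenerate calibration input: constant index")

    best = None
    tried = []
    for p0 in _starts(v, y):
        tried.append(p0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(_model, v, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((_model(v, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise FitError(f"calibration fit did not converge from any of {len(tried)} starts")

    rss, popt, pcov = best
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    a, b, c, d = popt
    if b < 0:  # re-express with positive slope (logistic symmetry a<->d, b<->-b)
        a, d, b = d, a, -b
        se = se[[3, 1, 2, 0]]
    return CalibrationCurve(a=a, b=b, c=c, d=d,
                            se_a=float(se[0]), se_b=float(se[1]),
                            se_c=float(se[2]), se_d=float(se[3]),
                            index_method=index_method, rss=rss, n_fit=len(v))


def vod_to_agc(curve: CalibrationCurve, index_value) -> np.ndarray:
    """Curve image of an index value, with sentinel and zero-floor handling."""
    out = np.atleast_1d(np.asarray(curve(index_value), dtype=float))
    neg = out < 0
    if neg.any():
        warnings.warn(f"{int(neg.sum())} negative AGC value(s) clipped to 0",
                      stacklevel=2)
        out[neg] = 0.0
    return out[0] if np.ndim(index_value) == 0 else out


def build_agc_series(indices: pd.DataFrame,
                     curves: dict[str, CalibrationCurve]) -> pd.DataFrame:
    """Mean and SD over the three per-method AGC estimates per cell-year.

    ``indices`` is the frame produced by the L-VOD pipeline (one column per
    index method).  Cell-years missing any method are masked, not imputed.
    """
    missing = set(INDEX_METHODS) - set(curves)
    if missing:
        raise ValueError(f"missing calibration curve(s) for {sorted(missing)}")
    df = indices.copy()
    est_cols = []
    for method in INDEX_METHODS:
        col = f"agc_{method}"
        valid = df[method].notna()
        df[col] = np.nan
        df.loc[valid, col] = vod_to_agc(curves[method], df.loc[valid, method].to_numpy())
        est_cols.append(col)
    est = df[est_cols].to_numpy()
    complete = np.isfinite(est).all(axis=1)
    out = df[["cell_id", "year"]].copy()
    out["agc_mean"] = np.where(complete, est.mean(axis=1), np.nan)
    out["agc_sd"] = np.where(complete, est.std(axis=1, ddof=1), np.nan)
    out["masked"] = ~complete
    return out


def mask_anomalous_cells(agc: pd.DataFrame,
                         threshold: float = ANOMALY_THRESHOLD) -> pd.DataFrame:
    """Mask every year of cells with any year-over-year increase > threshold.

    The increase is evaluated between consecutive calendar years only;
    decreases never trigger the mask and the threshold is strict.
    """
    out = agc.copy()
    for cell_id, sub in out.groupby("cell_id"):
        sub = sub.sort_values("year")
        dy = sub["year"].diff().to_numpy()
        dv = sub["agc_mean"].diff().to_numpy()
        if np.any((dy == 1) & (dv > threshold)):
            out.loc[out["cell_id"] == cell_id, "masked"] = True
    return out


def aggregate_reference_map(biomass: np.ndarray, grid: GridSpec,
                            valid: np.ndarray | None = None) -> np.ndarray:
    """Area-weighted mean of the fine biomass map per coarse cell.

    ``valid`` masks out non-land pixels (water etc.); with equal-area
    pixels the area-weighted mean reduces to the mean over valid pixels.
    """
    if valid is None:
        return grid.coarsen_mean(biomass)
    num = grid.coarsen_sum(np.where(valid, biomass, 0.0))
    den = grid.coarsen_sum(valid)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)
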