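"""Daily L-VOD filtering, seasonal-trend decomposition and annual indices.

The processing chain, in the fixed order the filters must run:

1. quality masks (auxiliary flags; cells more than 25% inundated),
2. RFI rejection (TB-RMSE strictly greater than 8 K),
3. orbit reconciliation (trimester ASC/DESC mean difference > 0.05 drops
   TB-RMSE > 5 K observations; same-day duplicates keep the lower TB-RMSE),
4. trimester outlier rejection (beyond 2 standard deviations),
5. seasonal/trend curve fit and the three annual aggregate indices over the
   January-April window.

All thresholds are strict inequalities exactly as worded, and each filter is
idempotent.  The curve fit follows the classic decomposition of a flask-record
smoother: a quadratic polynomial plus two annual harmonics fitted by least
squares, with the residuals interpolated to a daily grid and low-pass filtered
twice -- a short cutoff (80 days) added back to the full fit gives the
*smoothed* series, a long cutoff (667 days) added to the polynomial alone
gives the *trend* series with seasonality removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FitConfig",
    "SmoothedSeries",
    "AnnualIndexSet",
    "INDEX_METHODS",
    "apply_quality_masks",
    "filter_rfi",
    "reconcile_orbits",
    "remove_outliers",
    "fit_seasonal_trend",
    "annual_indices",
    "run_lvod_pipeline",
]

logger = logging.getLogger(__name__)

#: The three annual aggregate indices, in reporting order.
INDEX_METHODS = ("max_smooth", "mean_smooth", "mean_trend")

RFI_TB_RMSE_K = 8.0
ORBIT_DIFF_THRESHOLD = 0.05
ORBIT_TB_RMSE_K = 5.0
OUTLIER_SD = 2.0
INUNDATION_MAX = 0.25


@dataclass(frozen=True)
class FitConfig:
    """Seasonal/trend decomposition parameters.

    ``poly_order``/``n_harmonics`` define the fitted function; the two
    cutoffs (days, half-power points of the residual low-pass) control how
    much residual variability re-enters the smoothed and trend series.
    """

    poly_order: int = 2
    n_harmonics: int = 2
    short_cutoff_days: float = 80.0
    long_cutoff_days: float = 667.0
    min_window_obs: int = 20   # retained Jan-Apr values required per index


@dataclass
class SmoothedSeries:
    """Daily smoothed and seasonality-free trend curves for one cell."""

    cell_id: int
    dates: pd.DatetimeIndex
    smoothed: np.ndarray
    trend: np.ndarray


@dataclass
class AnnualIndexSet:
    """The three Jan-Apr aggregate indices for one cell-year."""

    cell_id: int
    year: int
    max_smooth: float
    mean_smooth: float
    mean_trend: float
    n_obs_used: int


def _trimester(dates: pd.Series) -> pd.Series:
    """Calendar-quarter key (JFM/AMJ/JAS/OND) as year*10 + quarter."""
    return dates.dt.year * 10 + dates.dt.quarter


# --------------------------------------------------------------------------
# filters
# --------------------------------------------------------------------------

def apply_quality_masks(obs: pd.DataFrame,
                        cell_inundation_fraction: dict | pd.Series) -> pd.DataFrame:
    """Drop flagged observations and cells more than 25% inundated."""
    frac = pd.Series(cell_inundation_fraction, dtype=float)
    missing = set(obs["cell_id"].unique()) - set(frac.index)
    if missing:
        raise KeyError(f"cells missing from inundation table: {sorted(missing)[:5]}")
    inundated = frac[frac > INUNDATION_MAX].index
    keep = (obs["flag"] == 0) & ~obs["cell_id"].isin(inundated)
    return obs[keep].reset_index(drop=True)


def filter_rfi(obs: pd.DataFrame, threshold: float = RFI_TB_RMSE_K) -> pd.DataFrame:
    """Exclude observations with TB-RMSE strictly greater than ``threshold``."""
    if (obs["tb_rmse"] < 0).any():
        raise ValueError("negative TB-RMSE encountered")
    return obs[obs["tb_rmse"] <= threshold].reset_index(drop=True)


def reconcile_orbits(obs: pd.DataFrame,
                     diff_threshold: float = ORBIT_DIFF_THRESHOLD,
                     tb_threshold: float = ORBIT_TB_RMSE_K,
                     mode: str = "both") -> pd.DataFrame:
    """Reconcile ascending and descending orbit streams.

    Per (cell, trimester): if the two orbit VOD means differ by strictly
    more than ``diff_threshold``, remove the observations with TB-RMSE
    strictly above ``tb_threshold`` -- from both orbits (``mode="both"``,
    default) or only from the orbit whose mean is farther from the pooled
    mean (``mode="farther"``).  Then, for days carrying both an ASC and a
    DESC record, keep the record with the lower TB-RMSE.
    """
    if mode not in ("both", "farther"):
        raise ValueError(f"unknown reconciliation mode {mode!r}")
    df = obs.copy()
    df["_trim"] = _trimester(df["date"])

    means = df.pivot_table(index=["cell_id", "_trim"], columns="orbit",
                           values="vod", aggfunc="mean")
    for col in ("ASC", "DESC"):
        if col not in means:
            means[col] = np.nan
    single = means["ASC"].isna() | means["DESC"].isna()
    if single.any():
        logger.warning("orbit-difference test skipped for %d cell-trimesters "
                       "with a single orbit", int(single.sum()))
    offending = means.index[(means["ASC"] - means["DESC"]).abs() > diff_threshold]

    if len(offending):
        key = pd.MultiIndex.from_frame(df[["cell_id", "_trim"]])
        in_bad = key.isin(offending)
        drop = in_bad & (df["tb_rmse"] > tb_threshold).to_numpy()
        if mode == "farther":
            # only the orbit whose mean is farther from the pooled mean
            pooled = df.groupby(["cell_id", "_trim"])["vod"].transform("mean")
            asc_m = means["ASC"].reindex(key).to_numpy()
            desc_m = means["DESC"].reindex(key).to_numpy()
            farther_is_asc = (np.abs(asc_m - pooled.to_numpy())
                              >= np.abs(desc_m - pooled.to_numpy()))
            on_farther = np.where(farther_is_asc, df["orbit"] == "ASC",
                                  df["orbit"] == "DESC")
            drop &= on_farther
        df = df[~drop]

    # same-day duplicates: keep the lower TB-RMSE record
    df = (df.sort_values(["cell_id", "date", "tb_rmse", "orbit"], kind="stable")
            .drop_duplicates(subset=["cell_id", "date"], keep="first"))
    return df.drop(columns="_trim").reset_index(drop=True)


def remove_outliers(obs: pd.DataFrame, n_sd: float = OUTLIER_SD) -> pd.DataFrame:
    """Drop observations beyond ``n_sd`` SD of their (cell, trimester) mean.

    Mean and SD are computed once on the incoming set (not iteratively);
    groups with fewer than 3 observations pass through unchanged.
    """
    df = obs.copy()
    trim = _trimester(df["date"])
    grp = df.groupby([df["cell_id"], trim])["vod"]
    mean = grp.transform("mean")
    sd = grp.transform("std")           # ddof=1
    n = grp.transform("size")
    dev = (df["vod"] - mean).abs()
    # an (effectively) constant series has sd at rounding level: keep all
    degenerate = sd <= 1e-12 * mean.abs().clip(lower=1e-30)
    keep = (n < 3) | sd.isna() | degenerate | (dev <= n_sd * sd)
    return obs[keep.to_numpy()].reset_index(drop=True)


# --------------------------------------------------------------------------
# curve fitting
# --------------------------------------------------------------------------

def _lowpass(x: np.ndarray, cutoff_days: float) -> np.ndarray:
    """FFT low-pass with half-power at 1/cutoff (smooth quartic roll-off)."""
    n = len(x)
    pad = min(n, int(2 * cutoff_days))
    padded = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    freqs = np.fft.rfftfreq(len(padded), d=1.0)
    gain = np.exp(-np.log(2.0) * (freqs * cutoff_days) ** 4)
    out = np.fft.irfft(np.fft.rfft(padded) * gain, n=len(padded))
    return out[pad:pad + n]


def _design_matrix(t_years: np.ndarray, cfg: FitConfig) -> np.ndarray:
    cols = [t_years**k for k in range(cfg.poly_order + 1)]
    for h in range(1, cfg.n_harmonics + 1):
        cols.append(np.cos(2 * np.pi * h * t_years))
        cols.append(np.sin(2 * np.pi * h * t_years))
    return np.column_stack(cols)


def fit_seasonal_trend(obs: pd.DataFrame,
                       config: FitConfig | None = None) -> SmoothedSeries:
    """Decompose one cell's daily record into smoothed and trend curves.

    Fits polynomial + annual harmonics by least squares, low-pass filters
    the residuals on a complete daily grid, and returns the smoothed series
    (function + short-cutoff residual) and the trend series (polynomial +
    long-cutoff residual, harmonics excluded).
    """
    cfg = config or FitConfig()
    cells = obs["cell_id"].unique()
    if len(cells) != 1:
        raise ValueError("fit_seasonal_trend expects observations of one cell")
    df = obs.sort_values("date")
    dates = pd.to_datetime(df["date"])
    if dates.nunique() < 8:
        raise ValueError("need at least 8 distinct observation dates")
    span_days = (dates.iloc[-1] - dates.iloc[0]).days
    if span_days < 700:
        logger.warning("cell %s: only %.1f years of data for the seasonal fit",
                       cells[0], span_days / 365.25)

    t0 = dates.iloc[0]
    ty = (dates - t0).dt.days.to_numpy(float) / 365.25
    y = df["vod"].to_numpy(float)
    X = _design_matrix(ty, cfg)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta

    daily = pd.date_range(dates.iloc[0].normalize(), dates.iloc[-1].normalize(),
                          freq="D")
    td = (daily - t0.normalize()).days.to_numpy(float) / 365.25
    Xd = _design_matrix(td, cfg)
    func_daily = Xd @ beta
    poly_daily = Xd[:, :cfg.poly_order + 1] @ beta[:cfg.poly_order + 1]

    # average duplicate-date residuals before gridding
    rs = pd.Series(resid, index=dates.dt.normalize().values).groupby(level=0).mean()
    t_obs = (rs.index.to_numpy() - daily[0].to_numpy()).astype("timedelta64[D]").astype(float)
    resid_daily = np.interp(np.arange(len(daily), dtype=float), t_obs, rs.to_numpy())

    smoothed = func_daily + _lowpass(resid_daily, cfg.short_cutoff_days)
    trend = poly_daily + _lowpass(resid_daily, cfg.long_cutoff_days)
    return SmoothedSeries(cell_id=int(cells[0]), dates=daily,
                          smoothed=smoothed, trend=trend)


def annual_indices(series: SmoothedSeries, year: int,
                   n_obs_used: int | None = None,
                   min_window_obs: int = 20) -> AnnualIndexSet | None:
    """The three aggregate indices over the closed Jan 1 - Apr 30 window.

    Returns ``None`` (missing, never zero) when fewer than
    ``min_window_obs`` retained observations fall in the window.
    """
    lo = pd.Timestamp(year=year, month=1, day=1)
    hi = pd.Timestamp(year=year, month=4, day=30)
    if series.dates[0] > lo or series.dates[-1] < hi:
        raise ValueError(f"series span does not cover Jan-Apr {year}")
    win = (series.dates >= lo) & (series.dates <= hi)
    if n_obs_used is not None and n_obs_used < min_window_obs:
        return None
    return AnnualIndexSet(
        cell_id=series.cell_id, year=year,
        max_smooth=float(series.smoothed[win].max()),
        mean_smooth=float(series.smoothed[win].mean()),
        mean_trend=float(series.trend[win].mean()),
        n_obs_used=-1 if n_obs_used is None else int(n_obs_used),
    )


# --------------------------------------------------------------------------
# pipeline driver
# --------------------------------------------------------------------------

def run_lvod_pipeline(obs: pd.DataFrame,
                      cell_inundation_fraction: dict | pd.Series,
                      years: list[int] | None = None,
                      config: FitConfig | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filters -> fit -> indices for every cell.

    Returns ``(indices, rejection_log)``: one row per (cell_id, year) with
    the three indices and the retained Jan-Apr observation count, and the
    per-stage removal log.
    """
    cfg = config or FitConfig()
    log = []

    def _stage(name, frame):
        log.append({"stage": name, "n_obs": len(frame)})
        return frame

    _stage("input", obs)
    obs = _stage("quality_masks", apply_quality_masks(obs, cell_inundation_fraction))
    obs = _stage("rfi", filter_rfi(obs))
    obs = _stage("orbit_reconciliation", reconcile_orbits(obs))
    obs = _stage("outliers", remove_outliers(obs))
    log_df = pd.DataFrame(log)
    log_df["n_removed"] = -log_df["n_obs"].diff().fillna(0).astype(int)

    if years is None:
        years = sorted(pd.to_datetime(obs["date"]).dt.year.unique())

    rows = []
    for cell_id, cell_obs in obs.groupby("cell_id"):
        try:
            series = fit_seasonal_trend(cell_obs, cfg)
        except ValueError:
            logger.warning("cell %s skipped: insufficient data for fit", cell_id)
            continue
        dts = pd.to_datetime(cell_obs["date"])
        for year in years:
            lo = pd.Timestamp(year=year, month=1, day=1)
            hi = pd.Timestamp(year=year, month=4, day=30)
            if series.dates[0] > lo or series.dates[-1] < hi:
                continue
            n_win = int(((dts >= lo) & (dts <= hi)).sum())
            idx = annual_indices(series, year, n_obs_used=n_win,
                                 min_window_obs=cfg.min_window_obs)
            if idx is None:
                continue
            rows.append({
                "cell_id": cell_id, "year": year,
                "max_smooth": idx.max_smooth, "mean_smooth": idx.mean_smooth,
                "mean_trend": idx.mean_trend, "n_obs_used": idx.n_obs_used,
            })
    return pd.DataFrame(rows), log_df
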