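"""Plain-text readers/writers for the pipeline's tabular interfaces.

Observation streams, annual index sets and flux tables travel as CSV with
the documented column schemas; calibration curves persist as YAML.  Scene
raster stacks can be saved to NPZ for scratch use.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import CalibrationCurve

__all__ = [
    "write_observations", "read_observations",
    "write_table", "read_table",
    "write_curve", "read_curve",
    "save_scene_npz",
]

_OBS_COLUMNS = ["cell_id", "date", "orbit", "vod", "tb_rmse", "flag"]


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    out = obs[_OBS_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    obs = pd.read_csv(path, parse_dates=["date"])
    missing = set(_OBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"observation file lacks column(s) {sorted(missing)}")
    return obs


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(curve.to_dict(), sort_keys=False))


def read_curve(path: str | Path) -> CalibrationCurve:
    return CalibrationCurve.from_dict(yaml.safe_load(Path(path).read_text()))


def save_scene_npz(scene, path: str | Path) -> None:
    """Raster stack to NPZ (scratch format; rasters are NumPy arrays)."""
    np.savez_compressed(
        path,
        years=np.asarray(scene.years),
        class_rasters=scene.class_rasters,
        degradation_events=scene.degradation_events,
        biomass=scene.biomass,
        inundation_fraction=scene.inundation_fraction,
        affine=np.asarray(scene.grid.affine),
    )
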