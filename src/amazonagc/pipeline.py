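"""End-to-end drivers tying the stages together on one scene.

Two entry points:

* :func:`retrieve_agc_series` -- the top-down chain: daily observations ->
  filters -> seasonal/trend fit -> annual indices -> calibration curves ->
  per-cell annual AGC densities (mean of the three index-based estimates,
  with the anomaly mask applied).
* :func:`run_scene_bookkeeping` -- the bottom-up chain: class/event rasters
  -> forest-state engine -> per-process flux table, attributing old-growth
  change from the top-down series by residual.

The ``agc_series`` argument of the bookkeeping driver accepts either the
retrieved series or a known truth series, so the bookkeeping can be
validated independently of retrieval error.
"""

from __future__ import annotations

import pandas as pd

from . import landcover as lc
from .calibration import (aggregate_reference_map, build_agc_series,
                          fit_vod_agc_curve, mask_anomalous_cells)
from .curves import CalibrationCurve
from .fluxes import BookkeepingConfig, run_bookkeeping
from .lvod import FitConfig, INDEX_METHODS, run_lvod_pipeline
from .synthetic import FineScene, SceneConfig

__all__ = ["calibrate_indices", "retrieve_agc_series", "run_scene_bookkeeping",
           "bookkeeping_config_from_scene"]


def calibrate_indices(indices: pd.DataFrame,
                      scene: FineScene) -> dict[str, CalibrationCurve]:
    """Fit one calibration curve per index method at the reference year.

    Pairs each method's reference-year index values with the reference
    biomass map aggregated to the coarse grid.  Fitting per method absorbs
    each index's own offset (e.g. the seasonal uplift of the smoothed-curve
    indices), which is why the three products carry separate a-d parameters.
    """
    ref = aggregate_reference_map(scene.biomass, scene.grid).ravel()
    sub = indices[indices["year"] == scene.reference_year] \
        .set_index("cell_id").reindex(range(scene.grid.n_cells))
    return {
        m: fit_vod_agc_curve(sub[m].to_numpy(), ref, index_method=m)
        for m in INDEX_METHODS
    }


def retrieve_agc_series(obs: pd.DataFrame,
                        scene: FineScene,
                        curves: dict[str, CalibrationCurve] | CalibrationCurve | None = None,
                        fit_config: FitConfig | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observations -> filtered indices -> calibrated AGC series.

    ``curves`` maps each index method to its calibration curve (a single
    curve is broadcast to all three methods); by default the curves are
    fitted per method against the scene's reference biomass map.  Returns
    ``(agc, rejection_log)`` where ``agc`` has one row per (cell_id, year)
    with ``agc_mean``, ``agc_sd`` and ``masked``.
    """
    inund = pd.Series(scene.inundation_fraction.ravel(),
                      index=scene.grid.cell_ids().ravel())
    indices, log = run_lvod_pipeline(obs, inund, years=list(scene.years),
                                     config=fit_config)
    if curves is None:
        curves = calibrate_indices(indices, scene)
    elif isinstance(curves, CalibrationCurve):
        curves = {m: curves for m in INDEX_METHODS}
    agc = build_agc_series(indices, curves)
    return mask_anomalous_cells(agc), log


def run_scene_bookkeeping(scene: FineScene,
                          agc_series: pd.DataFrame,
                          config: BookkeepingConfig | None = None,
                          vocab: lc.ClassVocabulary | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, list[lc.ForestStateYear]]:
    """Classify a scene and book all five process fluxes.

    Returns ``(flux_table, fractions, states)``.
    """
    states = lc.classify_scene(scene.class_rasters, scene.degradation_events,
                               list(scene.years), scene.grid.pixel_edge_m,
                               vocab=vocab)
    fractions, _ages = lc.aggregate_fractions(states, scene.grid)
    flux = run_bookkeeping(states, fractions, scene.biomass, agc_series,
                           scene.grid, config=config,
                           reference_year=scene.reference_year)
    return flux, fractions, states


def bookkeeping_config_from_scene(config: SceneConfig) -> BookkeepingConfig:
    """Bookkeeping configuration matched to a synthetic scene's truth."""
    return BookkeepingConfig(loss_factor=config.loss_factor,
                             growth=config.growth_curve,
                             edge_curve=config.edge_curve)
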