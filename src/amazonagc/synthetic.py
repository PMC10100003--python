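"""Fully synthetic Amazon-like scenes with known per-process carbon truth.

The generator simulates an annual land-cover history on the fine grid
(clustered deforestation patches, regrowing secondary forest, canopy
degradation events), carries a per-pixel carbon density forward with the
same growth / edge-loss / loss-factor parameterisation the bookkeeping
model is configured with, and emits:

* annual class rasters (old-growth / degraded / secondary forest, pasture,
  agriculture, bare) and degradation-event rasters;
* a static reference biomass raster (the density snapshot at the
  calibration reference year, ESA-CCI-like);
* a daily two-orbit L-VOD observation stream obtained by inverting the
  configured VOD-to-AGC curve on the interpolated true carbon trajectory,
  plus seasonality, Gaussian noise, a constant inter-orbit offset,
  injected RFI spikes and quality flags;
* a :class:`SceneTruth` table of per-cell, per-year, per-process carbon
  stock changes that is additive to the total change by construction.

Because truth densities follow exactly the bookkeeping rules (degraded
pixels sit at (1 - loss_factor) x local old-growth density, edge pixels at
(1 - loss(age)), secondary pixels on the growth curve), a bookkeeping run
with matched parameters recovers every per-process total exactly; tests
exploit this closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .curves import CalibrationCurve, EdgeLossCurve, GrowthCurve
from .grids import GridSpec
from . import landcover as lc

__all__ = ["NoiseConfig", "SceneConfig", "FineScene", "SceneTruth",
           "generate_scene", "generate_lvod_series", "PROCESSES"]

#: The five bookkeeping processes, in reporting order.
PROCESSES = ("deforestation", "edge_degradation", "nonedge_degradation",
             "secondary_growth", "old_growth")

_CODE_OG, _CODE_DEG, _CODE_SEC = 10, 11, 12
_CODES_CLEARED = (21, 22, 23)  # pasture, agriculture, bare

#: Seasonal VOD peak near day-of-year 90 (wet-season canopy water maximum).
_SEASONAL_PHASE = np.pi / 2 - 2 * np.pi * 90.0 / 365.25


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-noise model for the synthetic L-VOD stream.

    Defaults are the study conditions: per-observation Gaussian noise of
    0.02 VOD, a seasonal cycle of amplitude 0.05 VOD, 5% RFI contamination
    (TB-RMSE drawn above the 8 K threshold), a 0.01 constant ASC-DESC
    offset and 2% flagged observations.
    """

    vod_sd: float = 0.02
    seasonal_amplitude: float = 0.05
    rfi_rate: float = 0.05
    rfi_tb_rmse: float = 8.0
    orbit_offset: float = 0.01
    flag_rate: float = 0.02
    nominal_tb_rmse: tuple[float, float] = (2.0, 7.0)

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """Noise-free limit: clean stream, constant nominal TB-RMSE."""
        return cls(vod_sd=0.0, seasonal_amplitude=0.0, rfi_rate=0.0,
                   orbit_offset=0.0, flag_rate=0.0, nominal_tb_rmse=(3.0, 3.0))


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic scene.

    Rates are annual fractions of the eligible area: ``deforestation_rate``
    of current forest is cleared each year (spatially clustered so edges
    exist), ``degradation_rate`` of forest receives a canopy-disturbance
    event, and ``regrowth_rate`` of previously-observed non-forest
    transitions back to (secondary) forest.  ``og_drift`` is a uniform
    old-growth density change (Mg C ha-1 yr-1) used to exercise residual
    attribution; it defaults to zero.
    """

    n_coarse_x: int = 8
    n_coarse_y: int = 8
    fine_per_coarse: int = 64
    years: tuple[int, ...] = tuple(range(2011, 2020))
    deforestation_rate: float = 0.015
    degradation_rate: float = 0.01
    regrowth_rate: float = 0.03
    initial_nonforest: float = 0.10
    og_drift: float = 0.0
    biomass_mean: float = 126.4
    biomass_gradient: float = 0.0       # optional linear E-W density gradient, Mg C ha-1 across scene
    loss_factor: float = 0.353
    growth_params: tuple[float, float, float] = (90.0, 0.06, 1.5)
    edge_params: tuple[float, float] = (0.4, 0.8)
    calib_params: tuple[float, float, float, float] = (170.0, 9.0, 0.45, 5.0)
    reference_year: int | None = None   # defaults to the middle year
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    pixel_edge_m: float = 30.0
    cell_deg: float = 0.25
    patch_sigma_px: float = 3.0         # clustering scale of change patches
    frontier_strength: float = 2.0      # weight of the static deforestation-pressure field
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.years) < 2:
            raise ValueError("a scene needs at least 2 years")
        if list(self.years) != list(range(self.years[0], self.years[-1] + 1)):
            raise ValueError("years must be consecutive")
        for name in ("deforestation_rate", "degradation_rate", "regrowth_rate",
                     "initial_nonforest", "loss_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(nx=self.n_coarse_x, ny=self.n_coarse_y,
                        fine_per_coarse=self.fine_per_coarse,
                        pixel_edge_m=self.pixel_edge_m, cell_deg=self.cell_deg)

    @property
    def growth_curve(self) -> GrowthCurve:
        return GrowthCurve(*self.growth_params)

    @property
    def edge_curve(self) -> EdgeLossCurve:
        return EdgeLossCurve(*self.edge_params)

    @property
    def calibration_curve(self) -> CalibrationCurve:
        a, b, c, d = self.calib_params
        return CalibrationCurve(a=a, b=b, c=c, d=d, index_method="truth")

    @property
    def ref_year(self) -> int:
        return self.reference_year if self.reference_year is not None \
            else self.years[len(self.years) // 2]

    def with_noise(self, **kw) -> "SceneConfig":
        return replace(self, noise=replace(self.noise, **kw))


@dataclass
class FineScene:
    """Annual fine-grid stack: classes, degradation events, static biomass."""

    years: tuple[int, ...]
    class_rasters: np.ndarray        # (n_years, H, W) uint8
    degradation_events: np.ndarray   # (n_years, H, W) bool
    biomass: np.ndarray              # (H, W) Mg C ha-1, reference-year snapshot
    inundation_fraction: np.ndarray  # (ny, nx) in [0, 1]
    grid: GridSpec
    reference_year: int

    def __post_init__(self) -> None:
        if np.any(self.biomass < 0):
            raise ValueError("biomass raster must be non-negative")


@dataclass
class SceneTruth:
    """Known ground truth of a synthetic scene.

    ``fluxes`` has one row per (cell_id, year, process) with the true carbon
    stock change in Mg C (explicit zeros included); ``agc_density`` is the
    true mean density per cell-year in Mg C ha-1.  ``states`` are the
    generator's own per-year state rasters, kept so the land-cover engine
    can be verified against an independent simulation of the same rules.
    """

    fluxes: pd.DataFrame
    agc_density: pd.DataFrame
    states: list[lc.ForestStateYear]
    config: SceneConfig

    def total_change(self) -> pd.DataFrame:
        """Per cell-year total stock change, additive over processes."""
        return (self.fluxes.groupby(["cell_id", "year"], as_index=False)["delta_agc"]
                .sum())

    def biome_series(self) -> pd.DataFrame:
        """Per process-year biome totals (Mg C)."""
        return (self.fluxes.groupby(["process", "year"], as_index=False)["delta_agc"]
                .sum())


# --------------------------------------------------------------------------
# scene simulation
# --------------------------------------------------------------------------

def _clustered_pick(rng: np.random.Generator, eligible: np.ndarray,
                    count: int, sigma: float,
                    pressure: np.ndarray | None = None) -> np.ndarray:
    """Choose ``count`` spatially clustered pixels among ``eligible``.

    ``pressure`` is an optional static large-scale field added to the
    per-call patch noise so that change concentrates in the same region
    year after year (an arc-of-deforestation analogue), leaving most of
    the scene's interior intact.
    """
    out = np.zeros(eligible.shape, dtype=bool)
    n_eligible = int(eligible.sum())
    if count <= 0 or n_eligible == 0:
        return out
    noise = ndimage.gaussian_filter(rng.standard_normal(eligible.shape), sigma)
    if pressure is not None:
        noise = noise + pressure
    if count >= n_eligible:
        return eligible.copy()
    vals = noise[eligible]
    thr = np.partition(vals, -count)[-count]
    picked = eligible & (noise >= thr)
    # continuous field: ties have measure zero, but guard against them
    if picked.sum() > count:
        idx = np.flatnonzero(picked.ravel())
        drop = rng.choice(idx, size=picked.sum() - count, replace=False)
        picked.ravel()[drop] = False
    return picked


def generate_scene(config: SceneConfig) -> tuple[FineScene, SceneTruth]:
    """Simulate a land-cover history and its per-process carbon truth."""
    grid = config.grid
    H, W = grid.fine_shape
    rng = np.random.default_rng(config.seed)
    growth = config.growth_curve
    edge_loss = config.edge_curve
    lf = config.loss_factor
    a_px = grid.pixel_area_ha
    g = config.og_drift

    # local old-growth base density (optionally an E-W gradient)
    base = np.full((H, W), config.biomass_mean, dtype=float)
    if config.biomass_gradient:
        base += config.biomass_gradient * (np.arange(W) / max(W - 1, 1) - 0.5)[None, :]

    # static deforestation-pressure field: human pressure concentrates along
    # a persistent frontier, leaving a mostly intact interior
    pressure = ndimage.gaussian_filter(rng.standard_normal((H, W)),
                                       config.fine_per_coarse)
    sd = pressure.std()
    pressure = config.frontier_strength * (pressure / sd if sd > 0 else pressure)

    # initial year: clustered non-forest (pasture) near the frontier,
    # the rest old-growth
    n_init = int(round(config.initial_nonforest * H * W))
    nonforest = _clustered_pick(rng, np.ones((H, W), dtype=bool), n_init,
                                config.patch_sigma_px, pressure)
    forest = ~nonforest

    # simulation state
    sec_age = np.zeros((H, W), dtype=np.int16)
    edge_age = np.zeros((H, W), dtype=np.int16)
    edge_ever = np.zeros((H, W), dtype=bool)
    degraded = np.zeros((H, W), dtype=bool)
    deforested_ever = np.zeros((H, W), dtype=bool)
    nonforest_seen = nonforest.copy()
    density = np.where(forest, base, 0.0)

    # independent edge mechanism: binary dilation with an inclusive
    # Euclidean disk (radius = buffer / pixel edge), vs. the engine's
    # distance transform
    r_px = lc.EDGE_BUFFER_M / config.pixel_edge_m
    r_int = int(np.floor(r_px + 1e-9))
    yy, xx = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    disk = np.hypot(yy, xx) <= r_px + 1e-9

    classes = np.where(forest, _CODE_OG, _CODES_CLEARED[0]).astype(np.uint8)
    class_rasters = np.zeros((len(config.years), H, W), dtype=np.uint8)
    event_rasters = np.zeros((len(config.years), H, W), dtype=bool)
    class_rasters[0] = classes

    flux = {p: np.zeros((len(config.years), grid.ny, grid.nx)) for p in PROCESSES}
    density_snapshots = [grid.coarsen_mean(density)]
    states: list[lc.ForestStateYear] = []
    states.append(lc.ForestStateYear(
        year=config.years[0],
        state=np.where(forest, lc.STATE_OLDGROWTH, lc.STATE_NONFOREST).astype(np.uint8),
        secondary_age=sec_age.copy(), edge_age=edge_age.copy(),
        newly_deforested=np.zeros((H, W), dtype=bool),
        new_degradation=np.zeros((H, W), dtype=bool)))
    biomass_snapshot = density.copy() if config.ref_year == config.years[0] else None

    for t, year in enumerate(config.years[1:], start=1):
        # --- deforestation: clustered clearing of current forest
        n_clear = int(round(config.deforestation_rate * forest.sum()))
        cleared = _clustered_pick(rng, forest, n_clear, config.patch_sigma_px,
                                  pressure)
        flux["deforestation"][t] = -grid.coarsen_sum(density * cleared) * a_px
        density[cleared] = 0.0
        target = rng.integers(0, len(_CODES_CLEARED), size=(H, W))
        classes = classes.copy()
        for i, code in enumerate(_CODES_CLEARED):
            classes[cleared & (target == i)] = code
        deforested_ever |= cleared
        sec_age[cleared] = 0
        degraded[cleared] = False
        edge_ever[cleared] = False
        edge_age[cleared] = 0

        # --- regrowth: previously-observed non-forest back to forest
        regrow_eligible = ~forest & ~cleared
        n_regrow = int(round(config.regrowth_rate * regrow_eligible.sum()))
        regrown = _clustered_pick(rng, regrow_eligible, n_regrow,
                                  config.patch_sigma_px)
        forest = (forest & ~cleared) | regrown

        # --- secondary forest ageing (and new regrowth at age 1)
        persisting = forest & (sec_age > 0) & ~regrown
        inc = np.zeros((H, W))
        inc[persisting] = growth(sec_age[persisting] + 1) - growth(sec_age[persisting])
        inc[regrown] = growth(1)
        flux["secondary_growth"][t] = grid.coarsen_sum(inc) * a_px
        density += inc
        sec_age = np.where(forest & ((sec_age > 0) | regrown), sec_age + 1, 0).astype(np.int16)
        nonforest_seen |= ~forest
        secondary = sec_age > 0

        # --- 120 m edge zones around deforested (still cleared) land
        src = deforested_ever & ~forest
        zone = ndimage.binary_dilation(src, structure=disk) & forest \
            & ~secondary & ~degraded
        aged = zone.copy()
        edge_inc = np.zeros((H, W))
        edge_inc[aged] = base[aged] * (edge_loss(edge_age[aged] + 1)
                                       - edge_loss(edge_age[aged]))
        flux["edge_degradation"][t] = -grid.coarsen_sum(edge_inc) * a_px
        density -= edge_inc
        edge_age = np.where(aged, edge_age + 1, edge_age).astype(np.int16)
        edge_ever |= zone
        edge = edge_ever & forest

        # --- canopy degradation events (TMF-like); only events on
        #     undisturbed old-growth forest create new non-edge losses
        n_events = int(round(config.degradation_rate * forest.sum()))
        events = _clustered_pick(rng, forest, n_events, config.patch_sigma_px,
                                 pressure)
        event_rasters[t] = events
        accepted = events & ~edge_ever & ~secondary & ~degraded
        flux["nonedge_degradation"][t] = -grid.coarsen_sum(
            np.where(accepted, base * lf, 0.0)) * a_px
        density -= np.where(accepted, base * lf, 0.0)
        degraded |= accepted

        # --- old-growth drift
        old_growth = forest & ~secondary & ~degraded & ~edge
        if g:
            flux["old_growth"][t] = g * grid.coarsen_sum(old_growth) * a_px
            density += np.where(old_growth, g, 0.0)

        # --- emit class raster and bookkeeping snapshots
        classes[old_growth] = _CODE_OG
        classes[forest & (degraded | edge)] = _CODE_DEG
        classes[secondary] = _CODE_SEC
        class_rasters[t] = classes
        density_snapshots.append(grid.coarsen_mean(density))

        state = np.full((H, W), lc.STATE_NONFOREST, dtype=np.uint8)
        state[old_growth] = lc.STATE_OLDGROWTH
        state[forest & degraded] = lc.STATE_DEGRADED
        state[edge] = lc.STATE_EDGE
        state[secondary] = lc.STATE_SECONDARY
        states.append(lc.ForestStateYear(
            year=year, state=state,
            secondary_age=np.where(secondary, sec_age, 0).astype(np.int16),
            edge_age=np.where(edge, edge_age, 0).astype(np.int16),
            newly_deforested=cleared, new_degradation=accepted))
        if year == config.ref_year:
            biomass_snapshot = density.copy()

    if biomass_snapshot is None:  # reference year outside the simulated span
        raise ValueError(f"reference year {config.ref_year} not in {config.years}")

    # --- assemble truth tables
    ids = grid.cell_ids().ravel()
    rows = []
    for t, year in enumerate(config.years):
        if t == 0:
            continue
        for p in PROCESSES:
            rows.append(pd.DataFrame({
                "cell_id": ids, "year": year, "process": p,
                "delta_agc": flux[p][t].ravel(),
            }))
    fluxes = pd.concat(rows, ignore_index=True)
    agc = pd.concat([
        pd.DataFrame({"cell_id": ids, "year": year,
                      "agc_mgc_ha": density_snapshots[t].ravel()})
        for t, year in enumerate(config.years)
    ], ignore_index=True)

    scene = FineScene(
        years=config.years, class_rasters=class_rasters,
        degradation_events=event_rasters,
        biomass=biomass_snapshot,
        inundation_fraction=np.zeros((grid.ny, grid.nx)),
        grid=grid, reference_year=config.ref_year)
    return scene, SceneTruth(fluxes=fluxes, agc_density=agc, states=states,
                             config=config)


# --------------------------------------------------------------------------
# L-VOD observation stream
# --------------------------------------------------------------------------

#: Day-of-year at which the annual truth density is anchored (middle of the
#: January-April index window).
ANCHOR_DOY = 59


def generate_lvod_series(scene: FineScene, truth: SceneTruth,
                         config: SceneConfig,
                         saturation_margin: float = 0.03) -> pd.DataFrame:
    """Daily two-orbit L-VOD observations for every coarse cell.

    The clean signal is the inverse of the configured VOD-AGC curve applied
    to a piecewise-linear interpolation of the true annual cell densities
    (anchored at the middle of each year's Jan-Apr window), plus a
    sinusoidal seasonal term, Gaussian noise, a constant +/- offset split
    between ascending and descending orbits, RFI spikes with TB-RMSE above
    the configured threshold, and randomly flagged observations.

    Densities are clamped to the curve's invertible range, staying
    ``saturation_margin`` x (a - d) away from the asymptotes -- the
    observation operator saturates for cells outside the representable
    range, as a real retrieval does.  Pass ``saturation_margin=0`` to
    raise instead when a density is not invertible.
    """
    noise = config.noise
    curve = config.calibration_curve
    rng = np.random.default_rng(config.seed + 1_000_003)
    years = list(config.years)

    start = np.datetime64(f"{years[0]}-01-01")
    end = np.datetime64(f"{years[-1]}-12-31")
    dates = np.arange(start, end + 1)
    t_days = (dates - start).astype(float)
    doy = (dates - dates.astype("datetime64[Y]")).astype(float)
    anchors_t = np.array([
        (np.datetime64(f"{y}-01-01") - start).astype(float) + ANCHOR_DOY
        for y in years
    ])
    seasonal = noise.seasonal_amplitude * np.sin(
        2 * np.pi * doy / 365.25 + _SEASONAL_PHASE)

    agc = truth.agc_density.pivot(index="cell_id", columns="year",
                                  values="agc_mgc_ha")
    asc_idx = np.arange(0, len(dates), 2)
    desc_idx = np.arange(1, len(dates), 2)

    frames = []
    lo = min(curve.a, curve.d) + saturation_margin * abs(curve.a - curve.d)
    hi = max(curve.a, curve.d) - saturation_margin * abs(curve.a - curve.d)
    for cell_id in agc.index:
        daily_agc = np.interp(t_days, anchors_t, agc.loc[cell_id, years].to_numpy())
        if saturation_margin > 0:
            daily_agc = np.clip(daily_agc, lo, hi)
        vod_clean = curve.inverse(daily_agc) + seasonal
        for orbit, idx, off in (("ASC", asc_idx, +0.5), ("DESC", desc_idx, -0.5)):
            n = len(idx)
            vod = vod_clean[idx] + off * noise.orbit_offset
            if noise.vod_sd > 0:
                vod = vod + rng.normal(0.0, noise.vod_sd, n)
            tb = rng.uniform(*noise.nominal_tb_rmse, n)
            rfi = rng.random(n) < noise.rfi_rate
            if rfi.any():
                tb[rfi] = rng.uniform(noise.rfi_tb_rmse, 20.0, rfi.sum())
                vod[rfi] += rng.uniform(0.05, 0.3, rfi.sum())
            vod = np.maximum(vod, 0.0)  # VOD is non-negative by definition
            flag = np.where(rng.random(n) < noise.flag_rate,
                            rng.integers(1, 8, n), 0)
            frames.append(pd.DataFrame({
                "cell_id": cell_id, "date": dates[idx], "orbit": orbit,
                "vod": vod, "tb_rmse": tb, "flag": flag,
            }))
    obs = pd.concat(frames, ignore_index=True)
    obs["date"] = pd.to_datetime(obs["date"])
    return obs.sort_values(["cell_id", "date", "orbit"], ignore_index=True)
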