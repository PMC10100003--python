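"""Annual forest-state engine on the fine grid.

From a stack of annual land-cover class rasters plus a degradation-event
raster, this module derives, year by year:

* newly deforested pixels (forest in the previous year -> pasture,
  agriculture or bare land this year);
* secondary forest and its age (consecutive forest years after at least one
  observed non-forest year; regrowth predating the record is undetectable);
* 120 m edge zones around deforested land, with edge age;
* new non-edge degradation events (events falling in edge zones are excluded
  from the degradation record);
* the old-growth layer (forest never degraded, never edge, never secondary);

and finally aggregates the per-pixel states to fractional covers per coarse
cell.  All cross-dataset logic runs at the native fine resolution before any
aggregation.

State precedence
----------------
Each forest pixel carries exactly one state.  Non-edge degradation and
secondary status are "sticky" and take precedence over later edge-zone
membership: a pixel that is already degraded (or is regrowing secondary
forest) does not additionally enter the edge class, and new degradation
events on edge pixels are ignored.  This keeps the carbon bookkeeping
conservative -- no pixel accrues both the 35.3% event loss and the
edge-age loss, and low-biomass secondary pixels are never debited with
old-growth-referenced edge losses.  Deforestation trumps everything: the
pixel moves to non-forest in the detection year and its forest history
(age counters, degradation status) is reset; if it later regrows it
re-enters as age-1 secondary forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec

__all__ = [
    "STATE_NONFOREST",
    "STATE_OLDGROWTH",
    "STATE_DEGRADED",
    "STATE_EDGE",
    "STATE_SECONDARY",
    "ClassVocabulary",
    "ForestStateYear",
    "detect_deforestation",
    "update_secondary_forest",
    "compute_edge_zones",
    "extract_degradation_events",
    "derive_old_growth",
    "classify_scene",
    "aggregate_fractions",
]

# Per-pixel state codes (exactly one per pixel per year).
STATE_NONFOREST = 0
STATE_OLDGROWTH = 1
STATE_DEGRADED = 2  # non-edge degradation event, pixel still forested
STATE_EDGE = 3      # forest within 120 m of a deforested edge (ever)
STATE_SECONDARY = 4

#: Buffer distance of edge-affected forest from deforested land, metres.
EDGE_BUFFER_M = 120.0


@dataclass(frozen=True)
class ClassVocabulary:
    """Mapping between integer land-cover codes and class names.

    The defaults match the synthetic scene generator; real Mapbiomas/TMF
    codes can be remapped via :meth:`from_dict` / a YAML mapping without
    touching any other code.
    """

    names: dict[int, str] = field(default_factory=lambda: {
        10: "old_growth_forest",
        11: "degraded_forest",
        12: "secondary_forest",
        21: "pasture",
        22: "agriculture",
        23: "bare",
    })
    forest_names: frozenset[str] = frozenset(
        {"old_growth_forest", "degraded_forest", "secondary_forest"}
    )
    deforestation_target_names: frozenset[str] = frozenset(
        {"pasture", "agriculture", "bare"}
    )

    @property
    def forest_codes(self) -> np.ndarray:
        return np.array(sorted(c for c, n in self.names.items() if n in self.forest_names))

    @property
    def deforestation_target_codes(self) -> np.ndarray:
        return np.array(sorted(
            c for c, n in self.names.items() if n in self.deforestation_target_names
        ))

    @property
    def known_codes(self) -> np.ndarray:
        return np.array(sorted(self.names))

    def validate(self, raster: np.ndarray) -> None:
        unknown = np.setdiff1d(np.unique(raster), self.known_codes)
        if unknown.size:
            raise ValueError(f"unknown land-cover class code(s): {unknown.tolist()}")

    def is_forest(self, raster: np.ndarray) -> np.ndarray:
        return np.isin(raster, self.forest_codes)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ClassVocabulary":
        return cls(
            names={int(k): str(v) for k, v in mapping["names"].items()},
            forest_names=frozenset(mapping.get(
                "forest_names", ["old_growth_forest", "degraded_forest", "secondary_forest"])),
            deforestation_target_names=frozenset(mapping.get(
                "deforestation_target_names", ["pasture", "agriculture", "bare"])),
        )


@dataclass
class ForestStateYear:
    """Per-pixel forest state for one year."""

    year: int
    state: np.ndarray            # uint8, STATE_* codes
    secondary_age: np.ndarray    # int16, >=1 iff state == SECONDARY
    edge_age: np.ndarray         # int16, >=1 iff state == EDGE
    newly_deforested: np.ndarray  # bool
    new_degradation: np.ndarray   # bool, accepted non-edge events this year
    ignored_events: dict[str, int] = field(default_factory=dict)


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def detect_deforestation(
    classes_prev: np.ndarray,
    classes_curr: np.ndarray,
    vocab: ClassVocabulary | None = None,
) -> np.ndarray:
    """Pixels that changed from forest to pasture/agriculture/bare."""
    vocab = vocab or ClassVocabulary()
    vocab.validate(classes_prev)
    vocab.validate(classes_curr)
    was_forest = vocab.is_forest(classes_prev)
    now_cleared = np.isin(classes_curr, vocab.deforestation_target_codes)
    return was_forest & now_cleared


def update_secondary_forest(
    class_history: list[np.ndarray],
    vocab: ClassVocabulary | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Secondary-forest extent and age after the last year of ``class_history``.

    A pixel is secondary if it was non-forest in some observed year and has
    been forest continuously since; its age is the number of consecutive
    forest years (1 in the first forest year).  Pixels forested throughout
    the record are never secondary -- regrowth that began before the record
    cannot be identified.
    """
    if len(class_history) < 2:
        raise ValueError("secondary-forest derivation needs >= 2 years of history")
    vocab = vocab or ClassVocabulary()
    nonforest_seen = ~vocab.is_forest(class_history[0])
    age = np.zeros(class_history[0].shape, dtype=np.int16)
    for classes in class_history[1:]:
        forest = vocab.is_forest(classes)
        growing = forest & (nonforest_seen | (age > 0))
        age = np.where(growing, age + 1, 0).astype(np.int16)
        nonforest_seen |= ~forest
    return age > 0, age


def compute_edge_zones(
    forest: np.ndarray,
    deforested: np.ndarray,
    prior_edge_age: np.ndarray,
    prior_edge_ever: np.ndarray,
    pixel_edge_m: float,
    exclude: np.ndarray | None = None,
    buffer_m: float = EDGE_BUFFER_M,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Annual 120 m edge classification.

    Forest pixels whose center lies within ``buffer_m`` (inclusive,
    Euclidean) of any deforested pixel are in this year's edge *zone*.
    Edge membership is a ratchet (``edge_ever``); edge age increments only
    while the pixel remains inside the current zone and is frozen if the
    adjacent clearing regrows.

    Returns ``(edge, edge_age, edge_ever, zone)``.
    """
    if deforested.any():
        dist_px = ndimage.distance_transform_edt(~deforested)
    else:
        dist_px = np.full(deforested.shape, np.inf)
    zone = forest & (dist_px * pixel_edge_m <= buffer_m + 1e-9)
    if exclude is not None:
        zone &= ~exclude
    edge_ever = prior_edge_ever | zone
    edge = edge_ever & forest
    if exclude is not None:
        edge &= ~exclude
    edge_age = np.where(zone, prior_edge_age + 1, prior_edge_age).astype(np.int16)
    edge_age = np.where(edge | zone, edge_age, prior_edge_age).astype(np.int16)
    return edge, edge_age, edge_ever, zone


def extract_degradation_events(
    events: np.ndarray,
    forest: np.ndarray,
    edge_ever: np.ndarray,
    secondary: np.ndarray,
    baseline: np.ndarray,
    recurrent_degradation_losses: bool = False,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """New non-edge degradation this year, plus the updated sticky baseline.

    Events on non-forest, edge or secondary pixels are ignored (counted);
    repeat events on already-degraded pixels are ignored by default
    (``recurrent_degradation_losses`` books them again as new losses).
    """
    ignored = {
        "nonforest": int((events & ~forest).sum()),
        "edge": int((events & forest & edge_ever).sum()),
        "secondary": int((events & forest & ~edge_ever & secondary).sum()),
    }
    eligible = events & forest & ~edge_ever & ~secondary
    if recurrent_degradation_losses:
        accepted = eligible
        ignored["repeat"] = 0
    else:
        accepted = eligible & ~baseline
        ignored["repeat"] = int((eligible & baseline).sum())
    return accepted, baseline | accepted, ignored


def derive_old_growth(
    forest: np.ndarray,
    degraded_baseline: np.ndarray,
    secondary: np.ndarray,
    edge: np.ndarray,
) -> np.ndarray:
    """Forest never degraded, never edge-affected and not secondary."""
    return forest & ~degraded_baseline & ~secondary & ~edge


# --------------------------------------------------------------------------
# scene driver
# --------------------------------------------------------------------------

def classify_scene(
    class_rasters: np.ndarray,
    event_rasters: np.ndarray,
    years: list[int],
    pixel_edge_m: float,
    vocab: ClassVocabulary | None = None,
    baseline_degraded: np.ndarray | None = None,
    recurrent_degradation_losses: bool = False,
) -> list[ForestStateYear]:
    """Run the full annual state machine over a class/event raster stack.

    ``class_rasters`` and ``event_rasters`` are (n_years, H, W); the event
    raster marks canopy-disturbance detections (TMF-like).  The optional
    ``baseline_degraded`` seeds the sticky degraded set from events that
    predate the record.
    """
    vocab = vocab or ClassVocabulary()
    n_years = len(years)
    if class_rasters.shape[0] != n_years or event_rasters.shape[0] != n_years:
        raise ValueError("class/event raster stacks must have one layer per year")
    shape = class_rasters.shape[1:]

    forest_prev = vocab.is_forest(class_rasters[0])
    nonforest_seen = ~forest_prev
    sec_age = np.zeros(shape, dtype=np.int16)
    degraded = np.zeros(shape, dtype=bool) if baseline_degraded is None else baseline_degraded.copy()
    deforested_ever = np.zeros(shape, dtype=bool)
    edge_ever = np.zeros(shape, dtype=bool)
    edge_age = np.zeros(shape, dtype=np.int16)

    states: list[ForestStateYear] = []
    for t, year in enumerate(years):
        classes = class_rasters[t]
        vocab.validate(classes)
        forest = vocab.is_forest(classes)

        if t == 0:
            newly_def = np.zeros(shape, dtype=bool)
        else:
            newly_def = detect_deforestation(class_rasters[t - 1], classes, vocab)
            deforested_ever |= newly_def
            # deforestation resets the pixel's forest history
            reset = newly_def
            sec_age[reset] = 0
            degraded[reset] = False
            edge_ever[reset] = False
            edge_age[reset] = 0
            # secondary ageing: consecutive forest years after observed non-forest
            growing = forest & (nonforest_seen | (sec_age > 0))
            sec_age = np.where(growing, sec_age + 1, 0).astype(np.int16)

        nonforest_seen |= ~forest
        secondary = sec_age > 0

        deforested_now = deforested_ever & ~forest  # regrown pixels stop being edge sources
        edge, edge_age, edge_ever, _zone = compute_edge_zones(
            forest, deforested_now, edge_age, edge_ever, pixel_edge_m,
            exclude=secondary | degraded,
        )

        accepted, degraded, ignored = extract_degradation_events(
            event_rasters[t].astype(bool), forest, edge_ever, secondary, degraded,
            recurrent_degradation_losses,
        )

        degraded_now = degraded & forest
        old_growth = derive_old_growth(forest, degraded, secondary, edge)

        state = np.full(shape, STATE_NONFOREST, dtype=np.uint8)
        state[old_growth] = STATE_OLDGROWTH
        state[degraded_now] = STATE_DEGRADED
        state[edge] = STATE_EDGE
        state[secondary] = STATE_SECONDARY

        states.append(ForestStateYear(
            year=year,
            state=state,
            secondary_age=np.where(secondary, sec_age, 0).astype(np.int16),
            edge_age=np.where(edge, edge_age, 0).astype(np.int16),
            newly_deforested=newly_def,
            new_degradation=accepted,
            ignored_events=ignored,
        ))
        forest_prev = forest
    return states


def aggregate_fractions(
    states: list[ForestStateYear],
    grid: GridSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractional covers per coarse cell and year.

    Returns ``(fractions, secondary_ages)``: the first frame has one row per
    (cell_id, year) with the five state fractions (summing to 1) and the cell
    area in hectares; the second carries the secondary-forest age histogram
    as fractions of the cell.
    """
    npx = grid.fine_per_coarse**2
    ids = grid.cell_ids().ravel()
    rows = []
    age_rows = []
    for s in states:
        fracs = {
            "f_oldgrowth": grid.coarsen_sum(s.state == STATE_OLDGROWTH) / npx,
            "f_degraded": grid.coarsen_sum(s.state == STATE_DEGRADED) / npx,
            "f_edge": grid.coarsen_sum(s.state == STATE_EDGE) / npx,
            "f_secondary": grid.coarsen_sum(s.state == STATE_SECONDARY) / npx,
            "f_nonforest": grid.coarsen_sum(s.state == STATE_NONFOREST) / npx,
        }
        frame = pd.DataFrame({
            "cell_id": ids,
            "year": s.year,
            **{k: v.ravel() for k, v in fracs.items()},
            "area_ha": grid.cell_area_ha,
        })
        rows.append(frame)
        for age in np.unique(s.secondary_age[s.secondary_age > 0]):
            counts = grid.coarsen_sum(s.secondary_age == age)
            nz = counts.ravel() > 0
            if nz.any():
                age_rows.append(pd.DataFrame({
                    "cell_id": ids[nz],
                    "year": s.year,
                    "age": int(age),
                    "fraction": counts.ravel()[nz] / npx,
                }))
    fractions = pd.concat(rows, ignore_index=True)
    ages = (pd.concat(age_rows, ignore_index=True) if age_rows
            else pd.DataFrame(columns=["cell_id", "year", "age", "fraction"]))
    return fractions, ages
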