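"""Full top-down vs bottom-up carbon accounting on one scene.

Runs the complete chain: simulate the scene and its L-VOD stream, retrieve
annual AGC per cell (filters -> decomposition -> per-method calibration),
classify the land-cover stack into forest states, book per-process fluxes,
and attribute old-growth change by residual in >90% old-growth cells.
Prints modeled vs true biome fluxes and verifies the residual-attribution
closure property.
"""

import numpy as np

from amazonagc import (SceneConfig, bookkeeping_config_from_scene,
                       generate_lvod_series, generate_scene,
                       retrieve_agc_series, run_scene_bookkeeping)

config = SceneConfig(seed=7)
scene, truth = generate_scene(config)
obs = generate_lvod_series(scene, truth, config)
agc, log = retrieve_agc_series(obs, scene)
flux, fractions, states = run_scene_bookkeeping(
    scene, agc, config=bookkeeping_config_from_scene(config))

model = flux.groupby("process")["delta_agc"].sum()
true = truth.fluxes.groupby("process")["delta_agc"].sum()
print("biome totals over the record (Mg C):")
print(f"{'process':<22}{'modeled':>12}{'truth':>12}")
for p in true.index:
    print(f"{p:<22}{model[p]:>12,.0f}{true[p]:>12,.0f}")
print(f"{'total':<22}{model.sum():>12,.0f}{true.sum():>12,.0f}")

# closure: in >90% old-growth cells the model reproduces the L-VOD change
lv = agc.pivot(index="cell_id", columns="year", values="agc_mean")
tot = flux.groupby(["cell_id", "year"])["delta_agc"].sum()
f_og = fractions.set_index(["cell_id", "year"])["f_oldgrowth"]
area = scene.grid.cell_area_ha
errs = [abs(v - (lv.loc[c, y] - lv.loc[c, y - 1]) * area)
        for (c, y), v in tot.items()
        if f_og.loc[(c, y)] > 0.9 and np.isfinite(lv.loc[c, y - 1])]
print(f"\nclosure in {len(errs)} reference cell-years: "
      f"max |modeled - top-down| = {max(errs):.2e} Mg C (exact by construction)")
print("Clearing and degradation losses dominate; the raster-driven processes "
      "are recovered exactly, the residual old-growth term carries the "
      "retrieval noise.")
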