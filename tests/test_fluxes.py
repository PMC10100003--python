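"""Bookkeeping arithmetic, circular-median oracle, residual attribution."""

import numpy as np
import pandas as pd
import pytest

from amazonagc import (GridSpec, bookkeeping_config_from_scene, circular_median,
                       edge_degradation_flux, loss_factor,
                       lvod_oldgrowth_change_reference,
                       nonedge_degradation_flux, old_growth_flux,
                       regional_reference_agc, run_scene_bookkeeping,
                       secondary_growth_flux, total_modeled_change)
from amazonagc.curves import EdgeLossCurve, GrowthCurve
from amazonagc.synthetic import PROCESSES


class TestLossFactor:
    def test_reference_medians_give_35_3_percent(self):
        """Old-growth 126.4 vs degraded 81.78 Mg C ha-1 -> 35.3% reduction."""
        assert loss_factor(126.4, 81.78) * 100 == pytest.approx(35.3, abs=0.05)

    def test_halving(self):
        assert loss_factor(200.0, 100.0) == 0.5

    def test_degenerate_equal_medians_rejected(self):
        with pytest.raises(ValueError):
            loss_factor(100.0, 100.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            loss_factor(0.0, -1.0)


def _brute_force_median(values, grid, radius_deg):
    """Independent window oracle: explicit loop over cell-center distances."""
    cx, cy = grid.cell_centers_deg()
    vals = np.asarray(values, float)
    out = np.full((grid.ny, grid.nx), np.nan)
    for i in range(grid.ny):
        for j in range(grid.nx):
            members = []
            for k in range(grid.ny):
                for l in range(grid.nx):
                    d = np.hypot(cx[i, j] - cx[k, l], cy[i, j] - cy[k, l])
                    if d <= radius_deg + 1e-12 and np.isfinite(vals[k, l]):
                        members.append(vals[k, l])
            if members:
                out[i, j] = np.median(members)
    return out


class TestCircularMedian:
    def test_simple_median(self):
        grid = GridSpec(nx=3, ny=1, fine_per_coarse=4)
        vals = np.array([[100.0, 120.0, 140.0]])
        out = circular_median(vals, grid, radius_deg=1.0)
        assert out[0, 1] == 120.0

    def test_matches_brute_force_oracle(self):
        grid = GridSpec(nx=7, ny=6, fine_per_coarse=4)
        rng = np.random.default_rng(5)
        vals = rng.normal(100, 20, (6, 7))
        vals[rng.random((6, 7)) < 0.3] = np.nan
        for radius in (0.3, 0.6, 1.0, 2.5):
            expected = _brute_force_median(vals, grid, radius)
            got = circular_median(vals, grid, radius)
            np.testing.assert_array_equal(np.isnan(got), np.isnan(expected))
            np.testing.assert_allclose(got[np.isfinite(got)],
                                       expected[np.isfinite(expected)])


class TestRegionalReference:
    def test_uniform_field_returns_constant(self):
        grid = GridSpec(nx=4, ny=4, fine_per_coarse=4)
        ref, flagged = regional_reference_agc(
            np.full((4, 4), 130.0), np.ones((4, 4)), grid)
        np.testing.assert_allclose(ref, 130.0)
        assert not flagged.any()

    def test_only_high_og_cells_donate(self):
        grid = GridSpec(nx=3, ny=1, fine_per_coarse=4)
        agc = np.array([[100.0, 999.0, 100.0]])
        f_og = np.array([[0.95, 0.5, 0.95]])  # the 999 cell is not a donor
        ref, _ = regional_reference_agc(agc, f_og, grid, radius_deg=1.0)
        np.testing.assert_allclose(ref, 100.0)

    def test_widening_then_flagging(self):
        grid = GridSpec(nx=8, ny=1, fine_per_coarse=4, cell_deg=1.0)
        agc = np.full((1, 8), np.nan)
        agc[0, 0] = 120.0
        f_og = np.zeros((1, 8)); f_og[0, 0] = 0.99
        ref, flagged = regional_reference_agc(agc, f_og, grid,
                                              radius_deg=1.0, widen_deg=2.0)
        assert ref[0, 1] == 120.0 and ref[0, 2] == 120.0  # within 2 deg
        assert flagged[0, 5] and np.isnan(ref[0, 5])


class TestResidualAttribution:
    def test_residual_arithmetic(self):
        grid = GridSpec(nx=1, ny=1, fine_per_coarse=4)
        dref, flagged = lvod_oldgrowth_change_reference(
            np.array([[-2.0]]), np.array([[-1.5]]), np.array([[0.95]]),
            np.array([[1.0]]), grid)
        assert dref[0, 0] == pytest.approx(-0.5)
        assert not flagged.any()

    def test_zero_processes_residual_equals_lvod_change(self):
        grid = GridSpec(nx=2, ny=2, fine_per_coarse=4)
        dl = np.array([[-3.0, -1.0], [2.0, 0.5]])
        dref, _ = lvod_oldgrowth_change_reference(
            dl, np.zeros((2, 2)), np.full((2, 2), 0.95), np.ones((2, 2)), grid)
        np.testing.assert_allclose(dref, dl)

    def test_two_step_widening_fills_non_reference_cells(self):
        grid = GridSpec(nx=5, ny=1, fine_per_coarse=4, cell_deg=2.0)
        f_og = np.array([[0.95, 0.2, 0.2, 0.2, 0.2]])
        dl = np.array([[-4.0, 0, 0, 0, 0.0]])
        dref, flagged = lvod_oldgrowth_change_reference(
            dl, np.zeros((1, 5)), f_og, np.ones((1, 5)), grid,
            radii_deg=(2.5, 5.0))
        assert dref[0, 1] == -4.0      # within 2.5 deg
        assert dref[0, 2] == -4.0      # via the 5 deg fallback
        assert flagged[0, 4]           # beyond 5 deg: excluded


class TestPerProcessArithmetic:
    def test_nonedge_loss_at_reference_and_factor(self):
        """100 ha at reference 126.4 and factor 0.353 -> -4462.3 Mg C."""
        grid = GridSpec(nx=1, ny=1, fine_per_coarse=4, pixel_edge_m=250.0)
        # 16 px x 6.25 ha = 100 ha
        events = np.ones((4, 4), dtype=bool)
        out = nonedge_degradation_flux(events, np.array([[126.4]]), 0.353, grid)
        assert out[0, 0] == pytest.approx(-4462.3, abs=0.5)

    def test_edge_increment_is_loss_difference(self):
        grid = GridSpec(nx=1, ny=1, fine_per_coarse=4, pixel_edge_m=100.0)
        curve = EdgeLossCurve(max_loss=0.4, rate=0.8)
        age = np.full((4, 4), 2, np.int16)
        prior = np.full((4, 4), 1, np.int16)
        out = edge_degradation_flux(age, prior, np.array([[100.0]]), curve, grid)
        expected = -(curve(2) - curve(1)) * 100.0 * 16 * 1.0  # 1 ha pixels
        assert out[0, 0] == pytest.approx(expected)

    def test_edge_increments_telescope_to_total_loss(self):
        grid = GridSpec(nx=1, ny=1, fine_per_coarse=4, pixel_edge_m=100.0)
        curve = EdgeLossCurve(max_loss=0.4, rate=0.8)
        total = 0.0
        for a in range(1, 9):
            age = np.full((4, 4), a, np.int16)
            prior = np.full((4, 4), a - 1, np.int16)
            total += edge_degradation_flux(age, prior, np.array([[100.0]]),
                                           curve, grid)[0, 0]
        assert total == pytest.approx(-curve(8) * 100.0 * 16)

    def test_saturated_edge_curve_adds_nothing(self):
        grid = GridSpec(nx=1, ny=1, fine_per_coarse=4)
        curve = EdgeLossCurve(max_loss=0.4, rate=50.0)  # saturates at age 1
        age = np.full((4, 4), 9, np.int16)
        prior = np.full((4, 4), 8, np.int16)
        out = edge_degradation_flux(age, prior, np.array([[100.0]]), curve, grid)
        assert out[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_secondary_growth_increment(self):
        grid = GridSpec(nx=1, ny=1, fine_per_coarse=4, pixel_edge_m=100.0)
        g = GrowthCurve(90.0, 0.06, 1.5)
        age = np.zeros((4, 4), np.int16); age[0, 0] = 4
        prior = np.zeros((4, 4), np.int16); prior[0, 0] = 3
        out = secondary_growth_flux(age, prior, g, grid)
        assert out[0, 0] == pytest.approx((g(4) - g(3)) * 1.0)

    def test_no_secondary_forest_zero_flux(self):
        grid = GridSpec(nx=1, ny=1, fine_per_coarse=4)
        z = np.zeros((4, 4), np.int16)
        assert secondary_growth_flux(z, z, GrowthCurve(), grid).sum() == 0.0

    def test_old_growth_flux_arithmetic(self):
        out = old_growth_flux(np.array([[-0.5]]), np.array([[50_000.0]]))
        assert out[0, 0] == -25_000.0
        out = old_growth_flux(np.array([[-0.5]]), np.array([[0.0]]))
        assert out[0, 0] == 0.0


class TestTotals:
    def test_sum_and_units(self):
        flux = pd.DataFrame({
            "cell_id": 0, "year": 2015,
            "process": list(PROCESSES),
            "delta_agc": [-10.0, -5.0, -3.0, 4.0, -1.0],
        })
        cell, biome = total_modeled_change(flux)
        assert cell["delta_agc"].iloc[0] == -15.0
        tot = biome[biome.process == "total"].iloc[0]
        assert tot["delta_agc_tg"] == pytest.approx(-15.0 / 1e6)
        assert tot["delta_agc_pg"] == pytest.approx(-15.0 / 1e9)

    def test_empty_table(self):
        cell, biome = total_modeled_change(pd.DataFrame(
            columns=["cell_id", "year", "process", "delta_agc"]))
        assert cell.empty and biome.empty


@pytest.fixture(scope="module")
def run(small_scene):
    scene, truth = small_scene
    cfg = bookkeeping_config_from_scene(truth.config)
    flux, fractions, states = run_scene_bookkeeping(
        scene, truth.agc_density, config=cfg)
    return scene, truth, flux, fractions


class TestSceneBookkeeping:
    def test_sign_discipline(self, run):
        _, _, flux, _ = run
        by = flux.set_index("process")
        assert (by.loc["deforestation", "delta_agc"] <= 0).all()
        assert (by.loc["edge_degradation", "delta_agc"] <= 0).all()
        assert (by.loc["nonedge_degradation", "delta_agc"] <= 0).all()
        assert (by.loc["secondary_growth", "delta_agc"] >= 0).all()

    def test_exact_recovery_with_matched_parameters(self, run):
        """Identity observation + matched curves: truth recovered exactly."""
        _, truth, flux, _ = run
        m = flux.groupby(["process", "year"])["delta_agc"].sum()
        t = truth.fluxes.groupby(["process", "year"])["delta_agc"].sum()
        scale = t.abs().max()
        for key in t.index:
            assert m[key] == pytest.approx(t[key], rel=1e-9, abs=1e-9 * scale)

    def test_eq2_closure_in_reference_cells(self, run):
        """Modeled total equals the top-down change in >90% old-growth cells."""
        scene, truth, flux, fractions = run
        tot = flux.groupby(["cell_id", "year"])["delta_agc"].sum()
        agc = truth.agc_density.pivot(index="cell_id", columns="year",
                                      values="agc_mgc_ha")
        f = fractions.set_index(["cell_id", "year"])["f_oldgrowth"]
        area = scene.grid.cell_area_ha
        checked = 0
        for (cid, yr), v in tot.items():
            if f.loc[(cid, yr)] > 0.9:
                dl = (agc.loc[cid, yr] - agc.loc[cid, yr - 1]) * area
                assert abs(v - dl) <= 1e-9 * max(abs(dl), 1.0)
                checked += 1
        assert checked > 0

    def test_region_totals_match_truth_partition(self, run, small_scene):
        """Two half-weighted regions each receive half of every flux."""
        from amazonagc import aggregate_region
        scene, truth, flux, _ = run
        n = scene.grid.n_cells
        w = np.full(n, 0.5)
        out = aggregate_region(flux, {"west": w, "east": w})
        biome = flux.groupby("process")["delta_agc"].sum()
        for region in ("west", "east"):
            for p in PROCESSES:
                got = out[(out.region == region) & (out.process == p)]
                assert got["delta_agc"].iloc[0] == pytest.approx(biome[p] / 2)
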