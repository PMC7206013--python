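"""Scale/B fitting, merging, and the quality statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from micromerge.datasets import OBS_COLUMNS, concat_observations
from micromerge.scaling import (
    ScalingConfig,
    ScalingModel,
    cc_half_splits,
    fit_scales,
    merge,
    prepare_observations,
)
from micromerge.simulate import SimulationConfig, simulate_collection
from micromerge.symmetry import SpaceGroup, UnitCell

from conftest import gauge_project


def apply_scale(ds, k):
    obs = ds.observations.copy()
    obs["intensity"] *= k
    obs["sigma"] *= k
    ds.observations = obs
    return ds


class TestFitScales:
    def test_identity_recovery_noiseless(self):
        cfg = SimulationConfig(
            n_crystals=3, scale_range=(1, 1), B_range=(0, 0), cell_jitter_sigma=0,
            noise_scale=0.0, seed=31,
        )
        datasets, _ = simulate_collection(cfg)
        obs = concat_observations(datasets)
        cells = {d.crystal_id: d.cell for d in datasets}
        model = fit_scales(obs, cfg.spacegroup(), cells)
        for k in model.scales.values():
            assert k == pytest.approx(1.0, abs=1e-6)
        for b in model.b_factors.values():
            assert b == pytest.approx(0.0, abs=1e-3)

    def test_two_crystal_scale_ratio_recovered(self):
        cfg = SimulationConfig(
            n_crystals=2, scale_range=(1, 1), B_range=(0, 0), cell_jitter_sigma=0,
            noise_scale=0.0, seed=32,
        )
        datasets, _ = simulate_collection(cfg)
        datasets[1] = apply_scale(datasets[1], 2.0)
        obs = concat_observations(datasets)
        cells = {d.crystal_id: d.cell for d in datasets}
        model = fit_scales(obs, cfg.spacegroup(), cells)
        ratio = model.scales["xtal001"] / model.scales["xtal000"]
        assert ratio == pytest.approx(2.0, rel=1e-4)

    def test_parameter_recovery_under_noise(self):
        """30 crystals, k in [0.5,2], B in [0,20]: k to <5% RMS, B to <2 Å²."""
        cfg = SimulationConfig(n_crystals=30, seed=33)
        datasets, truth = simulate_collection(cfg)
        obs = concat_observations(datasets)
        cells = {d.crystal_id: d.cell for d in datasets}
        model = fit_scales(obs, cfg.spacegroup(), cells)
        kt = gauge_project(truth.scales, "k")
        bt = gauge_project(truth.b_factors, "b")
        k_err = [(model.scales[c] - kt[c]) / kt[c] for c in kt]
        b_err = [model.b_factors[c] - bt[c] for c in bt]
        assert np.sqrt(np.mean(np.square(k_err))) < 0.05
        assert np.sqrt(np.mean(np.square(b_err))) < 2.0

    def test_disconnected_graph_fails_with_components(self):
        cell = UnitCell(30, 40, 50)
        sg = SpaceGroup("P1")
        rows = [
            (1, 0, 0, 10.0, 1.0, 0, "a"),
            (0, 1, 0, 10.0, 1.0, 0, "a"),
            (0, 0, 1, 10.0, 1.0, 0, "b"),
            (0, 0, 2, 10.0, 1.0, 0, "b"),
        ]
        obs = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
        with pytest.raises(ValueError, match="disconnected"):
            fit_scales(obs, sg, {"a": cell, "b": cell})

    def test_per_frame_scales_fitted(self):
        cfg = SimulationConfig(n_crystals=3, frames_per_wedge=4, seed=34)
        datasets, _ = simulate_collection(cfg)
        obs = concat_observations(datasets)
        cells = {d.crystal_id: d.cell for d in datasets}
        model = fit_scales(obs, cfg.spacegroup(), cells, ScalingConfig(per_frame=True, max_iter=20))
        assert model.frame_scales
        assert all(v > 0 for v in model.frame_scales.values())
        pairs = set(map(tuple, obs[["crystal", "frame"]].drop_duplicates().to_numpy()))
        assert set(model.frame_scales) == pairs


class TestMerge:
    def test_duplicated_noiseless_observations(self, toy_cell):
        """Identical copies merge with R_merge = 0 and CC1/2 = 1."""
        sg = SpaceGroup("P1")
        rng = np.random.default_rng(0)
        hkl = np.array([(h, k, l) for h in range(1, 5) for k in range(1, 4) for l in range(1, 3)])
        base = pd.DataFrame(
            {
                "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                "intensity": rng.uniform(50, 500, len(hkl)),
                "sigma": 1.0, "frame": 0, "crystal": "a",
            }
        )
        dup = pd.concat([base, base.assign(crystal="b")], ignore_index=True)
        merged = merge(dup, None, sg, toy_cell, n_shells=3)
        assert merged.overall["r_merge"] == pytest.approx(0.0, abs=1e-12)
        assert merged.overall["cc_half"] == pytest.approx(1.0, abs=1e-12)
        assert (merged.table["multiplicity"] == 2).all()

    def test_r_merge_matches_hand_computation(self, toy_cell):
        """2 uniques / 4 observations, against spreadsheet arithmetic."""
        sg = SpaceGroup("P1")
        rows = [
            (1, 0, 0, 10.0, 1.0, 0, "a"),
            (1, 0, 0, 12.0, 1.0, 0, "b"),
            (0, 1, 0, 20.0, 1.0, 0, "a"),
            (0, 1, 0, 24.0, 1.0, 0, "b"),
        ]
        obs = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
        merged = merge(obs, None, sg, toy_cell, n_shells=1)
        # equal sigmas: means are 11 and 22; deviations 1,1,2,2; sum I = 66
        assert merged.overall["r_merge"] == pytest.approx(6.0 / 66.0)
        assert merged.overall["r_meas"] == pytest.approx(6.0 * np.sqrt(2.0) / 66.0)
        assert merged.overall["r_pim"] == pytest.approx(6.0 / 66.0)
        row = merged.table.set_index(["h", "k", "l"]).loc[(1, 0, 0)]
        assert row["intensity"] == pytest.approx(11.0)
        assert row["sigma"] == pytest.approx(np.sqrt(0.5))

    def test_r_factor_ordering(self, small_pool):
        """R_pim <= R_merge <= R_meas on every shell with n >= 2."""
        cfg, obs, cells, _ = small_pool
        sg = cfg.spacegroup()
        model = fit_scales(obs, sg, cells)
        merged = merge(obs, model, sg, cells)
        shells = merged.shell_table.dropna(subset=["r_merge"])
        assert len(shells) > 0
        assert (shells["r_pim"] <= shells["r_merge"] + 1e-12).all()
        assert (shells["r_merge"] <= shells["r_meas"] + 1e-12).all()

    @pytest.mark.parametrize("symbol,cell", [
        ("P1", UnitCell(15, 18, 21)),
        ("P21", UnitCell(16, 19, 14, 90, 101, 90)),
        ("P212121", UnitCell(18, 22, 26)),
    ])
    def test_completeness_matches_brute_force_enumeration(self, symbol, cell):
        """Shell n_possible equals an independent gemmi-operator enumeration."""
        import gemmi

        from test_symmetry import GEMMI_NAMES

        sg = SpaceGroup(symbol)
        cfg = SimulationConfig(
            n_crystals=4, cell0=cell, space_group=symbol, d_min=3.0,
            cell_jitter_sigma=0.0, wedge_width=360.0, seed=35,
        )
        datasets, _ = simulate_collection(cfg)
        obs = concat_observations(datasets)
        cells = {d.crystal_id: d.cell for d in datasets}
        merged = merge(obs, None, sg, cells, n_shells=4, reference_cell=cell)

        ref_ops = gemmi.SpaceGroup(GEMMI_NAMES[symbol]).operations()
        gcell = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
        lim = [int(cell.a / 3.0), int(cell.b / 3.0), int(cell.c / 3.0)]
        for _, shell in merged.shell_table.iterrows():
            seen = set()
            for h in range(-lim[0], lim[0] + 1):
                for k in range(-lim[1], lim[1] + 1):
                    for l in range(-lim[2], lim[2] + 1):
                        if (h, k, l) == (0, 0, 0):
                            continue
                        d = gcell.calculate_d([h, k, l])
                        if not (shell["d_min"] <= d < shell["d_max"]):
                            continue
                        if ref_ops.is_systematically_absent([h, k, l]):
                            continue
                        orbit = set()
                        for op in ref_ops:
                            eq = tuple(op.apply_to_hkl([h, k, l]))
                            orbit.add(eq)
                            orbit.add(tuple(-x for x in eq))
                        seen.add(frozenset(orbit))
            assert shell["n_possible"] == len(seen)
            # full 360° rotation data: every possible reflection observed
            assert shell["n_unique"] == shell["n_possible"]
            assert shell["completeness"] == pytest.approx(1.0)

    def test_observation_order_and_labels_irrelevant(self, small_pool):
        cfg, obs, cells, _ = small_pool
        sg = cfg.spacegroup()
        model = fit_scales(obs, sg, cells)
        m1 = merge(obs, model, sg, cells)
        shuffled = obs.sample(frac=1.0, random_state=5).reset_index(drop=True)
        m2 = merge(shuffled, model, sg, cells)
        t1 = m1.table.sort_values(["h", "k", "l"]).reset_index(drop=True)
        t2 = m2.table.sort_values(["h", "k", "l"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)

    def test_uniform_rescale_of_one_crystal_absorbed(self):
        """Scaling one crystal's data by c changes nothing after refit."""
        cfg = SimulationConfig(n_crystals=4, seed=36)
        datasets, _ = simulate_collection(cfg)
        cells = {d.crystal_id: d.cell for d in datasets}
        sg = cfg.spacegroup()
        obs1 = concat_observations(datasets)
        m1 = merge(obs1, fit_scales(obs1, sg, cells), sg, cells)
        datasets[2] = apply_scale(datasets[2], 3.7)
        obs2 = concat_observations(datasets)
        m2 = merge(obs2, fit_scales(obs2, sg, cells), sg, cells)
        # the gauge (mean log k = 0) absorbs c into an overall factor, so
        # compare the merged patterns after normalizing the global scale
        i1 = m1.table["intensity"].to_numpy()
        i2 = m2.table["intensity"].to_numpy()
        np.testing.assert_allclose(i1 / i1.mean(), i2 / i2.mean(), rtol=1e-4)

    def test_cc_half_split_stability(self, small_pool):
        """Single-split CC1/2 sits within 3 sd of the 20-split mean."""
        cfg, obs, cells, _ = small_pool
        sg = cfg.spacegroup()
        model = fit_scales(obs, sg, cells)
        mean, sd, values = cc_half_splits(obs, model, sg, cells, n_splits=20)
        single = merge(obs, model, sg, cells, split_seed=99).overall["cc_half"]
        assert abs(single - mean) < 3 * sd + 1e-6

    def test_empty_shell_reports_nan_not_zero(self, toy_cell):
        sg = SpaceGroup("P1")
        rows = [(1, 0, 0, 10.0, 1.0, 0, "a"), (1, 0, 0, 11.0, 1.0, 0, "a")]
        obs = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
        merged = merge(obs, None, sg, toy_cell, n_shells=3)
        # only one unique: CC1/2 undefined everywhere
        assert np.isnan(merged.overall["cc_half"])

    def test_empty_table_rejected(self, toy_cell):
        with pytest.raises(ValueError, match="empty"):
            merge(pd.DataFrame(columns=list(OBS_COLUMNS)), None, SpaceGroup("P1"), toy_cell)
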