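"""Generator contracts: layout, determinism, closed-form expectations."""

import numpy as np
import pandas as pd
import pytest

from senscreen import (
    SimulationConfig,
    make_plate_maps,
    simulate_expression,
    simulate_qpcr,
    simulate_utrs,
    simulate_well,
)
from senscreen.simulate import CONTROL_ROLES, positive_probability, simulate_screen_cells


class TestPlateMaps:
    def test_full_library_yields_1884_library_wells(self):
        platemap, _ = make_plate_maps(SimulationConfig())
        lib = platemap[platemap["role"] == "library"]
        assert len(lib) == 471 * 4
        # each miRNA appears exactly replicates_per_mirna times
        assert (lib.groupby("sample").size() == 4).all()

    def test_every_plate_has_all_control_roles(self, small_config):
        platemap, _ = make_plate_maps(small_config)
        for _, grp in platemap.groupby("plate"):
            assert set(grp["role"]) >= set(CONTROL_ROLES)

    def test_zero_hit_fraction_means_all_effects_one(self, small_config):
        _, truth = make_plate_maps(small_config.replace(hit_fraction=0.0))
        assert (truth.mirna_effects["effect"] == 1.0).all()
        assert (truth.mirna_effects["direction"] == "none").all()

    def test_fixed_seed_is_reproducible(self, small_config):
        pm1, t1 = make_plate_maps(small_config)
        pm2, t2 = make_plate_maps(small_config)
        pd.testing.assert_frame_equal(pm1, pm2)
        pd.testing.assert_frame_equal(t1.mirna_effects, t2.mirna_effects)
        pd.testing.assert_frame_equal(t1.plate_effects, t2.plate_effects)

    def test_capacity_error(self):
        cfg = SimulationConfig(n_library_mirnas=500, n_plates=1)
        with pytest.raises(ValueError, match="capacity"):
            make_plate_maps(cfg)

    def test_down_hit_folds_within_configured_range(self):
        _, truth = make_plate_maps(SimulationConfig(rng_seed=3))
        down = truth.mirna_effects.query("direction == 'down'")["effect"]
        assert len(down) > 0
        assert ((1 / down >= 5.0) & (1 / down <= 10.0)).all()


class TestPositiveProbability:
    def test_zero_noise_is_clamped_product(self):
        cfg = SimulationConfig(baseline_positive_fraction=0.4, plate_noise_sd=0, well_noise_sd=0)
        assert positive_probability(1.0, cfg) == pytest.approx(0.4)
        assert positive_probability(2.0, cfg) == pytest.approx(0.8)
        assert positive_probability(5.0, cfg) == 1.0  # clamp

    def test_uninduced_role_ignores_effect(self):
        cfg = SimulationConfig(uninduced_positive_fraction=0.02)
        assert positive_probability(7.0, cfg, role="SCR_uninduced") == pytest.approx(0.02)

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ValueError):
            positive_probability(0.0, SimulationConfig())


class TestSimulateWell:
    def test_zero_noise_fraction_matches_binomial_expectation(self, rng):
        cfg = SimulationConfig(
            baseline_positive_fraction=0.4, plate_noise_sd=0.0, well_noise_sd=0.0
        )
        cells = simulate_well(1.0, cfg, rng)
        frac = cells["true_positive"].mean()
        n = len(cells)
        # within 4 binomial SDs of 0.4 at n ~ 600 cells
        assert abs(frac - 0.4) < 4 * np.sqrt(0.4 * 0.6 / n)

    def test_marker_components_are_separable(self, rng):
        cells = simulate_well(1.0, SimulationConfig(), rng)
        pos = cells.loc[cells["true_positive"], "marker_intensity"]
        neg = cells.loc[~cells["true_positive"], "marker_intensity"]
        assert neg.max() < pos.min() or neg.quantile(0.999) < pos.quantile(0.001)

    def test_positions_respect_minimum_separation(self, rng):
        cells = simulate_well(
            1.0, SimulationConfig(images_per_well=1), rng, with_positions=True
        )
        xy = cells[["row", "col"]].to_numpy()
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 12.0**2

    def test_impossible_separation_raises(self, rng):
        cfg = SimulationConfig(images_per_well=1, cells_per_image_mean=200)
        with pytest.raises(ValueError, match="could not place|too small"):
            simulate_well(1.0, cfg, rng, with_positions=True, image_shape=(40, 40))


class TestScreenCells:
    def test_zero_noise_well_fractions(self, small_config):
        cfg = small_config.replace(plate_noise_sd=0.0, well_noise_sd=0.0, hit_fraction=0.0)
        platemap, truth = make_plate_maps(cfg)
        cells = simulate_screen_cells(platemap, truth, cfg, np.random.default_rng(0))
        lib = cells[cells["role"] == "library"]
        frac = lib["true_positive"].mean()
        assert frac == pytest.approx(cfg.baseline_positive_fraction, abs=0.01)
        unind = cells[cells["role"] == "SCR_uninduced"]
        assert unind["true_positive"].mean() == pytest.approx(
            cfg.uninduced_positive_fraction, abs=0.01
        )


class TestSimulateUtrs:
    SEED = "TCCTGAC"  # positions 2-8 of a mature miRNA

    def test_clean_background_has_no_sites(self, rng):
        from senscreen import MatureMiRNA, scan_sites

        utrs, _ = simulate_utrs(20, 300, [], self.SEED, rng)
        m = MatureMiRNA("m", "C" + self.SEED.replace("T", "U") + "AGGUCCUGUGU")
        assert all(scan_sites(seq, m, tx) == [] for tx, seq in utrs.items())

    @pytest.mark.parametrize("stype,length", [("8mer", 8), ("7mer-m8", 7), ("7mer-A1", 7), ("6mer", 6)])
    def test_planted_site_recorded_and_fits(self, rng, stype, length):
        utrs, truth = simulate_utrs(1, 100, [(0, 30, stype)], self.SEED, rng)
        assert truth.utr_sites == [("tx0001", 30, 30 + length, stype)]
        assert len(utrs["tx0001"]) == 100

    def test_overlapping_planted_sites_rejected(self, rng):
        with pytest.raises(ValueError, match="overlap"):
            simulate_utrs(1, 100, [(0, 30, "8mer"), (0, 33, "6mer")], self.SEED, rng)

    def test_site_outside_transcript_rejected(self, rng):
        with pytest.raises(ValueError, match="fit"):
            simulate_utrs(1, 100, [(0, 95, "8mer")], self.SEED, rng)


class TestSimulateQpcr:
    def test_zero_noise_recovers_ratio_exactly(self, rng):
        from senscreen import delta_delta_ct

        for ratio in (0.25, 0.5, 1.0, 2.0, 4.0):
            table = simulate_qpcr(ratio, n_replicates=3, ct_noise_sd=0.0, rng=rng)
            assert delta_delta_ct(table) == pytest.approx(ratio)

    def test_half_ratio_means_unit_ddct(self, rng):
        table = simulate_qpcr(0.5, ct_noise_sd=0.0, rng=rng)
        means = table.groupby(["condition", "role"])["ct"].mean()
        ddct = (means[("treated", "target")] - means[("treated", "reference")]) - (
            means[("control", "target")] - means[("control", "reference")]
        )
        assert ddct == pytest.approx(1.0)

    def test_noisy_mean_estimate_close(self):
        from senscreen import delta_delta_ct

        rng = np.random.default_rng(42)
        est = [
            delta_delta_ct(simulate_qpcr(0.5, 3, 0.1, rng)) for _ in range(1000)
        ]
        assert np.mean(est) == pytest.approx(0.5, rel=0.05)


class TestSimulateExpression:
    def test_truth_marks_exactly_the_planted_genes(self, rng):
        fc = {"gene0001": 0.5, "gene0010": 2.0}
        _, _, truth = simulate_expression(20, fc, rng=rng)
        t = truth.gene_fold_changes.set_index("gene")
        assert set(t.index[t["affected"]]) == set(fc)
        assert t.loc["gene0001", "log2_fold_change"] == pytest.approx(-1.0)

    def test_single_replicate_group_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_expression(10, n_per_group=1, rng=rng)

    def test_matrix_shape_and_groups(self, rng):
        expr, groups, _ = simulate_expression(15, n_per_group=4, rng=rng)
        assert expr.shape == (15, 8)
        assert (groups.value_counts() == 4).all()
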