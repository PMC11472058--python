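import numpy as np
import pandas as pd
import pytest

from capassays import binding, densitometry, expression, synthetic
from capassays.synthetic import SimulationConfig


class TestSimulationConfig:
    def test_unknown_noise_model_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_model="poisson")

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_scale=-0.1)


class TestTitrationGenerator:
    def test_noiseless_equals_model_prediction_after_dilution(
            self, reference_params, reference_protocol):
        raw, _ = synthetic.gen_titration(
            reference_params, reference_protocol,
            SimulationConfig(seed=0, noise_scale=0.0))
        sched = reference_protocol.schedule()
        f_true = binding.model_fluorescence(
            sched["ligand_uM"].to_numpy(), reference_params,
            p_act=sched["protein_uM"].to_numpy())
        # eps == 0 so the only forward distortion is dilution
        expected = f_true * reference_protocol.start_volume / sched["volume_ul"]
        assert np.allclose(raw["f_obs"], expected, rtol=1e-12)
        assert raw["f_obs"].iloc[0] == pytest.approx(reference_params.f0)

    def test_same_seed_bitwise_identical(self, reference_params, reference_protocol):
        a, _ = synthetic.gen_titration(reference_params, reference_protocol,
                                       SimulationConfig(seed=42, noise_scale=0.02))
        b, _ = synthetic.gen_titration(reference_params, reference_protocol,
                                       SimulationConfig(seed=42, noise_scale=0.02))
        pd.testing.assert_frame_equal(a, b)

    def test_correction_inverts_simulated_inner_filter(self, reference_params):
        # with absorbing ligand the generator attenuates and build_curve undoes it
        aliquots, stocks = synthetic.escalating_stocks(42.1, n_points=20)
        protocol = binding.TitrationProtocol(
            aliquot_volumes=aliquots, stock_concs=stocks, eps_ex=32.0, eps_em=5.0)
        raw, _ = synthetic.gen_titration(
            reference_params, protocol, SimulationConfig(seed=0, noise_scale=0.0))
        curve = binding.build_curve(raw, protocol)
        sched = protocol.schedule()
        f_true = binding.model_fluorescence(
            sched["ligand_uM"].to_numpy(), reference_params,
            p_act=sched["protein_uM"].to_numpy())
        assert np.allclose(curve.f_corrected, f_true, rtol=1e-12)

    def test_full_loop_recovers_reference_affinity(self):
        from capassays.pipeline import fit_binding_replicates
        pooled, _ = fit_binding_replicates(42.1, seeds=[1, 2, 3])
        assert abs(pooled.kd_nM - 42.1) / 42.1 < 0.10


class TestStockDesign:
    def test_targets_reach_saturation_for_tight_binders(self):
        aliquots, stocks = synthetic.escalating_stocks(5.0)
        protocol = binding.TitrationProtocol(
            aliquot_volumes=aliquots, stock_concs=stocks)
        final_L = protocol.schedule()["ligand_uM"].iloc[-1]
        assert final_L >= 4.0 * 0.1 * 0.999

    def test_total_dilution_stays_under_four_percent(self):
        aliquots, _ = synthetic.escalating_stocks(42.1)
        assert sum(aliquots) / 1400.0 < 0.04

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            synthetic.escalating_stocks(42.1, n_points=3)


class TestLaneGenerator:
    def test_single_band_integral_matches_area(self):
        x, y, _ = synthetic.gen_lane_profile(
            [(50.0, 7.0, 2.0)], baseline=(0.0,),
            sim=SimulationConfig(seed=0, noise_scale=0.0))
        assert np.trapezoid(y, x) == pytest.approx(7.0, rel=1e-3)

    def test_zero_area_bands_give_flat_baseline(self):
        x, y, _ = synthetic.gen_lane_profile(
            [(50.0, 0.0, 2.0)], baseline=(3.0,),
            sim=SimulationConfig(seed=0, noise_scale=0.0))
        assert np.allclose(y, 3.0)

    def test_determinism_and_truth_metadata(self):
        sim = SimulationConfig(seed=9, noise_scale=0.01)
        _, y1, t1 = synthetic.gen_lane_profile([(30.0, 9.0, 2.0)], sim=sim)
        _, y2, t2 = synthetic.gen_lane_profile([(30.0, 9.0, 2.0)], sim=sim)
        assert np.array_equal(y1, y2)
        assert t1["band_areas"] == [9.0]

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_lane_profile([(50.0, -1.0, 2.0)])
        with pytest.raises(ValueError):
            synthetic.gen_lane_profile([(50.0, 1.0, 0.0)])
        with pytest.raises(ValueError):
            synthetic.gen_lane_profile([(500.0, 1.0, 2.0)])
        with pytest.raises(ValueError):
            synthetic.gen_lane_profile([(50.0, 1.0, 2.0)], n_points=5)


class TestDecappingGenerator:
    def test_zero_rate_keeps_capped_fraction_constant(self):
        table, truth = synthetic.gen_decapping_series(0.9, 0.0)
        cf = table["capped"] / (table["capped"] + table["uncapped"])
        assert np.allclose(cf, 0.9)

    def test_first_order_decay_drives_susceptibility(self):
        # rate chosen so 10% of caps remain at 30 min
        rate = -np.log(0.10) / 30.0
        table, _ = synthetic.gen_decapping_series(0.9, rate)
        series = {r.time_min: (r.capped, r.uncapped) for r in table.itertuples()}
        course = densitometry.decapping_course(series)
        assert course.decapped_at_query == pytest.approx(0.90, abs=1e-9)

    def test_lane_totals_conserved_before_noise(self):
        table, _ = synthetic.gen_decapping_series(0.7, 0.02)
        assert np.allclose(table["capped"] + table["uncapped"], 1000.0)

    def test_negative_timepoints_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_decapping_series(0.9, 0.1, timepoints_min=(-5.0, 0.0))


class TestExpressionGenerator:
    def test_zero_noise_recovers_exact_levels(self):
        levels = {"m7GpppAmpG": 1.0, "analog8": 1.32, "tetra": 0.02}
        table, _ = synthetic.gen_expression_plate(
            levels, sim=SimulationConfig(seed=0, noise_model="lognormal",
                                         noise_scale=0.0))
        totals = expression.cumulative_expression(table)
        norm = expression.normalize_to_reference(totals, "m7GpppAmpG", by=None)
        for sample, level in levels.items():
            row = norm.loc[norm["sample"] == sample].iloc[0]
            assert row["normalized_mean"] == pytest.approx(level, rel=1e-12)

    def test_reference_must_be_declared_at_unity(self):
        with pytest.raises(ValueError):
            synthetic.gen_expression_plate({"analog": 1.3})
        with pytest.raises(ValueError):
            synthetic.gen_expression_plate({})

    def test_noisy_mean_within_three_sd_of_truth(self):
        table, _ = synthetic.gen_expression_plate(
            {"m7GpppAmpG": 1.0, "analog8": 1.32},
            sim=SimulationConfig(seed=4, noise_model="lognormal",
                                 noise_scale=0.05))
        totals = expression.cumulative_expression(table)
        norm = expression.normalize_to_reference(totals, "m7GpppAmpG", by=None)
        row = norm.loc[norm["sample"] == "analog8"].iloc[0]
        # 5% CV over 3 replicates: allow 3 sigma around the true level
        assert abs(row["normalized_mean"] - 1.32) < 3 * 0.05 * 1.32


class TestProteinGroupGenerator:
    def test_clean_table_survives_when_nothing_flagged(self):
        from capassays import proteomics
        table, _ = synthetic.gen_proteingroups(
            n_background=200, sim=SimulationConfig(seed=0))
        cleaned = proteomics.clean_table(table)
        filtered = proteomics.completeness_filter(
            proteomics.log2_median_normalize(cleaned))
        assert len(filtered) == 200

    def test_all_decoys_removed_by_cleaning(self):
        from capassays import proteomics
        table, _ = synthetic.gen_proteingroups(
            n_background=50, flags_rate={"reverse": 1.0},
            sim=SimulationConfig(seed=0))
        with pytest.warns(UserWarning, match="all rows flagged"):
            cleaned = proteomics.clean_table(table)
        assert len(cleaned) == 0

    def test_spiked_rows_shifted_in_target_channels(self):
        table, truth = synthetic.gen_proteingroups(
            n_background=10, spikes=[("AR-2", 3.0)], sigma=0.01,
            sim=SimulationConfig(seed=1))
        row = table.loc[table["group_id"] == "SP00000"].iloc[0]
        ar1 = np.log2([row[f"reporter_{i}"] for i in (1, 2, 3)]).mean()
        ar2 = np.log2([row[f"reporter_{i}"] for i in (4, 5, 6)]).mean()
        assert ar2 - ar1 == pytest.approx(3.0, abs=0.1)
        assert truth["spiked"]["AR-2"] == ["SP00000"]

    def test_missing_rate_masks_values(self):
        table, _ = synthetic.gen_proteingroups(
            n_background=300, missing_rate=0.2, sim=SimulationConfig(seed=2))
        frac = table[[f"reporter_{i}" for i in range(1, 10)]].isna().mean().mean()
        assert 0.15 < frac < 0.25

    def test_unknown_spike_group_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_proteingroups(n_background=5, spikes=[("AR-9", 2.0)])
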