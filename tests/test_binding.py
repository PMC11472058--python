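import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from capassays import binding, synthetic
from capassays.binding import (
    BindingModelParams,
    TitrationProtocol,
    build_curve,
    complex_concentration,
    fit_titration,
    model_fluorescence,
    pool_replicates,
)


def cx_bruteforce(L, P, K):
    """Independent oracle: numerically robust root of the binding quadratic.

    K*cx^2 - (K(L+P)+1)*cx + K*L*P = 0, taking the root in [0, min(L, P)].
    """
    roots = np.roots([K, -(K * (L + P) + 1.0), K * L * P])
    roots = roots[np.isreal(roots)].real
    ok = roots[(roots >= -1e-12) & (roots <= min(L, P) + 1e-12)]
    return float(np.clip(ok[0], 0.0, min(L, P)))


class TestComplexConcentration:
    def test_no_ligand_or_no_protein_gives_no_complex(self):
        assert complex_concentration(0.0, 0.1, 23.753) == 0.0
        assert complex_concentration(0.5, 0.0, 23.753) == 0.0

    def test_equimolar_reference_case_matches_bruteforce(self):
        # 0.1 uM each at K_D = 42.1 nM
        cx = complex_concentration(0.1, 0.1, 23.753)
        assert cx == pytest.approx(0.05284, abs=5e-5)
        assert cx == pytest.approx(cx_bruteforce(0.1, 0.1, 23.753), rel=1e-12)

    def test_agreement_with_bruteforce_over_log_grid(self):
        grid = np.logspace(-4, 2, 13)
        for L in grid:
            for P in grid:
                for K in np.logspace(-3, 3, 7):
                    closed = complex_concentration(L, P, K)
                    brute = cx_bruteforce(L, P, K)
                    assert closed == pytest.approx(brute, rel=1e-10, abs=1e-14)

    @settings(max_examples=200, derandomize=True)
    @given(
        L=st.floats(0.0, 100.0),
        P=st.floats(0.0, 10.0),
        K=st.floats(1e-3, 1e3),
    )
    def test_mass_conservation_and_bounds(self, L, P, K):
        cx = complex_concentration(L, P, K)
        assert 0.0 <= cx <= min(L, P) + 1e-12
        # the equilibrium condition itself
        assert K * (L - cx) * (P - cx) == pytest.approx(cx, rel=1e-6, abs=1e-9)

    def test_monotone_in_each_argument(self):
        base = complex_concentration(0.2, 0.1, 10.0)
        assert complex_concentration(0.4, 0.1, 10.0) >= base
        assert complex_concentration(0.2, 0.2, 10.0) >= base
        assert complex_concentration(0.2, 0.1, 20.0) >= base

    def test_affinity_limits(self):
        assert complex_concentration(0.2, 0.1, 0.0) == 0.0
        assert complex_concentration(0.2, 0.1, 1e-9) == pytest.approx(0.0, abs=1e-9)
        assert complex_concentration(0.2, 0.1, 1e9) == pytest.approx(0.1, rel=1e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            complex_concentration(-0.1, 0.1, 1.0)


class TestModelFluorescence:
    def test_zero_ligand_returns_initial_fluorescence(self):
        p = BindingModelParams(k_as=10.0, p_act=0.1, f0=1234.5, delta_phi=5000.0)
        assert model_fluorescence(0.0, p) == pytest.approx(1234.5)

    def test_full_quench_plateau_at_saturation(self):
        p = BindingModelParams(k_as=1e8, p_act=0.1, f0=1000.0, delta_phi=5000.0,
                               phi_free=0.0)
        # ligand well above protein, no free-ligand fluorescence
        assert model_fluorescence(10.0, p) == pytest.approx(1000.0 - 5000.0 * 0.1,
                                                            rel=1e-5)

    def test_reference_point_arithmetic(self):
        p = BindingModelParams(k_as=23.753, p_act=0.1, f0=1000.0,
                               delta_phi=5000.0, phi_free=100.0)
        cx = complex_concentration(0.1, 0.1, 23.753)
        expected = 1000.0 - cx * 5100.0 + 0.1 * 100.0
        assert model_fluorescence(0.1, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(740.5, abs=0.1)


class TestBuildCurve:
    def test_single_aliquot_concentrations_and_dilution(self):
        protocol = TitrationProtocol(aliquot_volumes=(1.0,), stock_concs=(10.0,))
        raw = pd.DataFrame({"f_obs": [1000.0, 990.0]})
        curve = build_curve(raw, protocol)
        assert curve.ligand_uM[1] == pytest.approx(10.0 / 1401.0, rel=1e-12)
        assert curve.protein_uM[1] == pytest.approx(0.1 * 1400.0 / 1401.0, rel=1e-12)
        # dilution-corrected fluorescence
        assert curve.f_corrected[1] == pytest.approx(990.0 * 1401.0 / 1400.0,
                                                     rel=1e-12)

    def test_no_absorbance_means_no_inner_filter(self):
        protocol = TitrationProtocol(aliquot_volumes=(1.0,), stock_concs=(10.0,),
                                     eps_ex=0.0, eps_em=0.0)
        factors = binding.inner_filter_factor([0.0, 5.0], protocol)
        assert np.allclose(factors, 1.0)

    def test_inner_filter_factor_geometric_mean(self):
        # A_ex = 0.1 and A_em = 0.2 -> factor 10**0.15
        protocol = TitrationProtocol(
            aliquot_volumes=(1.0,), stock_concs=(10.0,),
            eps_ex=25.0, eps_em=20.0, path_ex=1.0, path_em=1.0)
        # ligand 10 uM = 0.01 mM: A_ex = 25*0.01 = 0.25... pick L for A=0.1/0.2
        f = binding.inner_filter_factor(4.0, protocol)  # 0.004 mM: A_ex=0.1, A_em=0.08
        assert f == pytest.approx(10 ** ((0.1 + 0.08) / 2), rel=1e-12)
        protocol2 = TitrationProtocol(
            aliquot_volumes=(1.0,), stock_concs=(10.0,),
            eps_ex=10.0, eps_em=20.0, path_ex=1.0, path_em=1.0)
        f2 = binding.inner_filter_factor(10.0, protocol2)  # A_ex=0.1, A_em=0.2
        assert f2 == pytest.approx(1.4125, abs=2e-4)

    def test_row_count_must_match_protocol(self):
        protocol = TitrationProtocol(aliquot_volumes=(1.0,), stock_concs=(10.0,))
        with pytest.raises(ValueError, match="rows"):
            build_curve(pd.DataFrame({"f_obs": [1.0, 2.0, 3.0]}), protocol)


class TestFitTitration:
    def test_noiseless_curve_recovers_parameters_exactly(
            self, reference_params, reference_protocol):
        raw, _ = synthetic.gen_titration(
            reference_params, reference_protocol,
            synthetic.SimulationConfig(seed=0, noise_scale=0.0))
        fit = fit_titration(build_curve(raw, reference_protocol))
        assert fit.converged
        assert fit.params.k_as == pytest.approx(reference_params.k_as, rel=1e-4)
        assert fit.params.p_act == pytest.approx(reference_params.p_act, rel=1e-4)
        assert fit.params.delta_phi == pytest.approx(
            reference_params.delta_phi, rel=1e-4)

    def test_three_noisy_replicates_pool_close_to_truth(
            self, reference_params, reference_protocol):
        fits = []
        for seed in (1, 2, 3):
            raw, _ = synthetic.gen_titration(
                reference_params, reference_protocol,
                synthetic.SimulationConfig(seed=seed, noise_scale=0.02))
            fits.append(fit_titration(
                build_curve(raw, reference_protocol),
                fix={"phi_free": reference_params.phi_free}, weights="relative"))
        pooled = pool_replicates(fits)
        assert abs(pooled.kd_nM - 42.1) / 42.1 < 0.10

    def test_per_point_vs_fixed_protein_small_difference(
            self, reference_params, reference_protocol):
        # dilution over the titration is < 4%, so the two handlings agree
        raw, _ = synthetic.gen_titration(
            reference_params, reference_protocol,
            synthetic.SimulationConfig(seed=5, noise_scale=0.0))
        curve = build_curve(raw, reference_protocol)
        k_pp = fit_titration(curve, per_point_protein=True).k_as
        k_fix = fit_titration(curve, per_point_protein=False).k_as
        assert abs(k_pp - k_fix) / k_pp < 0.04

    def test_too_few_points_rejected(self):
        curve = binding.TitrationCurve(
            ligand_uM=np.linspace(0, 1, 5),
            f_corrected=np.linspace(1000, 500, 5),
            protein_uM=np.full(5, 0.1))
        with pytest.raises(ValueError, match="at least 6"):
            fit_titration(curve)

    def test_standard_error_consistent_with_parametric_bootstrap(
            self, reference_params, reference_protocol):
        """lmfit curvature SE vs the spread of refits on re-noised data."""
        sim = synthetic.SimulationConfig(seed=11, noise_scale=0.02)
        raw, _ = synthetic.gen_titration(reference_params, reference_protocol, sim)
        fit = fit_titration(build_curve(raw, reference_protocol),
                            fix={"phi_free": 10.0}, weights="relative")
        boot = []
        for bseed in range(25):
            braw, _ = synthetic.gen_titration(
                reference_params, reference_protocol,
                synthetic.SimulationConfig(seed=1000 + bseed, noise_scale=0.02))
            bfit = fit_titration(build_curve(braw, reference_protocol),
                                 fix={"phi_free": 10.0}, weights="relative")
            boot.append(bfit.k_as)
        boot_se = np.std(boot, ddof=1)
        assert 0.35 * boot_se < fit.k_as_se < 2.5 * boot_se


class TestPooling:
    def test_equal_fits_pool_with_sqrt_n_shrinkage(self):
        p = BindingModelParams(k_as=10.0, p_act=0.1, f0=1.0, delta_phi=1.0)
        fits = [binding.BindingFitResult(p, {"k_as": 1.0}, 0.0, 10, True)
                for _ in range(3)]
        pooled = pool_replicates(fits)
        assert pooled.k_as == pytest.approx(10.0)
        assert pooled.k_as_se == pytest.approx(1.0 / np.sqrt(3.0), abs=1e-3)

    def test_inverse_variance_weighting_arithmetic(self):
        mk = lambda k, se: binding.BindingFitResult(
            BindingModelParams(k_as=k, p_act=0.1, f0=1.0, delta_phi=1.0),
            {"k_as": se}, 0.0, 10, True)
        pooled = pool_replicates([mk(10.0, 1.0), mk(20.0, 2.0)])
        assert pooled.k_as == pytest.approx(12.0)
        assert pooled.k_as_se == pytest.approx(0.894, abs=1e-3)

    def test_single_fit_passes_through(self):
        p = BindingModelParams(k_as=8.0, p_act=0.1, f0=1.0, delta_phi=1.0)
        fit = binding.BindingFitResult(p, {"k_as": 0.5}, 0.0, 10, True)
        pooled = pool_replicates([fit])
        assert pooled.k_as == pytest.approx(8.0)
        assert pooled.kd_nM == pytest.approx(125.0)

    def test_pooled_se_never_exceeds_best_replicate(self):
        mk = lambda k, se: binding.BindingFitResult(
            BindingModelParams(k_as=k, p_act=0.1, f0=1.0, delta_phi=1.0),
            {"k_as": se}, 0.0, 10, True)
        pooled = pool_replicates([mk(9.0, 0.8), mk(11.0, 1.5), mk(10.0, 2.0)])
        assert pooled.k_as_se <= 0.8

    def test_missing_se_falls_back_to_unweighted_mean(self):
        mk = lambda k, se: binding.BindingFitResult(
            BindingModelParams(k_as=k, p_act=0.1, f0=1.0, delta_phi=1.0),
            {"k_as": se}, 0.0, 10, True)
        with pytest.warns(UserWarning, match="unweighted"):
            pooled = pool_replicates([mk(10.0, np.nan), mk(20.0, 1.0)])
        assert pooled.k_as == pytest.approx(15.0)
        assert not pooled.weighted
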