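"""Two-state van't Hoff model: closed forms, simulation, fitting."""

import math

import numpy as np
import pytest

from quadstall.melt_thermo import (Baselines, MeltingCurve,
                                   NoTransitionError, R_KCAL, T37_K,
                                   TwoStateParams, dG_at, fit_two_state,
                                   fraction_folded, normalize_curve,
                                   params_from_dG37_Tm, read_melting_csv,
                                   simulate_curve, write_melting_csv)

WT = TwoStateParams(dH=-45.69, Tm=349.55)
GRID = 20.0 + 0.5 * np.arange(151)
BASELINES = Baselines(0.40, -2e-4, 0.30, -1e-4)


class TestClosedForms:
    def test_dG_zero_at_Tm(self):
        for dH in (-20.0, -45.69, -80.0):
            assert dG_at(349.55, TwoStateParams(dH=dH, Tm=349.55)) == 0.0

    def test_wildtype_dG37(self):
        assert dG_at(T37_K, WT) == pytest.approx(-5.15, abs=0.005)

    def test_u_mutant_dG37(self):
        assert dG_at(T37_K, TwoStateParams(dH=-50.73, Tm=313.05)) == \
            pytest.approx(-0.47, abs=0.005)

    def test_fraction_half_at_Tm(self):
        assert fraction_folded(WT.Tm, WT) == pytest.approx(0.5, abs=1e-14)

    def test_fraction_matches_independent_boltzmann_evaluation(self):
        # oracle: plain-math logistic of the equilibrium constant
        T = 310.15
        dG = WT.dH * (1 - T / WT.Tm)
        K = math.exp(-dG / (R_KCAL * T))
        assert fraction_folded(T, WT) == pytest.approx(K / (1 + K),
                                                       rel=1e-12)
        assert fraction_folded(T, WT) == pytest.approx(0.99976, abs=5e-5)

    def test_fraction_limits_and_monotonicity(self):
        T = np.linspace(250, 400, 500)
        f = fraction_folded(T, WT)
        assert np.all(np.diff(f) < 0)           # melting on heating
        assert fraction_folded(1.0, WT) == pytest.approx(1.0)
        assert fraction_folded(4000.0, WT) < 0.51

    def test_two_state_entropy_constraint(self):
        assert WT.dS == pytest.approx(WT.dH / WT.Tm)

    def test_params_from_printed_pair_roundtrip(self, reported_params):
        expected = {"wild-type": (-5.15, 76.4), "C-mutant": (-4.77, 72.6),
                    "G-mutant": (-5.86, 82.4), "U-mutant": (-0.47, 39.9)}
        for name, params in reported_params.items():
            dg, tm = expected[name]
            assert params.dG37 == pytest.approx(dg, abs=1e-9)
            assert params.Tm_celsius == pytest.approx(tm, abs=1e-9)


class TestSimulate:
    def test_pure_fraction_curve(self):
        flat = Baselines(1.0, 0.0, 0.0, 0.0)
        curve = simulate_curve(WT, flat, GRID, noise_sd=0.0)
        np.testing.assert_allclose(
            curve.signal, fraction_folded(GRID + 273.15, WT), rtol=1e-12)

    def test_seed_determinism(self):
        c1 = simulate_curve(WT, BASELINES, GRID, noise_sd=0.01, seed=3)
        c2 = simulate_curve(WT, BASELINES, GRID, noise_sd=0.01, seed=3)
        np.testing.assert_array_equal(c1.signal, c2.signal)
        c3 = simulate_curve(WT, BASELINES, GRID, noise_sd=0.01, seed=4)
        assert not np.array_equal(c1.signal, c3.signal)

    def test_inflection_near_Tm(self):
        """Numerical inflection of the dense noiseless curve sits at Tm."""
        dense = np.linspace(20, 95, 4001)
        flat = Baselines(1.0, 0.0, 0.0, 0.0)
        curve = simulate_curve(WT, flat, dense, noise_sd=0.0)
        d = np.gradient(curve.signal, dense)
        t_inflect = dense[np.argmax(np.abs(d))]
        assert abs(t_inflect - WT.Tm_celsius) < 0.5

    def test_rejects_empty_grid(self):
        with pytest.raises(ValueError):
            simulate_curve(WT, BASELINES, [], noise_sd=0.0)

    def test_curve_validation(self):
        with pytest.raises(ValueError, match="at least 20"):
            MeltingCurve(np.arange(5.0), np.arange(5.0), 295.0)
        t = np.arange(25.0)
        t[3] = t[2]
        with pytest.raises(ValueError, match="strictly increasing"):
            MeltingCurve(t, np.zeros(25), 295.0)


class TestFit:
    def test_recovers_printed_Tm_wildtype(self):
        curve = simulate_curve(WT, BASELINES, GRID, noise_sd=0.0)
        fit = fit_two_state(curve)
        assert fit.params.Tm_celsius == pytest.approx(76.4, abs=0.1)

    def test_recovers_printed_Tm_g_mutant(self, reported_params):
        curve = simulate_curve(reported_params["G-mutant"], BASELINES, GRID,
                               noise_sd=0.0)
        fit = fit_two_state(curve)
        assert fit.params.Tm_celsius == pytest.approx(82.4, abs=0.1)

    def test_noiseless_parameter_recovery_across_range(self):
        """dG37 recovered to 0.01 kcal/mol over the admissible range."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            dH = rng.uniform(-80.0, -20.0)
            tm_c = rng.uniform(35.0, 90.0)
            truth = TwoStateParams(dH=dH, Tm=tm_c + 273.15)
            curve = simulate_curve(truth, BASELINES, GRID, noise_sd=0.0)
            fit = fit_two_state(curve)
            assert fit.params.dG37 == pytest.approx(truth.dG37, abs=0.01)

    def test_sign_agnostic_amplitude(self):
        """Hyperchromic (signal rising on melt) transitions fit equally."""
        rising = Baselines(0.30, -1e-4, 0.40, -2e-4)
        curve = simulate_curve(WT, rising, GRID, noise_sd=0.0)
        fit = fit_two_state(curve)
        assert fit.params.Tm_celsius == pytest.approx(76.4, abs=0.1)

    def test_noisy_recovery_bias(self):
        """Mean recovered dG37 within 0.2 kcal/mol at instrument noise."""
        recovered = []
        for seed in range(20):
            curve = simulate_curve(WT, BASELINES, GRID, noise_sd=0.002,
                                   seed=seed)
            recovered.append(fit_two_state(curve).params.dG37)
        assert np.mean(recovered) == pytest.approx(WT.dG37, abs=0.2)

    def test_replicate_aggregation(self):
        curves = [simulate_curve(WT, BASELINES, GRID, noise_sd=0.0,
                                 replicate_id=f"r{i}") for i in range(5)]
        fit = fit_two_state(curves)
        assert len(fit.per_replicate) == 5
        assert fit.dG37_sd == pytest.approx(0.0, abs=1e-9)
        assert fit.Tm_sd_celsius == pytest.approx(0.0, abs=1e-9)

    def test_single_replicate_has_no_sd(self):
        fit = fit_two_state(simulate_curve(WT, BASELINES, GRID))
        assert fit.dG37_sd is None

    def test_flat_curve_raises_no_transition(self):
        signal = BASELINES.unfolded(GRID + 273.15)
        curve = MeltingCurve(GRID, signal, 295.0)
        with pytest.raises(NoTransitionError):
            fit_two_state(curve)

    def test_noisy_baseline_only_curve_raises_no_transition(self):
        rng = np.random.default_rng(0)
        signal = BASELINES.unfolded(GRID + 273.15) + rng.normal(
            0, 0.002, GRID.size)
        with pytest.raises(NoTransitionError):
            fit_two_state(MeltingCurve(GRID, signal, 295.0))


class TestNormalize:
    def test_half_at_Tm_and_one_when_folded(self):
        curve = simulate_curve(WT, BASELINES, GRID, noise_sd=0.0)
        fit = fit_two_state(curve)
        norm = normalize_curve(curve, fit)
        i_tm = np.argmin(np.abs(GRID - WT.Tm_celsius))
        assert norm.signal[i_tm] == pytest.approx(0.5, abs=0.02)
        assert norm.signal[0] == pytest.approx(1.0, abs=1e-3)

    def test_roundtrip_equals_fraction_folded(self):
        curve = simulate_curve(WT, BASELINES, GRID, noise_sd=0.0)
        fit = fit_two_state(curve)
        norm = normalize_curve(curve, fit)
        np.testing.assert_allclose(
            norm.signal, fraction_folded(GRID + 273.15, WT), atol=1e-6)

    def test_degenerate_baselines_rejected(self):
        curve = simulate_curve(WT, BASELINES, GRID, noise_sd=0.0)
        fit = fit_two_state(curve)
        from quadstall.melt_thermo import TwoStateFit
        bad = TwoStateFit(params=fit.params,
                          baselines=Baselines(0.3, -1e-4, 0.3, -1e-4),
                          residual_rms=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_curve(curve, bad)


class TestCsvIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "melt.csv"
        curves = [simulate_curve(WT, BASELINES, GRID, noise_sd=0.002,
                                 seed=i, replicate_id=f"rep{i}")
                  for i in range(2)]
        write_melting_csv(curves, path)
        back = read_melting_csv(path, wavelength=295.0)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].signal, curves[0].signal,
                                   rtol=1e-9)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("temperature_C,signal\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_melting_csv(path)
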