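"""Model evaluation, starting values, and the nonlinear least-squares fit."""

import numpy as np
import pytest
from helpers_oracle import brute_force_fit

from vo2kinetics import (
    BreathNoiseModel,
    KineticParams,
    MonoExpKinetics,
    Protocol,
    fit_kinetics,
    generate_breath_series,
    initial_values,
    model_predict,
    resample_to_bins,
    stack,
    sweep_dtr,
)


class TestModelPredict:
    def test_closed_form_landmarks(self, true_params):
        p = true_params
        assert model_predict(p, p.td) == pytest.approx(p.a_b)
        # one time constant past the delay: 1 - 1/e of the amplitude
        assert model_predict(p, p.td + p.tau) == pytest.approx(
            p.a_b + p.da * (1 - np.exp(-1))
        )
        assert model_predict(p, 1e9) == pytest.approx(p.a_b + p.da)

    def test_constant_baseline_before_delay(self, true_params):
        t = np.linspace(-180, true_params.td - 1e-9, 50)
        np.testing.assert_allclose(model_predict(true_params, t),
                                   true_params.a_b)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            model_predict(np.array([700.0, 1000.0, -1.0, 10.0]), 5.0)
        with pytest.raises(ValueError):
            KineticParams(a_b=700, da=1000, tau=0.0, td=10)


class TestInitialValues:
    def test_standard_starting_values(self):
        times = np.array([-100.0, -50.0, 200.0, 300.0])
        values = np.array([300.0, 310.0, 1300.0, 1300.0])
        init = initial_values((times, values))
        assert init.tau == 25.0 and init.td == 0.0
        assert init.a_b == pytest.approx(305.0)
        assert init.da == pytest.approx(995.0)

    def test_windows_follow_protocol(self):
        protocol = Protocol(baseline_start_s=-60.0, exercise_end_s=240.0)
        times = np.array([-30.0, 100.0])
        values = np.array([500.0, 1500.0])
        init = initial_values((times, values), protocol)
        # steady window is the final 3 min: [60, 240]
        assert init.da == pytest.approx(1000.0)

    def test_missing_windows_rejected(self):
        with pytest.raises(ValueError):
            initial_values((np.array([10.0, 200.0]), np.array([1.0, 2.0])))
        with pytest.raises(ValueError):
            initial_values((np.array([-10.0, 5.0]), np.array([1.0, 2.0])))


class TestFit:
    def test_noiseless_recovery_machine_precision(self, noiseless_series,
                                                  true_params):
        res = fit_kinetics(noiseless_series)
        np.testing.assert_allclose(res.params.as_array(),
                                   true_params.as_array(), rtol=1e-6)
        assert res.rss < 1e-10
        assert res.converged

    def test_df_is_window_size_minus_four(self, noisy_series):
        res = fit_kinetics(noisy_series, dtr_s=20.0)
        n_window = np.sum((noisy_series.times < 0) | (noisy_series.times >= 20))
        assert res.n_points == n_window
        assert res.df == n_window - 4

    def test_dtr_shrinks_window_but_keeps_baseline(self, noisy_series):
        m = MonoExpKinetics.from_series(noisy_series)
        mask0, mask20 = m.window_mask(0.0), m.window_mask(20.0)
        assert mask0.sum() > mask20.sum()
        baseline = noisy_series.times < 0
        assert np.all(mask20[baseline])

    def test_baseline_switch_drops_baseline_points(self, noisy_series):
        m = MonoExpKinetics.from_series(noisy_series, include_baseline=False)
        assert not m.window_mask(0.0)[noisy_series.times < 0].any()
        res = m.fit(0.0)
        assert res.converged

    def test_fit_invariant_to_point_order(self, noisy_series):
        res1 = fit_kinetics(noisy_series, dtr_s=10.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(noisy_series.times))
        m = MonoExpKinetics(noisy_series.times[perm], noisy_series.values[perm])
        res2 = m.fit(10.0)
        np.testing.assert_allclose(res1.params.as_array(),
                                   res2.params.as_array(), rtol=1e-6)

    def test_ase_scales_linearly_with_noise_sd(self, true_params, protocol):
        # same seeds -> identical timing and noise shape, doubled scale; the
        # nonlinearity perturbs single draws, so compare the mean ratio
        ratios = []
        for seed in range(15):
            ases = []
            for sd in (50.0, 100.0):
                s = generate_breath_series(true_params, protocol,
                                           BreathNoiseModel(sd=sd), seed=seed)
                ases.append(fit_kinetics(s, 20.0).ase_for("tau"))
            ratios.append(ases[1] / ases[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_stacking_duplicate_reps_shrinks_ase(self, noisy_series):
        # doubling identical data leaves estimates put but increases df,
        # shrinking the ASE roughly by sqrt(2)
        single = fit_kinetics(noisy_series, 20.0)
        double = fit_kinetics(stack([noisy_series, noisy_series]), 20.0)
        np.testing.assert_allclose(double.params.as_array(),
                                   single.params.as_array(), rtol=1e-4)
        assert double.ase_for("tau") == pytest.approx(
            single.ase_for("tau") / np.sqrt(2), rel=0.05)

    def test_chi2_reported_only_with_known_noise_sd(self, noisy_series):
        plain = fit_kinetics(noisy_series, 0.0)
        assert plain.chi2 is None
        sim = fit_kinetics(noisy_series, 0.0, noise_sd=100.0)
        assert sim.chi2 == pytest.approx(sim.rss / 100.0**2)
        assert 0.0 <= sim.chi2_pvalue <= 1.0

    def test_too_small_window_rejected(self):
        m = MonoExpKinetics(np.array([-5.0, -1.0, 10.0, 20.0]),
                            np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError):
            m.fit(0.0)

    def test_summary_mentions_all_parameters(self, noisy_series):
        text = fit_kinetics(noisy_series, 20.0).summary()
        for name in ("a_b", "da", "tau", "td", "ASE", "df"):
            assert name in text


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [101, 202])
    def test_tau_matches_brute_force_grid_search(self, true_params, protocol,
                                                 noise, seed):
        s = generate_breath_series(true_params, protocol, noise, seed=seed)
        res = fit_kinetics(s, 20.0)
        *_, tau_bf, td_bf, rss_bf = brute_force_fit(s.times, s.values, 20.0)
        assert res.params.tau == pytest.approx(tau_bf, abs=1e-3)
        assert res.params.td == pytest.approx(td_bf, abs=1e-3)
        assert res.rss <= rss_bf * (1 + 1e-6)


class TestSweep:
    def test_default_sweep_has_41_results(self, noisy_series):
        results = sweep_dtr(noisy_series)
        assert len(results) == 41
        assert [r.dtr_s for r in results] == list(range(41))

    def test_single_value_sweep_equals_direct_fit(self, noisy_series):
        sweep = sweep_dtr(noisy_series, [0])[0]
        direct = fit_kinetics(noisy_series, 0.0)
        np.testing.assert_allclose(sweep.params.as_array(),
                                   direct.params.as_array())

    def test_noiseless_estimates_invariant_to_dtr(self, noiseless_series,
                                                  true_params):
        # on-curve data: removing early points is information-neutral
        for res in sweep_dtr(noiseless_series, [0, 10, 20, 40]):
            np.testing.assert_allclose(res.params.as_array(),
                                       true_params.as_array(), rtol=1e-6)

    def test_unsorted_or_negative_dtr_rejected(self, noisy_series):
        with pytest.raises(ValueError):
            sweep_dtr(noisy_series, [10, 0])
        with pytest.raises(ValueError):
            sweep_dtr(noisy_series, [-1, 0])


class TestDfAcrossProcedures:
    def test_stacking_df_linear_bins_df_constant(self, small_cohort):
        reps = small_cohort.subjects[0].reps
        stack_df, bins_df = [], []
        for nr in range(1, len(reps) + 1):
            stack_df.append(fit_kinetics(stack(reps[:nr]), 20.0).df)
            grids = [resample_to_bins(r, 1.0) for r in reps[:nr]]
            from vo2kinetics import average_bins
            bins_df.append(fit_kinetics(average_bins(grids), 20.0).df)
        # stacking: df grows ~linearly (one rep's breaths per step)
        steps = np.diff(stack_df)
        assert np.all(steps > 100)
        assert steps.std() / steps.mean() < 0.1
        # bins: df pinned to the grid length
        assert max(bins_df) - min(bins_df) <= 5
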