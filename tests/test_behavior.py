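"""Behavioral analyses: logistic factorizations, bounded drift-diffusion
choice probabilities and fits, pulse-model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from dvrelay.behavior import (DDMParams, DriftDiffusionModel,
                              _weaker_stronger, compare_pulse_models,
                              ddm_choice_prob, ddm_choice_prob_curve,
                              fit_choice_logistic,
                              simulate_bernoulli_choices)
from dvrelay.config import COHERENCE_MAGNITUDES
from dvrelay.containers import TrialTable
from dvrelay.simulate import simulate_behavior_trials, simulate_dv_paths

from conftest import make_trials


def pulse_table(c1, c2, y_plus):
    n = len(c1)
    return TrialTable(pd.DataFrame({
        "trial_id": np.arange(n), "task_variant": "two_pulse_v1",
        "config_id": 0, "c1": c1, "c2": c2, "t_dur": 0.08,
        "choice": np.where(y_plus, "T_plus", "T_minus"), "correct": True,
    }), validate=False)


def draw_pulses(n, rng):
    m1 = rng.choice(COHERENCE_MAGNITUDES, n)
    m2 = rng.choice(COHERENCE_MAGNITUDES, n)
    sgn = np.where(rng.random(n) < 0.5, 1, -1)
    return m1 * sgn, m2 * sgn


class TestLogistic:
    def test_choice_independent_of_coherence_gives_null_slope(self):
        rng = np.random.default_rng(0)
        c = rng.choice([-0.32, -0.08, 0.08, 0.32], 3000)
        t = make_trials([{"trial_id": i, "c1": ci,
                          "choice": "T_plus" if rng.random() < 0.5 else "T_minus"}
                         for i, ci in enumerate(c)], validate=False)
        fit = fit_choice_logistic(t, "C")
        assert abs(fit.beta1) < 2 * fit.bse[1]

    def test_recovery_coverage_from_pulse_average_model(self):
        # choices generated from logit = 0 + 10 * Cavg; the 95% CI should
        # cover the true slope in the vast majority of replicate fits
        rng = np.random.default_rng(1)
        hits = 0
        reps = 60
        for _ in range(reps):
            c1, c2 = draw_pulses(5000, rng)
            cavg = (c1 + c2) / 2
            y = rng.random(5000) < 1 / (1 + np.exp(-10 * cavg))
            f = fit_choice_logistic(pulse_table(c1, c2, y), "Cavg")
            hits += abs(f.params[1] - 10) < 1.96 * f.bse[1]
        assert hits / reps >= 0.85

    def test_deterministic_choices_flag_separation(self):
        c = np.repeat([-0.32, -0.04, 0.04, 0.32], 50)
        t = make_trials([{"trial_id": i, "c1": ci,
                          "choice": "T_plus" if ci > 0 else "T_minus"}
                         for i, ci in enumerate(c)], validate=False)
        assert fit_choice_logistic(t, "C").separation

    def test_unknown_spec_rejected(self):
        t = make_trials([{"c1": 0.1}, {"c1": -0.1}], validate=False)
        with pytest.raises(ValueError, match="spec"):
            fit_choice_logistic(t, "Cmax")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-0.64, 0.64), st.floats(-0.64, 0.64))
    def test_weaker_stronger_split(self, a, b):
        w, s = _weaker_stronger(np.array([a]), np.array([b]))
        assert abs(w[0]) <= abs(s[0])
        if abs(a) == abs(b):          # tie: first pulse labelled weaker
            assert w[0] == a and s[0] == b


class TestChoiceProb:
    def test_zero_net_drift_is_exactly_half(self):
        assert ddm_choice_prob(DDMParams(15, 1.0, 0.02), -0.02, 0.3) == \
            pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("c,t", [(0.08, 0.1), (0.08, 0.5), (0.32, 0.1),
                                     (0.32, 0.5), (0.64, 0.3)])
    def test_unbounded_limit_matches_normal_cdf(self, c, t):
        p = ddm_choice_prob(DDMParams(10, 1e6, 0.0), c, t)
        assert p == pytest.approx(norm.cdf(10 * c * np.sqrt(t)), abs=1e-3)

    def test_monotone_in_coherence_and_reflection_symmetric(self):
        params = DDMParams(15, 1.0, 0.0)
        cs = [-0.64, -0.16, -0.04, 0, 0.04, 0.16, 0.64]
        ps = [ddm_choice_prob(params, c, 0.4) for c in cs]
        assert (np.diff(ps) > 0).all()
        for c, p in zip(cs, ps):
            p_neg = ddm_choice_prob(params, -c, 0.4)
            assert p + p_neg == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_monte_carlo_paths(self):
        # brute-force Euler paths at the same step size are the oracle
        params = DDMParams(15, 1.0, 0.02)
        p = ddm_choice_prob(params, 0.08, 0.3)
        rng = np.random.default_rng(3)
        n = 100_000
        _, choice, _, _ = simulate_dv_paths(params, np.full(n, 0.08),
                                            np.full(n, 600), 5e-4, rng)
        mc = (choice > 0).mean()
        assert abs(p - mc) < 3 * np.sqrt(mc * (1 - mc) / n)

    def test_curve_is_probability_and_t0_is_half(self):
        t, p = ddm_choice_prob_curve(DDMParams(20, 0.8, -0.05), 0.16, 0.5)
        assert p[0] == 0.5
        assert ((p >= 0) & (p <= 1)).all()

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            ddm_choice_prob(DDMParams(10, 1.0, 0.0), 0.1, 0.0)


class TestFitDDM:
    def test_recovery_at_moderate_n(self):
        # kappa and C0 are well identified; the bound only loosely (choices
        # carry little information about B in this task regime)
        true = DDMParams(15.0, 1.0, 0.0)
        trials = simulate_behavior_trials(true, 6000, seed=4)
        res = DriftDiffusionModel(trials, dt=1e-3).fit()
        assert abs(res.params.kappa - 15) / 15 < 0.15
        assert abs(res.params.C0) < 0.02
        assert 0.4 < res.params.B < 2.5

    def test_likelihood_dominance_near_truth(self):
        true = DDMParams(15.0, 1.0, 0.0)
        trials = simulate_behavior_trials(true, 10_000, seed=5)
        m = DriftDiffusionModel(trials, dt=1e-3)
        ll_true = m.loglike(true)
        # perturbations along identified directions must lose likelihood
        for p in (DDMParams(22.5, 1.0, 0.0), DDMParams(7.5, 1.0, 0.0),
                  DDMParams(15.0, 0.5, 0.0), DDMParams(15.0, 1.0, 0.05),
                  DDMParams(15.0, 1.0, -0.05)):
            assert m.loglike(p) < ll_true

    def test_rmse_improves_with_sample_size(self):
        true = DDMParams(15.0, 1.0, 0.0)
        errs = {2000: [], 20_000: []}
        for rep in range(6):
            for n in errs:
                trials = simulate_behavior_trials(true, n, seed=100 + rep + n)
                res = DriftDiffusionModel(trials, dt=2e-3,
                                          grid_points=200).fit(maxiter=150)
                errs[n].append((res.params.kappa - 15) ** 2)
        assert np.mean(errs[20_000]) < np.mean(errs[2000])

    def test_degenerate_all_correct_hits_search_bounds(self):
        t = simulate_behavior_trials(DDMParams(15, 1.0, 0.0), 2000, seed=6)
        df = t.df[t.df.c1 != 0].copy()
        df["choice"] = np.where(df.c1 > 0, "T_plus", "T_minus")
        res = DriftDiffusionModel(TrialTable(df, validate=False), dt=2e-3,
                                  grid_points=200).fit(maxiter=150)
        assert res.at_bounds

    def test_needs_multiple_coherences_and_durations(self):
        t = make_trials([{"c1": 0.1, "t_dur": 0.3},
                         {"c1": 0.1, "t_dur": 0.3}], validate=False)
        with pytest.raises(ValueError):
            DriftDiffusionModel(t)


@pytest.fixture(scope="module")
def comparison():
    # data generated under Model-2 (both pulses summed)
    rng = np.random.default_rng(7)
    c1, c2 = draw_pulses(10_000, rng)
    y = simulate_bernoulli_choices(2, 0.0, 5.0, c1, c2, rng)
    data = pulse_table(c1, c2, y)
    return compare_pulse_models(data, n_choices=10_000, n_reps=50, seed=8)


class TestPulseModels:
    def test_model2_weights_equal(self, comparison):
        mu, _ = comparison.ensemble_stats(2)
        assert 0.9 < mu[0] / mu[1] < 1.1

    def test_model1_overweights_weaker_pulse(self, comparison):
        mu, _ = comparison.ensemble_stats(1)
        assert mu[0] > mu[1]

    def test_order_factorization_does_not_separate_models(self, comparison):
        mu1, _ = comparison.ensemble_stats(1, order=True)
        mu2, _ = comparison.ensemble_stats(2, order=True)
        assert abs(mu1[0] / mu1[1] - 1) < 0.1
        assert abs(mu2[0] / mu2[1] - 1) < 0.1

    def test_model2_data_identified_as_model2(self, comparison):
        d = comparison.data_fit_ws.params[1:]
        mu2, sd2 = comparison.ensemble_stats(2)
        mu1, sd1 = comparison.ensemble_stats(1)
        assert (np.abs(d - mu2) < 2 * sd2).all()
        assert (np.abs(d - mu1) > 2 * sd1).any()

    def test_too_few_reps_rejected(self):
        rng = np.random.default_rng(9)
        c1, c2 = draw_pulses(200, rng)
        y = simulate_bernoulli_choices(2, 0.0, 5.0, c1, c2, rng)
        with pytest.raises(ValueError):
            compare_pulse_models(pulse_table(c1, c2, y), n_reps=1)
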