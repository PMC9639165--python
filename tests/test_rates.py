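"""Firing-rate estimation, truncation rules, buildup rate, P2 analyses."""

import numpy as np
import pandas as pd
import pytest

from dvrelay.config import WINDOW_WIDTH
from dvrelay.containers import SpikeData, TrialTable
from dvrelay.rates import (buildup_rate, isolate_p2_component,
                           p2_regressions, smooth_rate)
from dvrelay.simulate import sample_subpoisson_counts

from conftest import make_spikes, make_trials, poisson_spike_trains


class TestSmoothRate:
    def test_constant_rate_recovered_flat(self):
        rng = np.random.default_rng(0)
        n = 5000
        trains = poisson_spike_trains(20.0, 1.2, n, rng)
        t = make_trials([{"trial_id": i, "motion_on": 0.2, "t_dur": 0.55}
                         for i in range(n)], validate=False)
        s = smooth_rate(SpikeData({0: trains}), t, "motion_on",
                        span=(0.0, 0.5), truncate=False)
        r = s.rates["all"]
        assert np.nanmax(np.abs(r - 20.0)) < 1.0

    def test_zero_spikes_zero_series(self):
        t = make_trials([{"motion_on": 0.2}], validate=False)
        s = smooth_rate(make_spikes({0: {}}), t, "motion_on",
                        span=(0.0, 0.4), truncate=False)
        assert np.nansum(np.abs(s.rates["all"])) == 0

    def test_single_spike_rectangular_bump(self):
        # unit impulse through a 100-ms boxcar at one trial: 10 sp/s plateau
        t = make_trials([{"motion_on": 0.5}], validate=False)
        s = smooth_rate(make_spikes({0: {0: [0.8]}}), t, "motion_on",
                        span=(0.0, 0.6), grid_step=0.001, truncate=False)
        r, tau = s.rates["all"], s.time
        inside = np.abs(tau - 0.3) < 0.049
        outside = np.abs(tau - 0.3) > 0.051
        assert np.allclose(r[inside], 10.0)
        assert np.allclose(r[outside], 0.0)

    def test_rate_integrates_to_count_per_trial(self):
        rng = np.random.default_rng(1)
        n = 400
        trains = poisson_spike_trains(25.0, 1.0, n, rng)
        t = make_trials([{"trial_id": i, "motion_on": 0.0, "t_dur": 0.55}
                         for i in range(n)], validate=False)
        s = smooth_rate(SpikeData({0: trains}), t, "motion_on",
                        span=(0.1, 0.9), grid_step=0.001, truncate=False)
        # integral over [0.2, 0.8] ~ spikes in [0.2, 0.8] per trial (boxcar
        # conserves mass away from edges)
        sel = (s.time >= 0.2) & (s.time < 0.8)
        integral = np.nansum(s.rates["all"][sel]) * 0.001
        count = np.mean([((tr >= 0.2) & (tr < 0.8)).sum() for tr in trains.values()])
        assert integral == pytest.approx(count, rel=0.02)

    def test_poisoned_spike_after_truncation_never_counts(self):
        # spikes later than motion_off + 250 ms are excluded by construction
        t = make_trials([{"motion_on": 0.2, "t_dur": 0.2,
                          "motion_off": 0.4}], validate=False)
        poison = make_spikes({0: {0: [0.66, 0.9, 1.2]}})  # cutoff = 0.65
        s = smooth_rate(poison, t, "motion_on", span=(0.0, 1.0),
                        truncate=True)
        assert np.nansum(np.abs(s.rates["all"])) == 0

    def test_grouping_by_trial_column(self):
        t = make_trials([{"motion_on": 0.2, "choice": "T_plus"},
                         {"motion_on": 0.2, "choice": "T_minus"}],
                        validate=False)
        s = smooth_rate(make_spikes({0: {0: [0.4], 1: []}}), t, "motion_on",
                        group_by="choice", span=(0.0, 0.4), truncate=False)
        assert set(s.rates) == {"T_plus", "T_minus"}
        assert s.n_trials == {"T_plus": 1, "T_minus": 1}


def ramp_dataset(slope_per_coh: float, r0: float, n_per: int, rng,
                 extra_rate=None):
    """Spikes with deterministic latent ramp r0 + slope*c*t over 600 ms."""
    cs = np.array([-0.64, -0.32, -0.16, -0.08, -0.04, 0.0,
                   0.04, 0.08, 0.16, 0.32, 0.64])
    c1 = np.repeat(cs, n_per)
    n = len(c1)
    bins = np.arange(0, 0.6, 0.02)
    tmid = bins + 0.01
    rate = r0 + slope_per_coh * c1[:, None] * tmid[None, :]
    if extra_rate is not None:
        rate = rate + extra_rate(tmid)[None, :]
    rate = np.maximum(rate, 0.0)
    counts = sample_subpoisson_counts(rate * 0.02, 0.6, rng)
    spikes = {}
    for i in range(n):
        k = counts[i]
        ts = np.repeat(bins, k) + 0.02 * rng.random(int(k.sum())) + 0.3
        spikes[i] = np.sort(ts)
    trials = make_trials([{"trial_id": i, "c1": c, "t_dur": 0.55,
                           "motion_on": 0.3, "motion_off": 0.85,
                           "choice": "T_plus" if c >= 0 else "T_minus"}
                          for i, c in enumerate(c1)], validate=False)
    return SpikeData({0: spikes}), trials


class TestBuildupRate:
    def test_deterministic_ramp_recovers_slope(self):
        rng = np.random.default_rng(2)
        spikes, trials = ramp_dataset(100.0, 40.0, 400, rng)
        res = buildup_rate(spikes, trials)
        assert not res.flagged
        assert res.onset == pytest.approx(0.0, abs=0.051)
        assert res.slope_vs_coherence == pytest.approx(100.0, rel=0.10)

    def test_detrending_removes_condition_independent_drive(self):
        rng = np.random.default_rng(3)
        spikes_a, trials_a = ramp_dataset(100.0, 40.0, 300, rng)
        spikes_b, trials_b = ramp_dataset(
            100.0, 40.0, 300, rng,
            extra_rate=lambda t: 30 * np.sin(2 * np.pi * t / 0.3))
        ra = buildup_rate(spikes_a, trials_a)
        rb = buildup_rate(spikes_b, trials_b)
        tol = 3 * np.hypot(ra.slope_se, rb.slope_se)
        assert abs(ra.slope_vs_coherence - rb.slope_vs_coherence) < tol

    def test_no_signal_flags_missing_onset(self):
        rng = np.random.default_rng(4)
        spikes, trials = ramp_dataset(0.0, 30.0, 150, rng)
        res = buildup_rate(spikes, trials)
        assert res.flagged and res.onset is None

    def test_requires_both_strongest_directions(self):
        t = make_trials([{"c1": 0.64, "motion_on": 0.2, "t_dur": 0.3,
                          "motion_off": 0.5}], validate=False)
        with pytest.raises(ValueError, match="direction"):
            buildup_rate(make_spikes({0: {}}), t)


class TestP2Analyses:
    def test_carryover_and_update_detected(self, tp1_session):
        leaders = list(range(6))
        res = p2_regressions(tp1_session.spikes, tp1_session.trials, leaders)
        assert res.alpha1 > 0 and res.p_alpha1 < 0.01
        assert res.beta1 > 0 and res.p_beta1 < 0.01

    def test_inactive_pool_shows_no_carryover(self, tp2_session):
        # variant-2 leaders are silent in the P2 epoch: alpha1, beta1 ~ 0
        leaders = list(range(6))
        res = p2_regressions(tp2_session.spikes, tp2_session.trials, leaders)
        per = res.per_choice
        assert (np.abs(per["alpha1"]) < 2 * per["alpha1_se"]).all()
        assert (np.abs(per["beta1"]) < 3 * per["beta1_se"]).all()

    def test_supporters_receive_p2_in_variant2(self, tp2_session):
        supporters = list(range(6, 12))
        res = p2_regressions(tp2_session.spikes, tp2_session.trials, supporters)
        assert res.alpha1 > 0 and res.p_alpha1 < 0.01
        assert res.beta1 > 0 and res.p_beta1 < 0.01

    def test_shuffling_c2_kills_beta1_keeps_alpha1(self, tp1_session):
        trials = tp1_session.trials
        res = p2_regressions(tp1_session.spikes, trials, list(range(6)))
        rng = np.random.default_rng(5)
        df = trials.df.copy()
        nc = np.isfinite(df["c2"].to_numpy(float))
        df.loc[nc, "c2"] = rng.permutation(df.loc[nc, "c2"].to_numpy())
        shuf = p2_regressions(tp1_session.spikes,
                              TrialTable(df, validate=False),
                              list(range(6)))
        per = shuf.per_choice
        assert (np.abs(per["beta1"]) < 3 * per["beta1_se"]).all()
        # Eq. 8 does not involve c2: alpha identical
        assert shuf.alpha1 == pytest.approx(res.alpha1, abs=1e-12)

    def test_isolated_p2_component_ordered_and_baseline_zero(self, tp1_session):
        iso = isolate_p2_component(tp1_session.spikes, tp1_session.trials,
                                   neuron_ids=list(range(6)))
        base = np.abs(iso.time) <= WINDOW_WIDTH / 2 + 1e-9
        post = (iso.time > 0.25) & (iso.time < 0.55)
        groups = sorted(iso.rates)
        base_means = [np.nanmean(iso.rates[g][base]) for g in groups]
        assert np.max(np.abs(base_means)) < 1e-10
        post_means = [np.nanmean(iso.rates[g][post]) for g in groups]
        assert np.corrcoef(groups, post_means)[0, 1] > 0.9
        assert post_means[-1] > post_means[0]

    def test_single_c2_group_is_identically_zero(self, tp1_session):
        trials = tp1_session.trials
        only0 = trials.subset(trials.df["c2"].to_numpy() == 0.0)
        iso = isolate_p2_component(tp1_session.spikes, only0,
                                   neuron_ids=[0, 1])
        assert np.nanmax(np.abs(iso.rates[0.0])) < 1e-10

    def test_variant_without_p2_rejected(self, vd_session):
        with pytest.raises(ValueError, match="P2"):
            isolate_p2_component(vd_session.spikes, vd_session.trials)
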