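"""VarCE/CorCE statistics, Fano-factor calibration, permutation inference,
mediation regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dvrelay.corce import (corce_matrix, corce_pair,
                           diffusion_corr_prediction, estimate_phi,
                           mediation_regressions, permutation_null,
                           residual_counts, varce)
from dvrelay.simulate import (sample_subpoisson_counts,
                              simulate_diffusion_counts,
                              simulate_pair_epochs)


class TestResiduals:
    def test_two_point_group(self):
        res = residual_counts(np.array([3.0, 5.0]), np.zeros(2))
        assert res.tolist() == [-1.0, 1.0]

    def test_equal_counts_give_zero_residuals(self):
        res = residual_counts(np.full(6, 7.0), np.repeat([0, 1], 3))
        assert (res == 0).all()

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(hnp.arrays(np.float64, st.integers(4, 40),
                      elements=st.floats(0, 50)),
           st.data())
    def test_group_means_vanish(self, counts, data):
        groups = data.draw(st.lists(st.sampled_from([0, 1, 2]),
                                    min_size=len(counts),
                                    max_size=len(counts)))
        groups = np.asarray(groups)
        # ensure no singleton groups
        for g in np.unique(groups):
            if (groups == g).sum() < 2:
                groups[groups == g] = 0
        if (groups == 0).sum() == 1:
            groups[:2] = 0
        res = residual_counts(counts, groups)
        for g in np.unique(groups):
            assert abs(res[groups == g].sum()) < 1e-8

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="single"):
            residual_counts(np.array([1.0, 2.0, 3.0]),
                            np.array([0, 0, 1]))


class TestVarCE:
    def test_poisson_counts_have_no_latent_variance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(9.0, 20_000).astype(float)
        res = residual_counts(counts, np.zeros(len(counts)))
        v = varce(res, counts.mean(), 1.0)
        assert abs(v.value if not v.clipped else 0.0) < 0.3

    def test_latent_rate_variance_recovered(self):
        # law of total variance: Var(count) = phi*mean + (window*sd_rate)^2
        rng = np.random.default_rng(1)
        n = 20_000
        rates = 30.0 + 10.0 * rng.standard_normal(n)
        rates = np.clip(rates, 0, None)
        counts = sample_subpoisson_counts(rates * 0.3, 0.6, rng).astype(float)
        res = residual_counts(counts, np.zeros(n))
        v = varce(res, counts.mean(), 0.6)
        expect = np.var(rates * 0.3)
        assert v.value == pytest.approx(expect, rel=0.06)

    def test_phi_zero_returns_raw_variance(self):
        x = np.array([1.0, 2.0, 6.0, 3.0])
        res = residual_counts(x, np.zeros(4))
        v = varce(res, x.mean(), 0.0)
        assert v.value == pytest.approx(np.var(x, ddof=1))

    def test_negative_estimate_clipped_and_flagged(self):
        v = varce(np.array([-0.5, 0.5, -0.5, 0.5]), 100.0, 1.0)
        assert v.value == 0.0 and v.clipped

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            varce(np.array([0.0]), 1.0, 0.5)


class TestCorCE:
    def test_self_pair_is_unity(self):
        rng = np.random.default_rng(2)
        x = sample_subpoisson_counts(np.full(5000, 9.0), 0.6, rng) \
            + rng.integers(0, 3, 5000)
        c = corce_pair(x, x, np.zeros(len(x)), 0.6, shared_point_noise=True)
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_independent_pools_near_zero(self):
        df = simulate_pair_epochs(3000, independent=True, seed=3)
        perm = permutation_null(df.l_pre.to_numpy(), df.s_iem.to_numpy(),
                                df.c1.to_numpy(), 0.6, n_perm=500, seed=4)
        assert abs(perm.observed) < 3 * perm.null_sd

    def test_recovers_latent_correlation_where_pearson_attenuates(self):
        df = simulate_pair_epochs(20_000, pool_size=1, sigma_pool=0.15,
                                  sigma_member=0.0, seed=5)
        cond = df.c1.to_numpy()
        lr = residual_counts(df.lam_l_pre.to_numpy() * 0.3, cond)
        sr = residual_counts(df.lam_s.to_numpy() * 0.3, cond)
        latent = (lr @ sr) / np.sqrt((lr @ lr) * (sr @ sr))
        cc = corce_pair(df.l_pre.to_numpy(), df.s_iem.to_numpy(), cond, 0.6)
        lres = residual_counts(df.l_pre.to_numpy(), cond)
        sres = residual_counts(df.s_iem.to_numpy(), cond)
        pearson = np.corrcoef(lres, sres)[0, 1]
        assert cc == pytest.approx(latent, abs=0.05)
        assert pearson < latent - 0.2
        assert cc > pearson

    def test_invariant_to_condition_dependent_offsets(self):
        # residualization removes any per-condition constant; with phi = 0
        # (no point-process subtraction, which depends on the raw mean) the
        # CorCE is exactly invariant
        df = simulate_pair_epochs(4000, seed=6)
        cond = df.c1.to_numpy()
        l, s = df.l_pre.to_numpy(float), df.s_iem.to_numpy(float)
        offs = {c: 50 * np.cos(i) for i, c in enumerate(np.unique(cond))}
        shift = np.array([offs[c] for c in cond])
        assert np.allclose(residual_counts(l, cond),
                           residual_counts(l + shift, cond))
        base = corce_pair(l, s, cond, 0.0)
        shifted = corce_pair(l + shift, s - 2 * shift, cond, 0.0)
        assert shifted == pytest.approx(base, abs=1e-12)


class TestEstimatePhi:
    def test_recovers_generating_fano_factor(self):
        counts, _ = simulate_diffusion_counts(10_000, phi=0.6, seed=7)
        est = estimate_phi(counts)
        assert 0.5 <= est.phi <= 0.7

    def test_poisson_counts_give_phi_near_one(self):
        counts, _ = simulate_diffusion_counts(10_000, phi=1.0, seed=8)
        assert estimate_phi(counts).phi >= 0.9

    def test_reported_phi_is_grid_argmin(self):
        counts, _ = simulate_diffusion_counts(2000, seed=9)
        est = estimate_phi(counts)
        assert est.phi == est.grid[np.argmin(est.objective)]
        assert np.isfinite(est.objective).any()

    def test_diffusion_prediction_shapes(self):
        p = diffusion_corr_prediction(5, "sqrt")
        assert p.shape == (5, 5)
        assert p[0, 4] == pytest.approx(np.sqrt(1 / 5))
        lin = diffusion_corr_prediction(5, "linear")
        assert lin[0, 4] == pytest.approx(1 / 5)
        # 5 bins -> 10 unique off-diagonal values
        assert len(np.triu_indices(5, k=1)[0]) == 10

    def test_diffusion_corce_matches_sqrt_prediction(self):
        counts, _ = simulate_diffusion_counts(20_000, phi=0.6, seed=10)
        C = corce_matrix(counts, None, 0.6)
        pred = diffusion_corr_prediction(counts.shape[1])
        iu = np.triu_indices_from(C, k=1)
        z = np.arctanh(np.clip(C[iu], -0.999, 0.999)) - np.arctanh(pred[iu])
        assert np.sqrt(np.mean(z ** 2)) < 0.05

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_phi(np.full((50, 5), 3.0))


class TestPermutationNull:
    def test_identical_vectors_extreme_p(self):
        rng = np.random.default_rng(11)
        x = sample_subpoisson_counts(np.full(500, 12.0), 0.6, rng).astype(float)
        x += rng.integers(0, 12, 500)  # substantial latent variance
        perm = permutation_null(x, x, np.zeros(500), 0.6, n_perm=500, seed=12)
        assert perm.pvalue <= 2 / 501

    def test_null_centered_on_zero(self):
        df = simulate_pair_epochs(2000, independent=True, seed=13)
        perm = permutation_null(df.l_pre.to_numpy(), df.s_iem.to_numpy(),
                                df.c1.to_numpy(), 0.6, n_perm=1000, seed=14)
        assert abs(perm.null_mean) < 3 * perm.null_sd / np.sqrt(1000)

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(np.ones(10), np.ones(10), np.zeros(10), 0.6,
                             n_perm=10)


class TestMediation:
    def test_independent_pools_show_no_transfer(self):
        df = simulate_pair_epochs(4000, independent=True, seed=15)
        out = mediation_regressions(df.l_pre, df.s_iem, df.l_post,
                                    df.c1, df.choice)
        res = out["s_on_lpre"]
        assert abs(res.params[3]) < 3 * res.bse[3]

    def test_pool_size_controls_conditional_autocorrelation(self):
        big = simulate_pair_epochs(5000, pool_size=50, sigma_pool=0.10, seed=16)
        one = simulate_pair_epochs(5000, pool_size=1, sigma_pool=0.0, seed=17)
        r_big = mediation_regressions(big.l_pre, big.s_iem, big.l_post,
                                      big.c1, big.choice)["mediation"]
        r_one = mediation_regressions(one.l_pre, one.s_iem, one.l_post,
                                      one.c1, one.choice)["mediation"]
        assert r_big.params[3] > 0 and r_big.pvalues[3] < 0.01
        assert abs(r_one.params[3]) < 2 * r_one.bse[3]

    def test_rank_deficient_design_names_columns(self):
        df = simulate_pair_epochs(500, seed=18)
        with pytest.raises(ValueError, match="C1st"):
            mediation_regressions(df.l_pre, df.s_iem, df.l_post,
                                  np.zeros(len(df)), df.choice)

    def test_coefficient_table_is_tidy(self):
        df = simulate_pair_epochs(800, seed=19)
        out = mediation_regressions(df.l_pre, df.s_iem, df.l_post,
                                    df.c1, df.choice)
        tab = out["table"]
        assert set(tab.model) == {"s_on_lpre", "lpost_on_s", "autocorr",
                                  "mediation"}
        assert {"coef", "se", "p"} <= set(tab.columns)
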