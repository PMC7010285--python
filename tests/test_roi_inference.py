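"""ROI extraction, random-intercept LMM, model comparison, RT analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from valuedyn import roi_inference as ri
from valuedyn.errors import InvalidArgumentError


class TestExtractROIMeans:
    def test_uniform_map(self):
        mask = np.zeros((4, 4, 2), bool)
        mask[1:3, 1:3, :] = True
        out = ri.extract_roi_means({"a": np.full((4, 4, 2), 3.25)}, mask)
        assert out["a"] == 3.25

    def test_single_voxel_mask(self, rng):
        vol = rng.normal(size=(4, 4, 2))
        mask = np.zeros((4, 4, 2), bool)
        mask[2, 1, 0] = True
        assert ri.extract_roi_means({"a": vol}, mask)["a"] == vol[2, 1, 0]

    def test_checkerboard_cancels(self):
        vol = np.indices((4, 4, 2)).sum(axis=0) % 2 * 2.0 - 1.0
        mask = np.ones((4, 4, 2), bool)
        assert ri.extract_roi_means({"a": vol}, mask)["a"] == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ri.extract_roi_means({"a": np.zeros((2, 2, 2))}, np.zeros((2, 2, 2), bool))


def _balanced_data(rng, n_subj=28, n_per=4, b=(-19.08, 5.10, 18.16),
                   su=14.6, se=9.0):
    g = np.repeat(np.arange(n_subj), n_per)
    v = rng.uniform(-1, 1, n_subj * n_per)
    u = rng.normal(0, su, n_subj)
    y = b[0] + b[1] * v + (b[2] * v ** 2 if len(b) > 2 else 0.0) \
        + u[g] + rng.normal(0, se, len(g))
    X = np.column_stack([np.ones_like(v), v, v ** 2])
    return y, X, v, g


class TestRandomInterceptLMM:
    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        y, X, v, g = _balanced_data(rng)
        mine = ri.fit_random_intercept_lmm(y, X, g, "REML")
        df = pd.DataFrame(dict(y=y, v=v, v2=v ** 2, g=g))
        ref = sm.MixedLM.from_formula("y ~ v + v2", groups="g", data=df).fit(reml=True)
        np.testing.assert_allclose(mine.params, ref.params.values[:3], rtol=1e-5)
        np.testing.assert_allclose(mine.sigma_u, np.sqrt(ref.cov_re.values[0, 0]),
                                   rtol=1e-4)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-5)
        ml = ri.fit_random_intercept_lmm(y, X, g, "ML")
        ref_ml = sm.MixedLM.from_formula("y ~ v + v2", groups="g", data=df).fit(reml=False)
        assert ml.loglik == pytest.approx(ref_ml.llf, abs=1e-5)

    def test_fixed_effects_match_gls_matrix_oracle(self, rng):
        y, X, _, g = _balanced_data(rng, n_subj=10)
        res = ri.fit_random_intercept_lmm(y, X, g, "REML")
        Z = np.zeros((len(y), 10))
        Z[np.arange(len(y)), g] = 1.0
        V = res.sigma_u ** 2 * Z @ Z.T + res.sigma_e ** 2 * np.eye(len(y))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(res.params, beta, atol=1e-8)

    def test_zero_between_subject_variance_reduces_to_ols(self, rng):
        # group-centred noise has *less* between-group spread than chance,
        # so the variance component is driven to its zero boundary
        n_subj, n_per = 12, 6
        g = np.repeat(np.arange(n_subj), n_per)
        x = rng.uniform(-1, 1, len(g))
        eps = rng.normal(0, 1.0, len(g))
        eps -= np.repeat(eps.reshape(n_subj, n_per).mean(axis=1), n_per)
        y = 2.0 + 3.0 * x + eps
        X = np.column_stack([np.ones_like(x), x])
        res = ri.fit_random_intercept_lmm(y, X, g, "ML")
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.boundary
        assert res.sigma_u == 0.0
        np.testing.assert_allclose(res.params, ols, atol=1e-8)

    def test_quadratic_nests_linear_in_ml_loglik(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            y, X, _, g = _balanced_data(local, b=(-19.0, 5.0))
            lin = ri.fit_random_intercept_lmm(y, X[:, :2], g, "ML")
            quad = ri.fit_random_intercept_lmm(y, X, g, "ML")
            assert quad.loglik >= lin.loglik - 1e-8

    def test_single_subject_rejected(self, rng):
        y = rng.normal(size=8)
        X = np.ones((8, 1))
        with pytest.raises(InvalidArgumentError):
            ri.fit_random_intercept_lmm(y, X, np.zeros(8, dtype=int))

    def test_information_criteria_definitions(self, rng):
        y, X, _, g = _balanced_data(rng)
        res = ri.fit_random_intercept_lmm(y, X, g, "ML")
        k = X.shape[1] + 2
        assert res.aic == pytest.approx(-2 * res.loglik_ml + 2 * k)
        assert res.bic == pytest.approx(-2 * res.loglik_ml + k * np.log(len(y)))


class TestLikelihoodRatioTest:
    def test_identical_models_give_null_result(self, rng):
        y, X, _, g = _balanced_data(rng)
        a = ri.fit_random_intercept_lmm(y, X[:, :2], g, "ML")
        b = ri.fit_random_intercept_lmm(y, X[:, :2] * 1.0, g, "ML")
        b2 = ri.LMMResult(**{**b.__dict__, "param_names": ["i", "v", "extra"]})
        chi2, df, p = ri.likelihood_ratio_test(a, b2)
        assert chi2 == pytest.approx(0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_df_one_for_added_quadratic(self, rng):
        y, X, _, g = _balanced_data(rng)
        lin = ri.fit_random_intercept_lmm(y, X[:, :2], g, "ML")
        quad = ri.fit_random_intercept_lmm(y, X, g, "ML")
        _, df, _ = ri.likelihood_ratio_test(lin, quad)
        assert df == 1

    def test_reml_fits_refused(self, rng):
        y, X, _, g = _balanced_data(rng)
        lin = ri.fit_random_intercept_lmm(y, X[:, :2], g, "REML")
        quad = ri.fit_random_intercept_lmm(y, X, g, "REML")
        with pytest.raises(InvalidArgumentError):
            ri.likelihood_ratio_test(lin, quad)

    def test_power_for_true_quadratic_effect(self, rng):
        """With a commit-phase-sized quadratic effect the LRT rejects
        essentially always at study scale (40 replicates here)."""
        hits = 0
        for rep in range(40):
            local = np.random.default_rng(900 + rep)
            y, X, _, g = _balanced_data(local, b=(-20.9, 2.9, 18.16),
                                        su=19.2, se=9.0)
            lin = ri.fit_random_intercept_lmm(y, X[:, :2], g, "ML")
            quad = ri.fit_random_intercept_lmm(y, X, g, "ML")
            _, _, p = ri.likelihood_ratio_test(lin, quad)
            hits += p < 0.001
        assert hits >= 38


class TestSimulatedCIs:
    def test_huge_effect_excludes_zero(self, rng):
        y, X, _, g = _balanced_data(rng, b=(-19.0, 5.0, 18.0), se=1.0)
        res = ri.fit_random_intercept_lmm(y, X, g, "REML")
        cis = ri.simulate_fixed_effect_cis(res, n_sim=2000, seed=0)
        lo, hi = cis["b2"]
        assert lo > 0 or hi < 0

    def test_converges_to_normal_quantiles(self, rng):
        y, X, _, g = _balanced_data(rng)
        res = ri.fit_random_intercept_lmm(y, X, g, "REML")
        cis = ri.simulate_fixed_effect_cis(res, n_sim=200000, seed=1)
        for i, name in enumerate(res.param_names):
            lo, hi = cis[name]
            half = (hi - lo) / 2
            assert half == pytest.approx(1.96 * res.se[i], rel=0.02)

    def test_seeded_determinism(self, rng):
        y, X, _, g = _balanced_data(rng)
        res = ri.fit_random_intercept_lmm(y, X, g, "REML")
        assert ri.simulate_fixed_effect_cis(res, 500, seed=4) == \
            ri.simulate_fixed_effect_cis(res, 500, seed=4)


def _summaries_from(b, n_subj, su, se, seed, phase="offer"):
    local = np.random.default_rng(seed)
    rows = []
    conds = ["RejCon", "RejAmb", "AccAmb", "AccCon"]
    centers = np.array([-0.85, -0.35, 0.35, 0.85])
    u = local.normal(0, su, n_subj)
    for s in range(n_subj):
        v = np.clip(centers + local.normal(0, 0.08, 4), -1, 1)
        y = b[0] + b[1] * v + (b[2] * v ** 2 if len(b) > 2 else 0.0) \
            + u[s] + local.normal(0, se, 4)
        for c, vv, yy in zip(conds, v, y):
            rows.append(dict(subject=s, phase=phase, condition=c,
                             roi_mean=yy, signed_value_mean=vv))
    return pd.DataFrame(rows)


class TestCompareLinearQuadratic:
    def test_linear_generative_data_prefers_linear(self):
        wins = 0
        for rep in range(30):
            summ = _summaries_from((-19.1, 5.1), 28, 14.6, 5.0, seed=100 + rep)
            mc = ri.compare_linear_quadratic(summ, "offer", n_sim=200, seed=rep)
            wins += mc.winner == "linear"
        assert wins >= 26  # type-I controlled near alpha = .05

    def test_quadratic_generative_data_prefers_quadratic(self):
        wins = 0
        for rep in range(30):
            summ = _summaries_from((-20.9, 2.9, 18.2), 28, 19.2, 5.0,
                                   seed=200 + rep, phase="commit")
            mc = ri.compare_linear_quadratic(summ, "commit", n_sim=200, seed=rep)
            wins += mc.winner == "quadratic"
        assert wins >= 29

    def test_missing_condition_rejected(self):
        summ = _summaries_from((-19.1, 5.1), 8, 14.6, 5.0, seed=0)
        broken = summ[summ.condition != "RejAmb"]
        with pytest.raises(InvalidArgumentError):
            ri.compare_linear_quadratic(broken, "offer")

    def test_lrt_pvalues_approximately_uniform_under_null(self):
        """Testing the quadratic fixed effect involves no boundary issue,
        so null LRT p-values should be near-uniform (KS at alpha = .01)."""
        ps = []
        for rep in range(200):
            summ = _summaries_from((-19.1, 5.1), 28, 14.6, 5.0, seed=3000 + rep)
            mc = ri.compare_linear_quadratic(summ, "offer", n_sim=100, seed=rep)
            ps.append(mc.lrt_p)
        d, p = stats.kstest(ps, "uniform")
        assert p > 0.01


class TestRTAnalysis:
    def _trials(self, rng, n_subj=10, n_trials=150, b=(800.0, -35.0, -77.0),
                sigma=60.0):
        rows = []
        for s in range(n_subj):
            v = rng.uniform(-1, 1, n_trials)
            sv = 2.5 * v  # a monotone stand-in for raw subjective value
            rt = b[0] + b[1] * v + b[2] * v ** 2
            if sigma:
                rt = rt + rng.normal(0, sigma, n_trials)
            rows.append(pd.DataFrame(dict(subject=s, signed_value=v, sv=sv,
                                          rt_ms=rt)))
        return pd.concat(rows, ignore_index=True)

    def test_constant_rts_give_zero_slopes_and_no_exclusions(self, rng):
        t = self._trials(rng, b=(700.0, 0.0, 0.0), sigma=0.0)
        res = ri.rt_analysis(t, n_sim=200)
        assert res.model.params[1] == pytest.approx(0, abs=1e-8)
        assert res.model.params[2] == pytest.approx(0, abs=1e-8)
        assert res.exclusions.n_stage1 == 0
        assert res.exclusions.n_stage2 == 0

    def test_injected_outlier_is_excluded_at_stage1(self, rng):
        t = self._trials(rng)
        sd = t.rt_ms.std()
        t.loc[3, "rt_ms"] = t.rt_ms.mean() + 10 * sd
        res = ri.rt_analysis(t, n_sim=200)
        assert res.exclusions.n_stage1 >= 1

    def test_recovers_generative_coefficients(self, rng):
        t = self._trials(rng, n_subj=28, n_trials=189)
        res = ri.rt_analysis(t, n_sim=200)
        for i, truth in ((1, -35.0), (2, -77.0)):
            assert abs(res.model.params[i] - truth) < 2 * res.model.se[i] + 2.0

    def test_sign_agreement_between_value_parametrizations(self, rng):
        t = self._trials(rng, n_subj=16, n_trials=189)
        res = ri.rt_analysis(t, n_sim=200)
        assert np.sign(res.model.params[1]) == np.sign(res.model_zsv.params[1])
        assert np.sign(res.model.params[2]) == np.sign(res.model_zsv.params[2])
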