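import numpy as np
import pytest

from polylife import gibbs_lmm
from polylife.datatypes import Kernel, UsageError, ValidationError
from polylife.gibbs_lmm import (McmcConfig, ModelTerm, auto_prior_scale,
                                hpd_interval, posterior_summary)


def _factor_kernel(rng, n, p, label="K"):
    z = rng.standard_normal((n, p))
    z = (z - z.mean(0)) / z.std(0, ddof=1)
    return Kernel(z @ z.T / p, ids=np.arange(n), label=label), z


class TestConfigAndPriors:
    def test_stored_draw_count(self):
        cfg = McmcConfig(n_iter=1000, burn_in=300, thin=7, seed=0)
        assert cfg.n_stored == (1000 - 300) // 7

    @pytest.mark.parametrize("kwargs", [
        {"n_iter": 100, "burn_in": 100}, {"thin": 0}, {"burn_in": -1, "n_iter": 10},
    ])
    def test_invalid_schedules(self, kwargs):
        with pytest.raises(ValidationError):
            McmcConfig(**kwargs)

    def test_auto_scale_single_term(self, rng):
        y = rng.normal(0, 10, 4000)
        y = (y - y.mean()) / y.std(ddof=1) * 10  # Var exactly 100
        s, se = auto_prior_scale(y, 1, r2=0.5, df=5)
        assert np.isclose(s, 50 * 7 / 5)
        assert np.isclose(5 * s / 7, 50)       # prior mode = r2 * Var(y)
        assert np.isclose(5 * se / 7, 50)

    def test_auto_scale_two_terms(self, rng):
        y = rng.normal(0, 10, 1000)
        y = (y - y.mean()) / y.std(ddof=1) * 10
        s, _ = auto_prior_scale(y, 2, r2=0.5, df=5)
        assert np.isclose(5 * s / 7, 25)

    def test_degenerate_r2_rejected(self, rng):
        with pytest.raises(ValidationError):
            auto_prior_scale(rng.normal(size=100), 1, r2=0.0)
        with pytest.raises(ValidationError):
            auto_prior_scale(np.ones(10), 1)


class TestFit:
    def test_intercept_only_residual_variance(self, rng):
        y = rng.normal(0.0, 1.0, 2000)
        s = gibbs_lmm.fit(y, np.ones((2000, 1)), [], McmcConfig.reduced(seed=1))
        assert abs(s.resid_variance.mean() - 1.0) < 0.1
        assert s.n_stored == McmcConfig.reduced().n_stored
        assert (s.resid_variance > 0).all()

    def test_oracle_equivalence_fixed_variances(self):
        """With variances held fixed, posterior-mean effects must match the
        closed-form GBLUP conditional mean within Monte-Carlo error."""
        rng = np.random.default_rng(2)
        n = 150
        k, _ = _factor_kernel(rng, n, 250)
        g = rng.multivariate_normal(np.zeros(n), 0.6 * k.matrix + 1e-10 * np.eye(n))
        y = g + rng.normal(0, np.sqrt(0.4), n)
        mask = np.zeros(n, bool); mask[:30] = True
        s = gibbs_lmm.fit(np.where(mask, np.nan, y), None,
                          [ModelTerm("g", kernel=k, fixed_variance=0.6)],
                          McmcConfig(6000, 1000, 5, seed=3),
                          fixed_residual_variance=0.4)
        obs = ~mask
        lam = 0.4 / 0.6
        oracle = k.matrix[:, obs] @ np.linalg.solve(
            k.matrix[np.ix_(obs, obs)] + lam * np.eye(obs.sum()), y[obs])
        u = s.effects["g"]
        se = u.std(0, ddof=1) / np.sqrt(s.n_stored)
        within = np.abs(u.mean(0) - oracle) <= 3 * se
        assert within.mean() >= 0.95
        assert np.corrcoef(u.mean(0), oracle)[0, 1] > 0.99

    def test_regression_form_equals_kernel_form(self):
        rng = np.random.default_rng(4)
        n, c = 150, 20
        z = rng.standard_normal((n, c))
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        y = z @ rng.normal(0, 0.5, c) + rng.normal(0, 1, n)
        kz = Kernel(z @ z.T, ids=np.arange(n), label="ZZ")
        s_reg = gibbs_lmm.fit(y, np.ones((n, 1)), [ModelTerm("t", design=z)],
                              McmcConfig(6000, 1000, 5, seed=5))
        s_ker = gibbs_lmm.fit(y, np.ones((n, 1)), [ModelTerm("t", kernel=kz)],
                              McmcConfig(6000, 1000, 5, seed=5))
        lp1 = s_reg.linear_predictor.mean(0)
        lp2 = s_ker.linear_predictor.mean(0)
        mc = (s_reg.linear_predictor.std(0, ddof=1)
              + s_ker.linear_predictor.std(0, ddof=1)) / np.sqrt(s_reg.n_stored)
        assert np.corrcoef(lp1, lp2)[0, 1] > 0.995
        assert (np.abs(lp1 - lp2) <= 5 * mc + 0.02).all()

    def test_determinism(self, rng):
        n = 80
        k, _ = _factor_kernel(rng, n, 60)
        y = rng.normal(0, 1, n)
        args = (y, np.ones((n, 1)), [ModelTerm("g", kernel=k)])
        s1 = gibbs_lmm.fit(*args, McmcConfig(300, 100, 2, seed=7))
        s2 = gibbs_lmm.fit(*args, McmcConfig(300, 100, 2, seed=7))
        assert np.array_equal(s1.effects["g"], s2.effects["g"])
        assert np.array_equal(s1.resid_variance, s2.resid_variance)

    def test_rank_deficient_design_rejected(self, rng):
        y = rng.normal(size=30)
        x = np.ones((30, 2))
        with pytest.raises(ValidationError):
            gibbs_lmm.fit(y, x, [], McmcConfig(100, 10, 1, seed=0))

    def test_non_psd_kernel_rejected(self, rng):
        mat = np.eye(10); mat[0, 1] = mat[1, 0] = 2.0
        k = Kernel(mat, np.arange(10), "bad")
        y = rng.normal(size=10)
        with pytest.raises(ValidationError):
            gibbs_lmm.fit(y, None, [ModelTerm("g", kernel=k)],
                          McmcConfig(100, 10, 1, seed=0))


class TestSummaries:
    def test_hpd_degenerate(self):
        assert hpd_interval(np.full(50, 5.0)) == (5.0, 5.0)

    def test_hpd_uniform_lowest_start(self):
        lo, hi = hpd_interval(np.arange(1, 101), level=0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_hpd_shorter_than_equal_tailed_for_skewed(self, rng):
        draws = np.exp(rng.standard_normal(10 ** 4))
        lo, hi = hpd_interval(draws, 0.95)
        q = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < q[1] - q[0]

    def test_summary_requires_draws(self, rng):
        y = rng.normal(size=50)
        s = gibbs_lmm.fit(y, np.ones((50, 1)), [], McmcConfig(20, 10, 5, seed=0))
        with pytest.raises(ValidationError):
            posterior_summary(s)

    def test_summary_contains_means(self, rng):
        y = rng.normal(size=200)
        s = gibbs_lmm.fit(y, np.ones((200, 1)), [], McmcConfig(600, 100, 5, seed=0))
        tab = posterior_summary(s)
        row = tab[tab["quantity"] == "var_residual"].iloc[0]
        assert row["lower"] <= row["mean"] <= row["upper"]


class TestPredict:
    def test_intercept_only_predictions_constant(self, rng):
        y = rng.normal(5.0, 1.0, 100)
        mask = np.zeros(100, bool); mask[:20] = True
        s = gibbs_lmm.fit(np.where(mask, np.nan, y), np.ones((100, 1)), [],
                          McmcConfig(600, 100, 5, seed=1))
        pred = gibbs_lmm.predict(s)
        assert np.allclose(pred, pred[0])
        assert abs(pred[0] - s.b.mean()) < 1e-12

    def test_duplicate_rows_get_equal_predictions(self, rng):
        n = 100
        k, z = _factor_kernel(rng, n, 150)
        mat = k.matrix.copy()
        mat[1, :] = mat[0, :]; mat[:, 1] = mat[:, 0]; mat[1, 1] = mat[0, 0]
        k2 = Kernel(mat, np.arange(n), "dup")
        y = rng.normal(0, 1, n)
        masked = y.copy(); masked[[0, 1]] = np.nan
        s = gibbs_lmm.fit(masked, None, [ModelTerm("g", kernel=k2)],
                          McmcConfig(4000, 1000, 5, seed=2))
        pred = gibbs_lmm.predict(s)
        mc = s.linear_predictor[:, [0, 1]].std(0, ddof=1).max() / np.sqrt(s.n_stored)
        assert abs(pred[0] - pred[1]) <= max(5 * mc, 0.02)

    def test_pure_noise_prediction_uncorrelated(self, rng):
        n = 400
        k, _ = _factor_kernel(rng, n, 300)
        y = rng.normal(0, 1, n)
        mask = np.zeros(n, bool); mask[:150] = True
        s = gibbs_lmm.fit(np.where(mask, np.nan, y), np.ones((n, 1)),
                          [ModelTerm("g", kernel=k)],
                          McmcConfig.reduced(seed=3))
        r = np.corrcoef(y[mask], gibbs_lmm.predict(s))[0, 1]
        assert abs(r) < 3.0 / np.sqrt(mask.sum())

    def test_mask_mismatch_rejected(self, rng):
        y = rng.normal(size=50)
        mask = np.zeros(50, bool); mask[:10] = True
        s = gibbs_lmm.fit(np.where(mask, np.nan, y), np.ones((50, 1)), [],
                          McmcConfig(100, 50, 5, seed=0))
        with pytest.raises(UsageError):
            gibbs_lmm.predict(s, rows=~mask)
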