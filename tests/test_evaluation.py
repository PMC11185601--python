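import numpy as np
import pytest

from polylife import gibbs_lmm
from polylife.adjustment import cohort_design
from polylife.datatypes import UsageError, ValidationError
from polylife.evaluation import (accuracy, bias_regression, build_model_spec,
                                 rnd_validation_mask, run_split,
                                 variance_decomposition, yo_validation_mask)
from polylife.gibbs_lmm import McmcConfig
from polylife.kernels import compute_grm, lifestyle_kernel, truncated_grm
from polylife.preprocess import (assign_cohorts, assign_random_groups,
                                 standardize)
from polylife.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="module")
def model_inputs(small_dataset, small_grm):
    ds = small_dataset
    m_std = np.column_stack([standardize(c) for c in ds.lifestyle.T])
    kernels = {k: lifestyle_kernel(m_std, small_grm.ids, f"{k}{k}")
               for k in ("M", "L", "E")}
    trunc = truncated_grm(small_grm, r=20)
    return small_grm, kernels, trunc


class TestModelSpecs:
    @pytest.mark.parametrize("mid,n_terms,names", [
        ("M0", 1, ["genetic"]),
        ("M1", 1, ["lifestyle"]),
        ("M3", 1, ["lifestyle"]),
        ("M11", 2, ["lifestyle", "genetic"]),
        ("M23", 3, ["lifestyle", "genetic", "interaction"]),
        ("M01", 1, ["structure"]),
        ("M02", 0, []),
    ])
    def test_term_composition(self, model_inputs, mid, n_terms, names):
        grm, kernels, trunc = model_inputs
        spec = build_model_spec(mid, grm, kernels, trunc)
        assert len(spec.terms) == n_terms
        assert [t.name for t in spec.terms] == names

    def test_interaction_kernel_is_hadamard(self, model_inputs):
        grm, kernels, trunc = model_inputs
        spec = build_model_spec("M21", grm, kernels, trunc)
        inter = spec.terms[-1].kernel
        assert np.allclose(inter.matrix,
                           grm.matrix * kernels["M"].matrix)

    def test_unknown_or_incomplete(self, model_inputs):
        grm, kernels, trunc = model_inputs
        with pytest.raises(ValidationError):
            build_model_spec("M99", grm, kernels, trunc)
        with pytest.raises(ValidationError):
            build_model_spec("M0")


class TestMetrics:
    def test_accuracy_limits(self, rng):
        y = rng.normal(size=30)
        assert accuracy(y, y) == pytest.approx(1.0)
        assert accuracy(y, -y) == pytest.approx(-1.0)

    def test_accuracy_hand_example(self):
        assert accuracy([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_accuracy_constant_warns(self):
        with pytest.warns(UserWarning):
            assert np.isnan(accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_bias_exact_relations(self, rng):
        yhat = rng.normal(size=40)
        assert bias_regression(yhat, yhat) == pytest.approx((0.0, 1.0))
        assert bias_regression(3 + 2 * yhat, yhat) == pytest.approx((3.0, 2.0))

    def test_bias_noisy_within_sampling_error(self, rng):
        n = 500
        yhat = rng.normal(0, 1, n)
        y = 5.0 + 0.5 * yhat + rng.normal(0, 1, n)
        b0, b1 = bias_regression(y, yhat)
        se1 = 1.0 / np.sqrt(n * yhat.var(ddof=1))
        se0 = np.sqrt(1.0 / n + yhat.mean() ** 2 / (n * yhat.var(ddof=1)))
        assert abs(b1 - 0.5) < 3 * se1
        assert abs(b0 - 5.0) < 3 * se0

    def test_ols_identities(self, rng):
        y = rng.normal(size=60)
        yhat = 0.4 * y + rng.normal(0, 1, 60)
        b0, b1 = bias_regression(y, yhat)
        r = accuracy(y, yhat)
        assert b1 == pytest.approx(r * y.std(ddof=1) / yhat.std(ddof=1))
        assert b0 == pytest.approx(y.mean() - b1 * yhat.mean())

    def test_bias_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            bias_regression([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestVarianceDecomposition:
    def test_cohort_only_recovery(self):
        cfg = SimulationConfig(n_individuals=2000, n_variants=100, seed=21,
                               trait_var_fractions=(0.15, 0.0, 0.0, 0.0, 0.85))
        ds = simulate_dataset(cfg)
        _, coh, _ = assign_cohorts(ds.demographics["sex"].to_numpy(),
                                   ds.demographics["age"].to_numpy())
        x = cohort_design(coh)
        y = standardize(ds.trait_truth.latent["SP"], "response")
        spec = build_model_spec("M02")
        fit = gibbs_lmm.fit(y, x, spec.terms, McmcConfig.reduced(seed=1))
        tab = variance_decomposition(fit, spec, x_design=x)
        coh_row = tab[tab["component"] == "cohort"].iloc[0]
        assert abs(coh_row["mean"] / 100.0 - 0.15) < 0.05
        assert coh_row["lower"] <= coh_row["mean"] <= coh_row["upper"]

    def test_components_sum_to_total_within_slack(self):
        """Posterior component variances plus residual approximate Var(y);
        fitted effects covary, so +-15% relative slack applies."""
        for seed in range(3):
            cfg = SimulationConfig(n_individuals=500, n_variants=300, seed=30 + seed,
                                   trait_var_fractions=(0.1, 0.25, 0.1, 0.0, 0.55))
            ds = simulate_dataset(cfg)
            grm = compute_grm(ds.genotypes)
            m_std = np.column_stack([standardize(c) for c in ds.lifestyle.T])
            kern = {"M": lifestyle_kernel(m_std, grm.ids, "MM")}
            _, coh, _ = assign_cohorts(ds.demographics["sex"].to_numpy(),
                                       ds.demographics["age"].to_numpy())
            x = cohort_design(coh)
            y = standardize(ds.trait_truth.latent["SP"], "response")
            spec = build_model_spec("M11", grm, kern)
            fit = gibbs_lmm.fit(y, x, spec.terms, McmcConfig.reduced(seed=seed))
            tab = variance_decomposition(fit, spec, x_design=x)
            total = tab["mean"].sum()
            assert abs(total - y.var(ddof=1)) / y.var(ddof=1) < 0.15

    def test_masked_fit_rejected(self, rng):
        y = rng.normal(size=50)
        mask = np.zeros(50, bool); mask[:10] = True
        fit = gibbs_lmm.fit(np.where(mask, np.nan, y), np.ones((50, 1)), [],
                            McmcConfig(100, 50, 5, seed=0))
        with pytest.raises(UsageError):
            variance_decomposition(fit, build_model_spec("M02"),
                                   x_design=np.ones((50, 1)))


class TestSplits:
    def test_yo_mask_is_old_age_groups(self, small_dataset):
        ag, coh, yo = assign_cohorts(small_dataset.demographics["sex"].to_numpy(),
                                     small_dataset.demographics["age"].to_numpy())
        mask = yo_validation_mask(yo)
        assert np.array_equal(mask, np.isin(ag, (3, 4)))

    def test_rnd_mask_sizes(self):
        rng = np.random.default_rng(5)
        coh = rng.choice([f"{s}-{a}" for s in (0, 1) for a in (1, 2, 3, 4)], 400)
        groups = assign_random_groups(coh, seed=2)
        mask = rnd_validation_mask(groups)
        assert mask.sum() == np.isin(groups, (5, 6, 7, 8)).sum()

    def test_empty_validation_rejected(self, model_inputs, rng):
        grm, kernels, trunc = model_inputs
        spec = build_model_spec("M02")
        coh = np.repeat([f"0-{a}" for a in (1, 2, 3, 4)], 75)
        with pytest.raises(ValidationError):
            run_split(spec, rng.normal(size=300), coh, np.zeros(300, bool),
                      McmcConfig(100, 50, 5, seed=0))

    def test_validation_phenotypes_do_not_influence_fit(self, small_dataset,
                                                        small_grm):
        """Mutation test: perturbing masked phenotypes leaves the fitted
        draws and predictions unchanged for a fixed chain seed."""
        ds = small_dataset
        _, coh, yo = assign_cohorts(ds.demographics["sex"].to_numpy(),
                                    ds.demographics["age"].to_numpy())
        y = standardize(ds.trait_truth.latent["SP"], "response")
        mask = yo_validation_mask(yo)
        spec = build_model_spec("M0", small_grm)
        mcmc = McmcConfig(400, 100, 5, seed=9)
        res1 = run_split(spec, y, coh, mask, mcmc)
        y2 = y.copy()
        y2[mask] += np.random.default_rng(0).normal(0, 50, mask.sum())
        res2 = run_split(spec, y2, coh, mask, mcmc)
        assert np.array_equal(res1.predictions, res2.predictions)

    def test_combined_model_outperforms_single_components(self):
        """With both genetic and lifestyle variance present, the model
        carrying both terms predicts at least as well on average as either
        single-component model."""
        r = {"M0": [], "M1": [], "M11": []}
        for seed in range(5):
            cfg = SimulationConfig(n_individuals=1200, n_variants=600,
                                   seed=60 + seed,
                                   trait_var_fractions=(0.05, 0.25, 0.25, 0.0, 0.45),
                                   rge_overlap=0.0, rg_young_old=1.0)
            ds = simulate_dataset(cfg)
            grm = compute_grm(ds.genotypes)
            m_std = np.column_stack([standardize(c) for c in ds.lifestyle.T])
            kern = {"M": lifestyle_kernel(m_std, grm.ids, "MM")}
            _, coh, _ = assign_cohorts(ds.demographics["sex"].to_numpy(),
                                       ds.demographics["age"].to_numpy())
            groups = assign_random_groups(coh, seed=seed)
            mask = rnd_validation_mask(groups)
            y = standardize(ds.trait_truth.latent["SP"], "response")
            for mid in r:
                spec = build_model_spec(mid, grm, kern)
                res = run_split(spec, y, coh, mask,
                                McmcConfig.reduced(seed=seed))
                r[mid].append(res.r)
        assert np.mean(r["M11"]) >= np.mean(r["M0"])
        assert np.mean(r["M11"]) >= np.mean(r["M1"])

    def test_prediction_accuracy_matches_gblup_oracle(self):
        """The sampler's masked-set accuracy should track the closed-form
        GBLUP prediction computed on the same data."""
        cfg = SimulationConfig(n_individuals=1000, n_variants=800, seed=33,
                               trait_var_fractions=(0.0, 0.4, 0.0, 0.0, 0.6),
                               rge_overlap=0.0, rg_young_old=1.0,
                               prop_medicated=0.0)
        ds = simulate_dataset(cfg)
        grm = compute_grm(ds.genotypes)
        _, coh, _ = assign_cohorts(ds.demographics["sex"].to_numpy(),
                                   ds.demographics["age"].to_numpy())
        groups = assign_random_groups(coh, seed=1)
        mask = rnd_validation_mask(groups)
        y = standardize(ds.trait_truth.latent["SP"], "response")
        spec = build_model_spec("M0", grm)
        res = run_split(spec, y, coh, mask, McmcConfig.reduced(seed=3))
        # closed-form GBLUP with the realized variance ratio
        obs = ~mask
        h2 = ds.trait_truth.realized_fractions["SP"]["genetic"]
        lam = (1 - h2) / h2
        yc = y - y[obs].mean()
        oracle = grm.matrix[np.ix_(mask, obs)] @ np.linalg.solve(
            grm.matrix[np.ix_(obs, obs)] + lam * np.eye(obs.sum()), yc[obs])
        r_oracle = accuracy(y[mask], oracle)
        assert res.r > 0.2
        assert abs(res.r - r_oracle) < 0.1
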