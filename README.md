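# polylife

Polygenic modelling of blood-pressure traits — systolic pressure (SP),
diastolic pressure (DP) and pulse pressure (PP = SP − DP) — that combines
genome-wide SNP data with a panel of 27 lifestyle variables, for
quantitative geneticists studying how environmental information improves
phenotype prediction and variance decomposition.

The scientific problem is genotype–environment correlation (rGE):
lifestyle variables are themselves partly heritable, so the genetic and
"environmental" components of a phenotype are correlated, violating the
independence assumption of standard polygenic models and biasing both
variance components and genotype-by-environment (G×L) interaction
estimates.  The package implements a simple remedy: decompose each
lifestyle variable with the mixed model

    m_l = X b_l + N_l u_l + a_l + e_l

(X: intercept + 8 sex-by-age cohort classes; N_l: the other lifestyle
variables, with the self-column replaced by noise; a_l ~ N(0, G σ²_a) a
genomic effect through the genomic relationship matrix G), and carry
forward the **adjusted** matrices E (residuals e_l) and L (predictions
N_l u_l) in place of the raw matrix M.  Phenotypes are then modelled with
multi-kernel Bayesian linear mixed models

    y = X b + u_life + u_gen + u_int + ε,
    u_life ~ N(0, [WW⊺/c] σ²),  u_gen ~ N(0, G σ²_a),
    u_int ~ N(0, (G ∘ WW⊺/c) σ²),   W ∈ {M, L, E},

fitted by Gibbs sampling (kernel terms re-parameterized through their
eigendecompositions; scaled-inverse-χ² priors on variances; flat priors on
fixed effects).  The pipeline evaluates variance decomposition on the full
sample, out-of-cohort prediction (train young / validate old, plus a
randomized-split control) with accuracy r = cor(y, ŷ) and bias regression
y = β0 + β1 ŷ + ε, and young–old genetic correlations by bivariate
average-information REML (rG ± 2·SE).

Restricted biobank data is not required: a synthetic-data module generates
genotypes, demographics, correlated lifestyle panels and
blood-pressure-like traits with known ground truth — including tunable rGE
and G×L — so every stage runs and is tested end to end.  See
`docs/methods.md` for the models, assumptions and numerical choices.

## Worked example: seeing the rGE bias

Simulate a trait whose genetic component overlaps the heritable part of
the lifestyle panel (`rge_overlap=0.5`), then decompose its variance with
the model that uses the **raw** lifestyle kernel MM⊺/c:

```python
import numpy as np
from polylife import SimulationConfig, simulate_dataset
from polylife.kernels import compute_grm, lifestyle_kernel
from polylife.preprocess import assign_cohorts, standardize
from polylife.adjustment import cohort_design
from polylife.evaluation import build_model_spec, variance_decomposition
from polylife.gibbs_lmm import McmcConfig, fit

cfg = SimulationConfig(n_individuals=800, n_variants=600, seed=1,
                       rge_overlap=0.5,
                       trait_var_fractions=(0.10, 0.25, 0.15, 0.0, 0.50))
ds = simulate_dataset(cfg)
grm = compute_grm(ds.genotypes)
_, cohort, _ = assign_cohorts(ds.demographics.sex.to_numpy(),
                              ds.demographics.age.to_numpy())
m = np.column_stack([standardize(c) for c in ds.lifestyle.T])
kernels = {"M": lifestyle_kernel(m, grm.ids, "MM")}
x = cohort_design(cohort)
y = standardize(ds.trait_truth.latent["SP"], mode="response")
spec = build_model_spec("M11", grm, kernels)
samples = fit(y, x, spec.terms, McmcConfig.reduced(seed=1))
print(variance_decomposition(samples, spec, x_design=x).round(1))
```

prints (the response is standardized to variance 100, so entries read as
percentages of phenotypic variance):

```
  model  component  mean  lower  upper
0   M11     cohort  15.5   10.8   20.4
1   M11  lifestyle  24.8   19.2   30.1
2   M11    genetic  15.2    9.6   21.0
3   M11   residual  49.3   42.2   55.4
```

The simulated truth is 9.5 % cohort, 14.2 % lifestyle, 23.6 % genetic and
47.3 % residual.  Because half the genetic variance flows through the
heritable lifestyle score, the raw-lifestyle kernel absorbs genetic signal:
lifestyle is overestimated (24.8 vs 14.2) and genetics underestimated
(15.2 vs 23.6).  Re-running the same dataset with `rge_overlap=0.0` gives
19.0 / 22.8 against truths 14.1 / 23.5 — the distortion follows the
overlap.  Replacing M with the adjusted E or L matrices (built by
`polylife.adjustment.adjust_lifestyle`) removes the heritable part of the
lifestyle panel before it enters the kernel; the test suite's
rGE-reduction check verifies that this more than halves the correlation
between adjusted lifestyle columns and true breeding values.

## Analysis drivers and CLI

`analysis/01_simulate.py` … `07_genetic_correlation.py` run the complete
study narrative (simulate → QC → kernels → lifestyle adjustment → variance
decomposition → young-to-old prediction → genetic correlation) on a
desk-scale synthetic cohort and write their tables under
`results/workspace/`.  The same stages are exposed as a CLI:

```bash
polylife all --workdir out/ --seed 7             # built-in small defaults
polylife simulate --config my_run.yml --workdir out/   # or any single stage
```

where the YAML config overrides any subset of the defaults in
`polylife.pipeline.DEFAULT_CONFIG` (sample sizes, QC thresholds, MCMC
schedule, model list, split type, seeds).

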