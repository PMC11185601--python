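"""Synthetic genotype / lifestyle / blood-pressure data with known truth.

The generator emulates the structure of a biobank blood-pressure study:

* biallelic SNP dosages in Hardy-Weinberg proportions, with optional
  missingness and planted near-duplicate pairs for relatedness-pruning
  tests;
* sex/age demographics with a blood-pressure-medication indicator;
* c correlated lifestyle variables, each the exact sum of a cohort
  (sex-by-age-class) part, an additive-genetic part, a cross-lifestyle
  (shared latent factor) part and residual noise, with in-sample component
  variances matching the requested fractions exactly;
* systolic/diastolic-like traits built from cohort effects, an additive
  genetic value with distinct (correlated) young/old effect scores, a linear
  lifestyle effect, a genotype-by-lifestyle interaction, and noise.

Genotype-environment correlation is induced by routing a configurable
fraction (``rge_overlap``) of each trait's genetic variance through the same
shared polygenic score that drives the genetic component of the lifestyle
variables.  Every realized component is returned in a TruthRecord so that
parameter-recovery and bias-reduction tests can compare estimates against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, GenotypeMatrix
from .preprocess import assign_cohorts

#: Fraction of entries perturbed in the second member of a duplicated pair.
DUPLICATE_PERTURBATION = 0.01


def _as_fractions(value, length, name):
    arr = np.asarray(value, dtype=float)
    if arr.shape != (length,):
        raise ConfigurationError(f"{name} must have {length} entries")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-12:
        raise ConfigurationError(f"{name} must be nonnegative and sum to 1")
    return tuple(arr)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    The default variance fractions mirror the real-data study conditions:
    lifestyle variables carry ~5% cohort, ~3% additive-genetic and ~18%
    cross-lifestyle variance; traits carry cohort/genetic/lifestyle/GxL
    fractions in the ranges reported for blood-pressure measures.
    """

    n_individuals: int = 2000
    n_variants: int = 1000
    n_lifestyle: int = 27
    maf_range: tuple = (0.05, 0.5)
    age_range: tuple = (40, 70)
    prop_medicated: float = 0.2
    n_duplicate_pairs: int = 0
    missing_rate: float = 0.0
    #: (cohort, genetic, cross-lifestyle, residual) per lifestyle variable
    lifestyle_var_fractions: tuple = (0.05, 0.03, 0.18, 0.74)
    #: (cohort, genetic, lifestyle, gxl, residual) per trait
    trait_var_fractions: tuple = (0.12, 0.10, 0.05, 0.02, 0.71)
    #: fraction of trait genetic variance carried by the lifestyle-shared score
    rge_overlap: float = 0.5
    rg_young_old: float = 0.9
    seed: int = 0
    # architecture knobs (counts of causal variants and latent factors)
    n_causal_common: int = 100
    n_causal_trait: int = 300
    n_cross_factors: int = 4
    #: share of each lifestyle variable's genetic variance on the common score
    genetic_common_frac: float = 1.0
    #: discretize the first n_ordinal lifestyle columns into 5 levels
    n_ordinal: int = 0

    def __post_init__(self):
        if self.n_individuals < 2 or self.n_variants < 1:
            raise ConfigurationError("need at least 2 individuals and 1 variant")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigurationError("empty age range")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be a fraction in [0, 1)")
        if 2 * self.n_duplicate_pairs > self.n_individuals:
            raise ConfigurationError("too many duplicate pairs for n_individuals")
        self.lifestyle_var_fractions = _as_fractions(
            self.lifestyle_var_fractions, 4, "lifestyle_var_fractions")
        self.trait_var_fractions = _as_fractions(
            self.trait_var_fractions, 5, "trait_var_fractions")
        if not (0.0 <= self.rge_overlap <= 1.0):
            raise ConfigurationError("rge_overlap must be in [0, 1]")
        if not (-1.0 <= self.rg_young_old <= 1.0):
            raise ConfigurationError("rg_young_old must be in [-1, 1]")
        if not (0.0 <= self.genetic_common_frac <= 1.0):
            raise ConfigurationError("genetic_common_frac must be in [0, 1]")


@dataclass
class TruthRecord:
    """Ground-truth components emitted alongside a simulated object."""

    components: dict = field(default_factory=dict)
    realized_fractions: dict = field(default_factory=dict)
    effect_variant_indices: dict = field(default_factory=dict)
    breeding_values: dict = field(default_factory=dict)
    breeding_values_young: dict = field(default_factory=dict)
    breeding_values_old: dict = field(default_factory=dict)
    latent: dict = field(default_factory=dict)


def _zscore(x):
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _scaled(x, frac):
    """Standardize and rescale so the in-sample variance equals ``frac``."""
    if frac == 0.0:
        return np.zeros_like(np.asarray(x, dtype=float))
    return _zscore(np.asarray(x, dtype=float)) * np.sqrt(frac)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Hardy-Weinberg dosages with optional duplicates and missingness."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, p = config.n_individuals, config.n_variants
    freq = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    x = rng.binomial(2, freq, size=(n, p)).astype(float)
    n_perturb = int(np.floor(DUPLICATE_PERTURBATION * p))
    for k in range(config.n_duplicate_pairs):
        src, dst = 2 * k, 2 * k + 1
        x[dst] = x[src]
        if n_perturb > 0:
            cols = rng.choice(p, size=n_perturb, replace=False)
            x[dst, cols] = rng.binomial(2, freq[cols])
    if config.missing_rate > 0:
        x[rng.random(size=(n, p)) < config.missing_rate] = np.nan
    ids = np.array([f"I{i:06d}" for i in range(n)])
    vids = np.array([f"snp{j}" for j in range(p)])
    return GenotypeMatrix(dosages=x, ids=ids, variant_ids=vids)


def simulate_demographics(config: SimulationConfig) -> pd.DataFrame:
    """Sex, integer age and medication flag per individual."""
    if config.n_individuals < 1:
        raise ConfigurationError("n_individuals must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_individuals
    lo, hi = config.age_range
    return pd.DataFrame({
        "IID": [f"I{i:06d}" for i in range(n)],
        "sex": rng.integers(0, 2, size=n),
        "age": rng.integers(lo, hi + 1, size=n),
        "medicated": rng.random(n) < config.prop_medicated,
    })


def _standardized_dosages(genotypes: GenotypeMatrix):
    """Mean-imputed, column-standardized dosages and the polymorphic mask."""
    raw = genotypes.dosages
    col_mean = 2.0 * genotypes.allele_frequencies()
    x = np.where(np.isnan(raw), col_mean, raw)
    sd = x.std(axis=0, ddof=1)
    poly = np.isfinite(sd) & (sd > 0)
    z = np.zeros_like(x)
    z[:, poly] = (x[:, poly] - x[:, poly].mean(axis=0)) / sd[poly]
    return z, poly


def _genetic_score(z_dosages, idx, rng):
    """Standardized linear polygenic score on the given variant subset."""
    beta = rng.standard_normal(len(idx))
    return _zscore(z_dosages[:, idx] @ beta)


def simulate_lifestyle(genotypes: GenotypeMatrix, demographics: pd.DataFrame,
                       config: SimulationConfig):
    """Correlated lifestyle variables with exact known components.

    Each column is the sum of a cohort part (a function of the 8 sex-by-age
    classes), an additive-genetic part (a polygenic score, by default fully
    carried by one score shared across variables), a cross-lifestyle part
    (loadings on shared latent factors) and residual noise, each rescaled
    in-sample to the configured variance fraction.

    Returns
    -------
    (M, truth) : (n, c) ndarray and TruthRecord whose component matrices sum
    to M exactly.
    """
    n = genotypes.n_individuals
    if len(demographics) != n:
        raise ConfigurationError("genotype and demographic row counts differ")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    c = config.n_lifestyle
    f_coh, f_gen, f_cross, f_res = config.lifestyle_var_fractions

    _, cohort, _ = assign_cohorts(demographics["sex"].to_numpy(),
                                  demographics["age"].to_numpy())
    classes, class_idx = np.unique(cohort, return_inverse=True)

    z, poly = _standardized_dosages(genotypes)
    poly_idx = np.flatnonzero(poly)
    n_common = min(config.n_causal_common, poly_idx.size)
    idx_common = rng.choice(poly_idx, size=n_common, replace=False) if n_common else poly_idx
    g_common = _genetic_score(z, idx_common, rng) if n_common else np.zeros(n)

    factors = rng.standard_normal((n, config.n_cross_factors))
    loadings = rng.standard_normal((config.n_cross_factors, c))

    comp = {k: np.zeros((n, c)) for k in
            ("cohort", "genetic", "cross_lifestyle", "residual")}
    kappa = config.genetic_common_frac
    specific_idx = {}
    for l in range(c):
        class_eff = rng.standard_normal(len(classes))
        comp["cohort"][:, l] = _scaled(class_eff[class_idx], f_coh)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if kappa >= 1.0 or f_gen == 0.0:
            g_l = g_common
        else:
            n_spec = min(config.n_causal_common, poly_idx.size)
            idx_spec = rng.choice(poly_idx, size=n_spec, replace=False)
            specific_idx[l] = idx_spec
            g_l = (np.sqrt(kappa) * g_common
                   + np.sqrt(1.0 - kappa) * _genetic_score(z, idx_spec, rng))
        comp["genetic"][:, l] = sign * _scaled(g_l, f_gen)
        comp["cross_lifestyle"][:, l] = _scaled(factors @ loadings[:, l], f_cross)
        comp["residual"][:, l] = _scaled(rng.standard_normal(n), f_res)

    m = sum(comp.values())
    if config.n_ordinal > 0:
        # discretize the first n_ordinal columns into 5 quantile levels;
        # truth components then describe the latent continuous variables
        for l in range(min(config.n_ordinal, c)):
            qs = np.quantile(m[:, l], [0.2, 0.4, 0.6, 0.8])
            m[:, l] = np.digitize(m[:, l], qs).astype(float)

    var_m = m.var(axis=0, ddof=1)
    realized = {k: comp[k].var(axis=0, ddof=1) / var_m for k in comp}
    truth = TruthRecord(
        components=comp,
        realized_fractions=realized,
        effect_variant_indices={"lifestyle_common": np.asarray(idx_common),
                                **{f"lifestyle_{l}": v
                                   for l, v in specific_idx.items()}},
    )
    # the realized shared score (with its effect sizes) is what the traits
    # must load on for genuine genotype-environment correlation
    truth.latent["lifestyle_common_score"] = g_common
    return m, truth


def simulate_phenotypes(genotypes: GenotypeMatrix, demographics: pd.DataFrame,
                        lifestyle_truth: TruthRecord, config: SimulationConfig):
    """Blood-pressure-like traits with known variance components.

    The additive genetic value of each trait routes ``rge_overlap`` of its
    variance through the lifestyle-shared polygenic score (creating
    genotype-environment correlation) and uses distinct young/old effect
    scores whose in-sample correlation equals ``rg_young_old``.  Raw
    readings are emitted on mmHg-like scales with 15/10 mmHg subtracted from
    medicated individuals, so the preprocessing adjustment reverses it.

    Returns
    -------
    (traits, truth) : DataFrame with IID, sp_raw, dp_raw, medicated and a
    TruthRecord with per-trait components on the latent (unit) scale.
    """
    if lifestyle_truth is None or "cross_lifestyle" not in lifestyle_truth.components:
        raise ConfigurationError("lifestyle truth record with components is required")
    n = genotypes.n_individuals
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    f_coh, f_gen, f_life, f_gxl, f_res = config.trait_var_fractions
    ov, rg = config.rge_overlap, config.rg_young_old

    _, cohort, yo = assign_cohorts(demographics["sex"].to_numpy(),
                                   demographics["age"].to_numpy())
    classes, class_idx = np.unique(cohort, return_inverse=True)
    young = yo == "Y"

    z, poly = _standardized_dosages(genotypes)
    poly_idx = np.flatnonzero(poly)
    # reuse the realized lifestyle-shared score (same variants AND same
    # effect sizes); sharing variants with fresh effects would induce no
    # genotype-environment correlation
    g_common = lifestyle_truth.latent.get("lifestyle_common_score",
                                          np.zeros(n))
    env_part = (lifestyle_truth.components["cross_lifestyle"]
                + lifestyle_truth.components["residual"])

    truth = TruthRecord()
    scales = {"SP": (137.0, 18.0), "DP": (82.0, 11.0)}
    med = demographics["medicated"].to_numpy(dtype=bool)
    out = {"IID": demographics["IID"].to_numpy()}
    for trait, (mu, sd) in scales.items():
        n_causal = min(config.n_causal_trait, poly_idx.size)
        idx_own = rng.choice(poly_idx, size=n_causal, replace=False)
        g_own = _genetic_score(z, idx_own, rng)
        bv_y = _zscore(np.sqrt(ov) * g_common + np.sqrt(1.0 - ov) * g_own)
        if rg == 1.0:
            bv_o = bv_y
            idx_old = idx_own
        else:
            idx_old = rng.choice(poly_idx, size=n_causal, replace=False)
            g2 = _genetic_score(z, idx_old, rng)
            g2 = _zscore(g2 - (g2 @ bv_y) / (bv_y @ bv_y) * bv_y)
            bv_o = rg * bv_y + np.sqrt(1.0 - rg ** 2) * g2

        bv_sel = np.where(young, bv_y, bv_o)
        class_eff = rng.standard_normal(len(classes))
        comp = {
            "cohort": _scaled(class_eff[class_idx], f_coh),
            "genetic": _scaled(bv_sel, f_gen),
        }
        w = rng.standard_normal(env_part.shape[1])
        life_raw = env_part @ w
        comp["lifestyle"] = _scaled(life_raw, f_life)
        comp["gxl"] = _scaled(_zscore(bv_sel) * _zscore(life_raw), f_gxl)
        comp["residual"] = _scaled(rng.standard_normal(n), f_res)
        latent = sum(comp.values())

        var_l = latent.var(ddof=1)
        truth.components[trait] = comp
        truth.realized_fractions[trait] = {
            k: v.var(ddof=1) / var_l for k, v in comp.items()}
        truth.breeding_values[trait] = comp["genetic"]
        truth.breeding_values_young[trait] = bv_y * np.sqrt(f_gen)
        truth.breeding_values_old[trait] = bv_o * np.sqrt(f_gen)
        truth.effect_variant_indices[trait] = idx_own
        truth.effect_variant_indices[f"{trait}_old"] = idx_old
        truth.latent[trait] = latent
        offset = {"SP": 15.0, "DP": 10.0}[trait]
        out[f"{trait.lower()}_raw"] = mu + sd * latent - offset * med
    out["medicated"] = med
    return pd.DataFrame(out), truth


@dataclass
class SimulatedDataset:
    """Bundle of one complete simulated study."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    demographics: pd.DataFrame
    lifestyle: np.ndarray
    lifestyle_truth: TruthRecord
    traits: pd.DataFrame
    trait_truth: TruthRecord


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all four simulation stages with consistent sub-seeds."""
    g = simulate_genotypes(config)
    demo = simulate_demographics(config)
    m, lt = simulate_lifestyle(g, demo, config)
    traits, tt = simulate_phenotypes(g, demo, lt, config)
    return SimulatedDataset(config=config, genotypes=g, demographics=demo,
                            lifestyle=m, lifestyle_truth=lt,
                            traits=traits, trait_truth=tt)
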