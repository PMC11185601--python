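"""Phenotype derivation, variant QC, relatedness pruning, and cohort assignment.

This module turns raw blood-pressure readings and genotype dosages into
analysis-ready inputs: medication-corrected systolic/diastolic pressure and
the derived pulse pressure, standard variant quality control, greedy
relatedness pruning on the genomic relationship matrix, the eight sex-by-age
cohort classes used as fixed effects, and the matching randomised (RND)
grouping used for cross-validation controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ValidationError

#: mmHg added back to systolic readings of medicated individuals.
SP_MEDICATION_OFFSET = 15.0
#: mmHg added back to diastolic readings of medicated individuals.
DP_MEDICATION_OFFSET = 10.0

#: Upper age bound (inclusive) of age groups 1..3; group 4 runs to AGE_MAX.
AGE_BREAKS = (51, 58, 63)
AGE_MIN, AGE_MAX = 40, 70

#: Relatedness threshold above which a pair may not be jointly retained.
RELATEDNESS_THRESHOLD = 0.025


def adjust_medication(sp_raw, dp_raw, medicated):
    """Correct blood-pressure readings for antihypertensive medication.

    Medicated individuals get +15 mmHg systolic and +10 mmHg diastolic added
    to their readings; pulse pressure is the difference of the adjusted
    measures.

    Parameters
    ----------
    sp_raw, dp_raw : scalar or array, mmHg readings.
    medicated : bool scalar or array flag.

    Returns
    -------
    (SP, DP, PP) adjusted systolic, diastolic and pulse pressure.
    """
    sp_raw = np.asarray(sp_raw, dtype=float)
    dp_raw = np.asarray(dp_raw, dtype=float)
    med = np.asarray(medicated, dtype=bool)
    sp = sp_raw + SP_MEDICATION_OFFSET * med
    dp = dp_raw + DP_MEDICATION_OFFSET * med
    return sp, dp, sp - dp


def qc_variants(g: GenotypeMatrix, maf_min: float = 0.01, mac_min: int = 5,
                miss_max: float = 0.1, hwe_p_min: float = 1e-10):
    """Filter variants on MAF, MAC, missing rate and Hardy-Weinberg equilibrium.

    A variant is retained iff MAF >= ``maf_min``, minor allele count >=
    ``mac_min``, missing rate < ``miss_max`` and the HWE goodness-of-fit
    p-value > ``hwe_p_min``.  Allele frequencies and counts use non-missing
    calls only.  The HWE test is a 1-df chi-square on the observed genotype
    counts against Hardy-Weinberg expectations.

    Returns
    -------
    (GenotypeMatrix, pandas.DataFrame)
        The filtered matrix and a per-variant report with one row per input
        variant, the computed statistics and pass/fail flags per criterion.
    """
    x = g.dosages
    n, p = x.shape
    obs = ~np.isnan(x)
    n_obs = obs.sum(axis=0)
    alt = np.nansum(x, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n_obs)
    freq = np.where(n_obs > 0, freq, 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    mac = np.minimum(alt, 2.0 * n_obs - alt)
    miss = 1.0 - n_obs / n

    hwe_p = np.ones(p)
    for j in range(p):
        xj = x[obs[:, j], j]
        nj = xj.size
        if nj == 0:
            continue
        counts = np.array([(xj == 0).sum(), (xj == 1).sum(), (xj == 2).sum()],
                          dtype=float)
        f = (counts[1] + 2 * counts[2]) / (2 * nj)
        if f <= 0.0 or f >= 1.0:
            continue
        expected = nj * np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        hwe_p[j] = stats.chi2.sf(chi2, df=1)

    pass_maf = maf >= maf_min
    pass_mac = mac >= mac_min
    pass_miss = miss < miss_max
    pass_hwe = hwe_p > hwe_p_min
    keep = pass_maf & pass_mac & pass_miss & pass_hwe

    report = pd.DataFrame({
        "variant_id": g.variant_ids,
        "maf": maf, "mac": mac, "missing_rate": miss, "hwe_p": hwe_p,
        "pass_maf": pass_maf, "pass_mac": pass_mac,
        "pass_missing": pass_miss, "pass_hwe": pass_hwe,
        "retained": keep,
    })
    report.attrs["n_retained"] = int(keep.sum())
    report.attrs["n_removed"] = int((~keep).sum())
    if not keep.any():
        warnings.warn("all variants removed by QC; returning empty matrix")
    filtered = GenotypeMatrix(
        dosages=x[:, keep].copy(),
        ids=g.ids,
        variant_ids=np.asarray(g.variant_ids)[keep].copy(),
    )
    return filtered, report


def prune_relatedness(grm, threshold: float = RELATEDNESS_THRESHOLD):
    """Greedily drop individuals until no retained pair exceeds ``threshold``.

    At each step the individual involved in the largest number of
    over-threshold pairs is removed (ties broken toward the larger row
    index), which is deterministic and keeps close to the maximum number of
    individuals.

    Parameters
    ----------
    grm : Kernel or square ndarray of genomic relationships.

    Returns
    -------
    ndarray of retained individual ids (or row indices when the input is a
    bare matrix).
    """
    mat = np.asarray(getattr(grm, "matrix", grm), dtype=float)
    ids = getattr(grm, "ids", None)
    n = mat.shape[0]
    if ids is None:
        ids = np.arange(n)
    over = (mat > threshold)
    np.fill_diagonal(over, False)
    over = over | over.T  # enforce symmetry of the violation graph
    active = np.ones(n, dtype=bool)
    degree = over.sum(axis=1).astype(int)
    while True:
        worst = degree.max(initial=0)
        if worst == 0:
            break
        # ties -> larger row index: search from the end
        cand = np.nonzero(active & (degree == worst))[0]
        drop = cand[-1]
        active[drop] = False
        degree[over[drop]] -= 1
        degree[drop] = 0
        over[drop, :] = False
        over[:, drop] = False
    return np.asarray(ids)[active]


def assign_cohorts(sex, age):
    """Map (sex, age) to age group, cohort label and young/old group.

    Ages 40-51, 52-58, 59-63 and 64-70 form age groups 1-4; the cohort label
    concatenates sex (0/1) and age group, e.g. ``"0-3"``; groups 1-2 are
    young (``Y``), 3-4 old (``O``).

    Returns
    -------
    (age_group, cohort, yo_group) arrays (or scalars for scalar input).
    """
    scalar = np.isscalar(sex) and np.isscalar(age)
    sex = np.atleast_1d(np.asarray(sex, dtype=int))
    age = np.atleast_1d(np.asarray(age, dtype=int))
    if np.any((age < AGE_MIN) | (age > AGE_MAX)):
        raise ValidationError(f"age outside [{AGE_MIN}, {AGE_MAX}]")
    if np.any((sex != 0) & (sex != 1)):
        raise ValidationError("sex must be coded 0/1")
    age_group = np.digitize(age, [b + 1 for b in AGE_BREAKS]) + 1
    cohort = np.array([f"{s}-{a}" for s, a in zip(sex, age_group)])
    yo = np.where(age_group <= 2, "Y", "O")
    if scalar:
        return int(age_group[0]), cohort[0], yo[0]
    return age_group, cohort, yo


def assign_random_groups(cohorts, seed=0):
    """Randomised grouping with the same group-size multiset as the cohorts.

    Individuals are randomly permuted and dealt into 8 groups whose sizes
    equal the cohort class sizes (cohort labels taken in sorted order map to
    RND labels 1..8).

    Returns
    -------
    ndarray of integer group labels in 1..8.
    """
    cohorts = np.asarray(cohorts)
    rng = np.random.default_rng(seed)
    labels, counts = np.unique(cohorts, return_counts=True)
    n = cohorts.size
    perm = rng.permutation(n)
    out = np.empty(n, dtype=int)
    start = 0
    for g, c in enumerate(counts, start=1):
        out[perm[start:start + c]] = g
        start += c
    return out


def standardize(values, mode: str = "predictor"):
    """Standardize a vector to the study's response or predictor scale.

    ``response`` mode recentres to mean 100 / sd 10 (so variance components
    read as percentages of phenotypic variance); ``predictor`` mode to
    mean 0 / sd 1.  The standard deviation uses the n-1 denominator.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValidationError("cannot standardize a constant vector")
    z = (x - x.mean()) / sd
    if mode == "response":
        return 100.0 + 10.0 * z
    if mode == "predictor":
        return z
    raise ValidationError(f"unknown standardization mode {mode!r}")


@dataclass
class PhenotypeTable:
    """Analysis-ready phenotypes with demographic groupings.

    Wraps a DataFrame with columns IID, SP, DP, PP (mmHg), sex, age,
    medicated, age_group, cohort, yo_group, rnd_group.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        pp = self.data["SP"] - self.data["DP"]
        if not np.allclose(pp, self.data["PP"]):
            raise ValidationError("PP must equal SP - DP for every row")


def derive_phenotypes(traits: pd.DataFrame, demographics: pd.DataFrame,
                      rnd_seed: int = 0) -> PhenotypeTable:
    """Assemble the phenotype table from raw trait readings and demographics.

    Applies the medication adjustment, derives pulse pressure, and attaches
    age-group / cohort / young-old / RND labels.
    """
    shared = [c for c in traits.columns if c != "IID" and c in demographics.columns]
    df = demographics.merge(traits.drop(columns=shared), on="IID",
                            validate="one_to_one")
    sp, dp, pp = adjust_medication(df["sp_raw"], df["dp_raw"], df["medicated"])
    age_group, cohort, yo = assign_cohorts(df["sex"].to_numpy(),
                                           df["age"].to_numpy())
    out = pd.DataFrame({
        "IID": df["IID"], "SP": sp, "DP": dp, "PP": pp,
        "sex": df["sex"], "age": df["age"],
        "medicated": df["medicated"].astype(bool),
        "age_group": age_group, "cohort": cohort, "yo_group": yo,
        "rnd_group": assign_random_groups(cohort, seed=rnd_seed),
    })
    return PhenotypeTable(out)
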