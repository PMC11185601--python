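"""Genetic/cohort/cross-lifestyle adjustment of lifestyle variables.

Each lifestyle variable m_l is decomposed with the mixed model

    m_l = X b_l + N_l u_l + a_l + e_l

where X carries the intercept and the 8 sex-by-age cohort classes, N_l is
the lifestyle matrix with column l replaced by pure noise (so the variable
cannot predict itself), u_l are ridge-type regression effects of the other
lifestyle variables, and a_l is a genomic (GRM-kernel) effect.  Posterior
means from this model define two adjusted matrices:

* ``E`` — the residuals e_l: lifestyle stripped of cohort, genetic and
  cross-lifestyle structure;
* ``L`` — the predictions N_l u_l: the purely 'lifestyle on lifestyle'
  component, free of cohort and genetic signal.

These feed the lifestyle kernels used by the phenotype models, replacing
the raw matrix M to avoid genotype-environment-correlation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gibbs_lmm
from .datatypes import Kernel, UsageError, ValidationError
from .gibbs_lmm import McmcConfig, ModelTerm
from .preprocess import standardize


def cohort_design(cohort_labels) -> np.ndarray:
    """Intercept + treatment-coded cohort dummies (first class as baseline)."""
    labels = np.asarray(cohort_labels)
    classes = np.unique(labels)
    x = np.ones((labels.size, classes.size))
    for j, cls in enumerate(classes[1:], start=1):
        x[:, j] = (labels == cls).astype(float)
    return x


def build_noise_column(n: int, seed) -> np.ndarray:
    """i.i.d. standard normal replacement column for the self-variable."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return np.random.default_rng(seed).standard_normal(n)


def fit_lifestyle_model(l: int, m: np.ndarray, cohort_labels, grm: Kernel,
                        mcmc: McmcConfig, noise_seed=None):
    """Fit the decomposition model for lifestyle variable ``l``.

    ``m`` must hold predictor-standardized columns; the response copy of
    column l is re-standardized to the response scale (mean 100 / sd 10) so
    fitted variances read as percentages.  The model is fitted on all
    individuals.

    Returns
    -------
    (PosteriorSamples, N_l) — the fit and the modified lifestyle matrix.
    """
    m = np.asarray(m, dtype=float)
    n, c = m.shape
    if not (0 <= l < c):
        raise ValidationError("column index out of range")
    y = standardize(m[:, l], mode="response")
    n_l = m.copy()
    if noise_seed is None:
        noise_seed = np.random.SeedSequence([0, l])
    n_l[:, l] = build_noise_column(n, noise_seed)
    x = cohort_design(cohort_labels)
    terms = [
        ModelTerm(name="lifestyle", design=n_l),
        ModelTerm(name="genetic", kernel=grm),
    ]
    samples = gibbs_lmm.fit(y, x, terms, mcmc)
    return samples, n_l


@dataclass
class LifestyleSet:
    """Raw (M), predicted (L) and residual-adjusted (E) lifestyle matrices."""

    M: np.ndarray = field(repr=False)
    L: np.ndarray = field(repr=False)
    E: np.ndarray = field(repr=False)
    ids: np.ndarray
    summaries: pd.DataFrame = field(repr=False)
    noise_seeds: list = field(default_factory=list)
    standardized: bool = True


def build_adjusted_matrices(fits, noise_matrices, m, cohort_labels, ids,
                            standardize_output: bool = True) -> LifestyleSet:
    """Assemble E and L from the per-variable fits.

    E column l is the posterior-mean residual m_l - X b - N_l u_l - a_l and
    L column l the posterior-mean prediction N_l u_l (both computed on the
    response scale of the per-variable model).  By default the columns of
    both matrices are re-standardized to predictor scale before kernel use;
    disable with ``standardize_output=False``.
    """
    m = np.asarray(m, dtype=float)
    n, c = m.shape
    if len(fits) != c:
        raise UsageError(f"expected {c} fits, got {len(fits)}")
    x = cohort_design(cohort_labels)
    e_mat = np.empty((n, c))
    l_mat = np.empty((n, c))
    rows = []
    for l, (samples, n_l) in enumerate(zip(fits, noise_matrices)):
        if samples is None:
            raise UsageError(f"missing fit for lifestyle variable {l}")
        y = standardize(m[:, l], mode="response")
        b_mean = samples.b.mean(axis=0)
        l_col = samples.effects["lifestyle"].mean(axis=0)
        a_col = samples.effects["genetic"].mean(axis=0)
        e_col = y - x @ b_mean - l_col - a_col
        e_mat[:, l] = e_col
        l_mat[:, l] = l_col
        xb = samples.b @ x.T
        u_noise = samples.coefficients["lifestyle"][:, l]
        rows.append({
            "variable": l,
            # Var over individuals of each effect draw, posterior-averaged;
            # /100 converts the response scale (sd 10) to fractions
            "frac_cohort": float(np.mean(xb.var(axis=1, ddof=1))) / 100.0,
            "frac_lifestyle": float(np.mean(
                samples.effects["lifestyle"].var(axis=1, ddof=1))) / 100.0,
            "frac_genetic": float(np.mean(
                samples.effects["genetic"].var(axis=1, ddof=1))) / 100.0,
            "frac_residual": float(np.mean(samples.resid_variance)) / 100.0,
            "noise_coef_share": float(np.mean(u_noise ** 2) / np.mean(
                samples.coefficients["lifestyle"] ** 2)),
        })
    if standardize_output:
        e_mat = np.column_stack([standardize(e_mat[:, l]) for l in range(c)])
        if np.allclose(l_mat, 0.0):
            raise ValidationError(
                "all L columns are zero; rerun with standardize_output=False")
        l_mat = np.column_stack([standardize(l_mat[:, l]) for l in range(c)])
    return LifestyleSet(M=m, L=l_mat, E=e_mat, ids=np.asarray(ids),
                        summaries=pd.DataFrame(rows),
                        standardized=standardize_output)


def adjust_lifestyle(m, cohort_labels, grm: Kernel, mcmc: McmcConfig,
                     seed: int = 0, standardize_output: bool = True) -> LifestyleSet:
    """Run the full per-variable adjustment over all c lifestyle columns.

    Noise replacement columns get independent sub-seeds derived from
    ``seed``; MCMC chains get per-variable seeds likewise.
    """
    m = np.asarray(m, dtype=float)
    c = m.shape[1]
    fits, noise_mats, seeds = [], [], []
    for l in range(c):
        noise_seed = np.random.SeedSequence([seed, 100 + l])
        chain = McmcConfig(n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                           thin=mcmc.thin,
                           seed=int(np.random.SeedSequence([seed, 200 + l])
                                    .generate_state(1)[0] % (2 ** 31)))
        samples, n_l = fit_lifestyle_model(l, m, cohort_labels, grm, chain,
                                           noise_seed=noise_seed)
        fits.append(samples)
        noise_mats.append(n_l)
        seeds.append(noise_seed)
    out = build_adjusted_matrices(fits, noise_mats, m, cohort_labels,
                                  ids=grm.ids,
                                  standardize_output=standardize_output)
    out.noise_seeds = seeds
    return out
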