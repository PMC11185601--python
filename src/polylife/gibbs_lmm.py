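"""Bayesian linear mixed models by Gibbs sampling.

Fits models of the form

    y = X b + sum_t u_t + eps,   u_t ~ N(0, K_t sigma_t^2)  (kernel form)
                                 u_t = Z_t beta_t, beta_t ~ N(0, I sigma_t^2)
                                 (regression form)

with a flat prior on the fixed block b, scaled-inverse-chi-square priors on
every variance, and Gaussian residuals.  Kernel-form terms are
re-parameterized through the kernel eigendecomposition (u = V delta with
independent prior variances d_j sigma_t^2), which makes every conditional
update univariate or small-block Gaussian.  Phenotypes may be masked
(missing); masked rows contribute no likelihood but the linear predictor is
stored at every row, which is how out-of-sample prediction works.

Three interchangeable update paths are used per term, chosen from the
problem shape: a fully vectorised draw when the eigenbasis is orthonormal on
the observed rows (no masking), a joint small-block draw with a Cholesky
factor for low-rank terms, and a compiled single-site scan otherwise.  All
three target the same conditional distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from ._samplers import scalar_coord_update
from .datatypes import Kernel, UsageError, ValidationError

#: Eigenvalues below EIG_RTOL * max are dropped from kernel terms.
EIG_RTOL = 1e-8
#: Largest coordinate count for which the joint block update is used.
BLOCK_LIMIT = 160

_log = logging.getLogger(__name__)
#: Iteration interval of the convergence log (variance trace at DEBUG level).
LOG_EVERY = 100


@dataclass
class ModelTerm:
    """One random term: either kernel-form or regression-form."""

    name: str
    kernel: Kernel | None = None
    design: np.ndarray | None = None
    prior_df: float = 5.0
    prior_scale: float | str = "auto"
    fixed_variance: float | None = None

    def __post_init__(self):
        if (self.kernel is None) == (self.design is None):
            raise ValidationError(
                f"term {self.name!r} needs exactly one of kernel or design")
        if self.fixed_variance is not None and self.fixed_variance <= 0:
            raise ValidationError("fixed_variance must be positive")

    @property
    def form(self) -> str:
        return "kernel" if self.kernel is not None else "regression"


@dataclass
class McmcConfig:
    """Gibbs schedule; the study default is 60000/10000/50."""

    n_iter: int = 60000
    burn_in: int = 10000
    thin: int = 50
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValidationError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def reduced(cls, seed: int = 0) -> "McmcConfig":
        """Short schedule (3000/500/5) for desk-scale fits and tests."""
        return cls(n_iter=3000, burn_in=500, thin=5, seed=seed)


@dataclass
class PosteriorSamples:
    """Stored Gibbs draws of one fitted model."""

    b: np.ndarray                      # (S, q) fixed-effect draws
    effects: dict                      # name -> (S, n) effect-vector draws
    coefficients: dict                 # name -> (S, m) regression coefficients
    variances: dict                    # name -> (S,) variance draws
    resid_variance: np.ndarray         # (S,)
    linear_predictor: np.ndarray       # (S, n) at every row, masked included
    observed: np.ndarray               # (n,) bool mask used in the fit
    mcmc: McmcConfig

    @property
    def n_stored(self) -> int:
        return self.resid_variance.shape[0]


def auto_prior_scale(y_observed, n_random_terms: int, r2: float = 0.5,
                     df: float = 5.0):
    """Default scaled-inverse-chi-square scales from the phenotypic variance.

    Each random term's prior mode is set to an equal share r2 * Var(y) /
    n_random_terms of the variance; the residual prior mode to
    (1 - r2) * Var(y).  The scale S solves mode = df * S / (df + 2).

    Returns
    -------
    (term_scale, resid_scale); ``term_scale`` is None when there are no
    random terms.
    """
    y = np.asarray(y_observed, dtype=float)
    vy = y.var(ddof=1)
    if not np.isfinite(vy) or vy <= 0:
        raise ValidationError("Var(y) must be positive")
    if not (0.0 < r2 < 1.0):
        raise ValidationError("r2 must lie strictly between 0 and 1")
    resid_scale = (1.0 - r2) * vy * (df + 2.0) / df
    if n_random_terms == 0:
        return None, resid_scale
    term_scale = r2 * vy / n_random_terms * (df + 2.0) / df
    return term_scale, resid_scale


class _TermState:
    """Per-term precomputed quantities and sampler state."""

    def __init__(self, term: ModelTerm, obs: np.ndarray, all_obs: bool):
        self.term = term
        if term.form == "kernel":
            d, v = term.kernel.eigen()
            keep = d > EIG_RTOL * max(d.max(), 0.0)
            if not keep.any():
                raise ValidationError(f"kernel term {term.name!r} has no usable eigenvalues")
            self.d = np.ascontiguousarray(d[keep])
            self.z_full = np.ascontiguousarray(v[:, keep])
        else:
            z = np.asarray(term.design, dtype=float)
            if z.ndim != 2:
                raise ValidationError("regression design must be 2-D")
            self.d = np.ones(z.shape[1])
            self.z_full = np.ascontiguousarray(z)
        self.m = self.d.size
        self.z_obs = np.ascontiguousarray(self.z_full[obs])
        self.zt_obs = np.ascontiguousarray(self.z_obs.T)
        self.vv = np.ascontiguousarray((self.z_obs ** 2).sum(axis=0))
        self.delta = np.zeros(self.m)
        if term.form == "kernel" and all_obs:
            self.path = "ortho"
        elif self.m <= BLOCK_LIMIT:
            self.path = "block"
            self.ztz = self.z_obs.T @ self.z_obs
        else:
            self.path = "scalar"

    def update(self, resid, sig2_t, sig2_e, rng):
        z = rng.standard_normal(self.m)
        prior_var = self.d * sig2_t
        if self.path == "ortho":
            t = self.zt_obs @ resid + self.vv * self.delta
            prec = self.vv / sig2_e + 1.0 / prior_var
            new = (t / sig2_e) / prec + z / np.sqrt(prec)
            resid -= self.z_obs @ (new - self.delta)
            self.delta = new
        elif self.path == "block":
            a = self.ztz / sig2_e + np.diag(1.0 / prior_var)
            rhs = (self.zt_obs @ resid + self.ztz @ self.delta) / sig2_e
            low = cholesky(a, lower=True)
            mean = cho_solve((low, True), rhs)
            new = mean + solve_triangular(low, z, lower=True, trans="T")
            resid -= self.z_obs @ (new - self.delta)
            self.delta = new
        else:
            scalar_coord_update(self.delta, self.zt_obs, self.vv, prior_var,
                                resid, sig2_e, z)

    def scaled_ssq(self) -> float:
        return float(np.sum(self.delta ** 2 / self.d))

    def effect_full(self) -> np.ndarray:
        return self.z_full @ self.delta


def fit(y, x_design, terms, mcmc: McmcConfig, observed=None,
        fixed_residual_variance: float | None = None,
        prior_r2: float = 0.5) -> PosteriorSamples:
    """Run the Gibbs sampler and return stored posterior draws.

    Parameters
    ----------
    y : (n,) response; NaN entries are treated as masked.
    x_design : (n, q) fixed-effect design (flat prior), or None for no
        fixed block.  Must have full column rank on the observed rows.
    terms : list of ModelTerm.
    observed : optional (n,) bool mask; rows that are False contribute no
        likelihood (their NaN/observed values are ignored) but do get a
        stored linear predictor.
    fixed_residual_variance : hold the residual variance at this value
        instead of sampling it (the degrees-of-freedom -> infinity limit).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    obs = np.isfinite(y)
    if observed is not None:
        obs = obs & np.asarray(observed, dtype=bool)
    n_obs = int(obs.sum())
    if n_obs < 1:
        raise ValidationError("at least one observed phenotype is required")
    y_obs = y[obs]
    all_obs = bool(obs.all())

    if x_design is not None:
        x_full = np.atleast_2d(np.asarray(x_design, dtype=float))
        if x_full.shape[0] != n:
            raise ValidationError("x_design row count must match y")
        q = x_full.shape[1]
        x_obs = x_full[obs]
        if np.linalg.matrix_rank(x_obs) < q:
            raise ValidationError("fixed-effect design is rank deficient on observed rows")
        xtx_low = cholesky(x_obs.T @ x_obs, lower=True)
    else:
        x_full = None
        x_obs = None
        q = 0

    states = [_TermState(t, obs, all_obs) for t in terms]
    for t in terms:
        if t.form == "kernel":
            t.kernel.require_psd()

    auto_term_scale, auto_resid_scale = (None, None)
    if any(t.prior_scale == "auto" for t in terms) or fixed_residual_variance is None:
        auto_term_scale, auto_resid_scale = auto_prior_scale(
            y_obs, len(terms), r2=prior_r2)
    scales = []
    for t in terms:
        s = auto_term_scale if t.prior_scale == "auto" else float(t.prior_scale)
        if t.fixed_variance is None and (s is None or s <= 0):
            raise ValidationError(f"prior scale for term {t.name!r} must be positive")
        scales.append(s)
    df_e = 5.0
    scale_e = auto_resid_scale

    # initial values: prior modes for variances, OLS for the fixed block
    sig2 = [t.fixed_variance if t.fixed_variance is not None
            else t.prior_df * s / (t.prior_df + 2.0)
            for t, s in zip(terms, scales)]
    sig2_e = (fixed_residual_variance if fixed_residual_variance is not None
              else df_e * scale_e / (df_e + 2.0))
    if q > 0:
        b = np.linalg.lstsq(x_obs, y_obs, rcond=None)[0]
        resid = y_obs - x_obs @ b
    else:
        b = np.zeros(0)
        resid = y_obs.copy()

    rng = np.random.default_rng(mcmc.seed)
    n_store = mcmc.n_stored
    store_b = np.empty((n_store, q))
    store_eff = {t.name: np.empty((n_store, n)) for t in terms}
    store_coef = {t.name: np.empty((n_store, st.m))
                  for t, st in zip(terms, states) if t.form == "regression"}
    store_var = {t.name: np.empty(n_store) for t in terms}
    store_rvar = np.empty(n_store)
    store_lp = np.empty((n_store, n))

    s_idx = 0
    for it in range(mcmc.n_iter):
        if q > 0:
            r_plus = resid + x_obs @ b
            mean = cho_solve((xtx_low, True), x_obs.T @ r_plus)
            b = mean + math.sqrt(sig2_e) * solve_triangular(
                xtx_low, rng.standard_normal(q), lower=True, trans="T")
            resid = r_plus - x_obs @ b
        for k, st in enumerate(states):
            st.update(resid, sig2[k], sig2_e, rng)
        for k, (t, st, s) in enumerate(zip(terms, states, scales)):
            if t.fixed_variance is None:
                ssq = st.scaled_ssq()
                sig2[k] = (ssq + t.prior_df * s) / rng.chisquare(t.prior_df + st.m)
        if fixed_residual_variance is None:
            sse = float(resid @ resid)
            sig2_e = (sse + df_e * scale_e) / rng.chisquare(df_e + n_obs)

        if (it + 1) % LOG_EVERY == 0 and _log.isEnabledFor(logging.DEBUG):
            _log.debug("iter %d: sigma2_e=%.5g %s", it + 1, sig2_e,
                       " ".join(f"sigma2_{t.name}={v:.5g}"
                                for t, v in zip(terms, sig2)))

        done = it + 1 - mcmc.burn_in
        if done > 0 and done % mcmc.thin == 0 and s_idx < n_store:
            store_b[s_idx] = b
            lp = x_full @ b if q > 0 else np.zeros(n)
            for t, st in zip(terms, states):
                eff = st.effect_full()
                store_eff[t.name][s_idx] = eff
                if t.form == "regression":
                    store_coef[t.name][s_idx] = st.delta
                lp = lp + eff
            for t, s2 in zip(terms, sig2):
                store_var[t.name][s_idx] = s2
            store_rvar[s_idx] = sig2_e
            store_lp[s_idx] = lp
            s_idx += 1

    return PosteriorSamples(
        b=store_b, effects=store_eff, coefficients=store_coef,
        variances=store_var, resid_variance=store_rvar,
        linear_predictor=store_lp, observed=obs, mcmc=mcmc)


def hpd_interval(draws, level: float = 0.95):
    """Shortest contiguous window containing ceil(level * n) sorted draws.

    Ties are broken toward the lowest starting index, which makes the
    interval deterministic.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    ns = x.size
    h = int(math.ceil(level * ns))
    if h >= ns:
        return float(x[0]), float(x[-1])
    widths = x[h - 1:] - x[: ns - h + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + h - 1])


def posterior_summary(s: PosteriorSamples, level: float = 0.95):
    """Posterior mean and empirical HPD interval for every scalar quantity.

    Summarizes the variance of each random term, the residual variance and
    each fixed-effect coefficient.
    """
    import pandas as pd

    if s.n_stored < 10:
        raise ValidationError("need at least 10 stored draws to summarize")
    rows = []
    quantities = {f"var_{k}": v for k, v in s.variances.items()}
    quantities["var_residual"] = s.resid_variance
    for j in range(s.b.shape[1]):
        quantities[f"b_{j}"] = s.b[:, j]
    for name, draws in quantities.items():
        lo, hi = hpd_interval(draws, level)
        rows.append({"quantity": name, "mean": float(np.mean(draws)),
                     "lower": lo, "upper": hi})
    return pd.DataFrame(rows)


def predict(s: PosteriorSamples, rows=None) -> np.ndarray:
    """Posterior-mean linear predictor at masked rows.

    ``rows`` defaults to the rows masked during the fit; passing rows that
    were observed in the fit is an error.
    """
    if rows is None:
        rows = ~s.observed
    rows = np.asarray(rows, dtype=bool)
    if rows.shape != s.observed.shape:
        raise UsageError("prediction mask length does not match the fit")
    if np.any(rows & s.observed):
        raise UsageError("requested rows were observed during the fit")
    return s.linear_predictor[:, rows].mean(axis=0)
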