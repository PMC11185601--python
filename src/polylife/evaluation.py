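"""Model suite orchestration, variance decomposition, prediction metrics,
and young/old genetic correlations.

The model ids follow the study's naming: M0 (cohort + genetic), M1/M2/M3
(cohort + one lifestyle kernel built from raw M, predicted L or residual E
matrices), M11/M12/M13 (lifestyle + genetic), M21/M22/M23 (lifestyle +
genetic + their Hadamard interaction), M01 (truncated-PC GRM structure
control) and M02 (cohort only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from . import gibbs_lmm
from .adjustment import cohort_design
from .datatypes import Kernel, UsageError, ValidationError
from .gibbs_lmm import McmcConfig, ModelTerm, PosteriorSamples, hpd_interval
from .kernels import hadamard

MODEL_IDS = ("M0", "M1", "M2", "M3", "M11", "M12", "M13",
             "M21", "M22", "M23", "M01", "M02")

_LIFESTYLE_OF = {"1": "M", "2": "L", "3": "E"}


@dataclass
class ModelSpec:
    """A model id together with its ordered random-term list."""

    model_id: str
    terms: list = field(default_factory=list)
    lifestyle_key: str | None = None


def build_model_spec(model_id: str, grm: Kernel | None = None,
                     lifestyle_kernels: dict | None = None,
                     truncated: Kernel | None = None) -> ModelSpec:
    """Assemble the exact random-term list for a model id.

    ``lifestyle_kernels`` maps 'M'/'L'/'E' to the corresponding WW'/c
    kernel.  Terms are ordered lifestyle, genetic, interaction, matching the
    model equations.
    """
    if model_id not in MODEL_IDS:
        raise ValidationError(f"unknown model id {model_id!r}")
    lifestyle_kernels = lifestyle_kernels or {}

    def _need(obj, what):
        if obj is None:
            raise ValidationError(f"model {model_id} requires {what}")
        return obj

    if model_id == "M02":
        return ModelSpec(model_id, [])
    if model_id == "M01":
        return ModelSpec(model_id, [ModelTerm("structure",
                                              kernel=_need(truncated, "the truncated GRM"))])
    if model_id == "M0":
        return ModelSpec(model_id, [ModelTerm("genetic", kernel=_need(grm, "the GRM"))])

    key = _LIFESTYLE_OF[model_id[-1]]
    k_life = _need(lifestyle_kernels.get(key), f"lifestyle kernel {key}")
    terms = [ModelTerm("lifestyle", kernel=k_life)]
    if len(model_id) == 3:  # M1x / M2x
        terms.append(ModelTerm("genetic", kernel=_need(grm, "the GRM")))
        if model_id[1] == "2":
            terms.append(ModelTerm("interaction",
                                   kernel=hadamard(_need(grm, "the GRM"), k_life)))
    return ModelSpec(model_id, terms, lifestyle_key=key)


def variance_decomposition(fit: PosteriorSamples, spec: ModelSpec,
                           x_design=None, level: float = 0.95) -> pd.DataFrame:
    """Per-component variance explained, from the stored Gibbs draws.

    At each stored draw the sample variance (n-1 denominator) across
    individuals of each fitted effect vector — and of the cohort prediction
    X b — is computed; the table reports the posterior mean and empirical
    HPD interval per component.  Requires a fit on fully observed data.
    """
    if not fit.observed.all():
        raise UsageError("variance decomposition requires an unmasked fit")
    draws = {}
    if x_design is not None and fit.b.shape[1] > 0:
        draws["cohort"] = (fit.b @ np.asarray(x_design, dtype=float).T).var(
            axis=1, ddof=1)
    for term in spec.terms:
        draws[term.name] = fit.effects[term.name].var(axis=1, ddof=1)
    draws["residual"] = fit.resid_variance
    rows = []
    for name, d in draws.items():
        lo, hi = hpd_interval(d, level)
        rows.append({"model": spec.model_id, "component": name,
                     "mean": float(d.mean()), "lower": lo, "upper": hi})
    return pd.DataFrame(rows)


def accuracy(y, yhat) -> float:
    """Pearson correlation between observed and predicted values."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 3 or y.size != yhat.size:
        raise ValidationError("need matched vectors of length >= 3")
    if y.std(ddof=1) == 0 or yhat.std(ddof=1) == 0:
        warnings.warn("accuracy undefined for constant input; returning nan")
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1])


def bias_regression(y, yhat):
    """OLS of observed on predicted: (beta0, beta1).

    Unbiased predictions have intercept 0 and slope 1.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    vh = yhat.var(ddof=1)
    if not np.isfinite(vh) or vh <= 0:
        raise ValidationError("Var(yhat) must be positive for the bias regression")
    b1 = float(np.cov(y, yhat, ddof=1)[0, 1] / vh)
    b0 = float(y.mean() - b1 * yhat.mean())
    return b0, b1


@dataclass
class PredictionResult:
    """Masked-set predictions and their accuracy/bias metrics."""

    split: str
    model_id: str
    validation_mask: np.ndarray = field(repr=False)
    predictions: np.ndarray = field(repr=False)
    r: float = float("nan")
    beta0: float = float("nan")
    beta1: float = float("nan")


def yo_validation_mask(yo_group) -> np.ndarray:
    """Validation rows of the young-train / old-validate design."""
    return np.asarray(yo_group) == "O"


def rnd_validation_mask(rnd_group, held_out=(5, 6, 7, 8)) -> np.ndarray:
    """Validation rows of the randomised-split design (RND groups held out)."""
    return np.isin(np.asarray(rnd_group), held_out)


def run_split(spec: ModelSpec, y, cohort_labels, validation_mask,
              mcmc: McmcConfig, split_name: str = "") -> PredictionResult:
    """Fit with the validation phenotypes masked and score the predictions.

    Kernels must have been built on all individuals; only the likelihood
    excludes the validation rows.
    """
    y = np.asarray(y, dtype=float)
    validation_mask = np.asarray(validation_mask, dtype=bool)
    if not validation_mask.any():
        raise ValidationError("validation set is empty")
    if validation_mask.all():
        raise ValidationError("training set is empty")
    x = cohort_design(cohort_labels)
    # cohort classes absent from the training rows (e.g. the old cohorts in
    # the Y-O design) have inestimable dummy coefficients: drop those
    # columns so the affected validation rows fall back to the baseline
    train = ~validation_mask
    keep = [0] + [j for j in range(1, x.shape[1])
                  if x[train, j].std() > 0]
    x = x[:, keep]
    fit = gibbs_lmm.fit(y, x, spec.terms, mcmc, observed=~validation_mask)
    yhat = gibbs_lmm.predict(fit, validation_mask)
    y_val = y[validation_mask]
    r = accuracy(y_val, yhat)
    try:
        b0, b1 = bias_regression(y_val, yhat)
    except ValidationError:
        b0, b1 = float("nan"), float("nan")
    return PredictionResult(split=split_name or "custom", model_id=spec.model_id,
                            validation_mask=validation_mask, predictions=yhat,
                            r=r, beta0=b0, beta1=b1)


# ---------------------------------------------------------------------------
# bivariate REML genetic correlation between age groups
# ---------------------------------------------------------------------------

@dataclass
class GeneticCorrelationResult:
    """Bivariate-GREML genetic correlation between the Y and O groups."""

    rg: float
    se: float
    ci: tuple
    params: dict
    loglik: float
    converged: bool
    boundary: bool
    n_iter: int
    trait: str = ""


def _assemble_v(theta, kyy, koo, kyo, n_y, n_o):
    s_gy, s_go, s_gyo, s_ey, s_eo = theta
    n = n_y + n_o
    v = np.empty((n, n))
    v[:n_y, :n_y] = s_gy * kyy
    v[n_y:, n_y:] = s_go * koo
    v[:n_y, n_y:] = s_gyo * kyo
    v[n_y:, :n_y] = s_gyo * kyo.T
    idx = np.arange(n)
    v[idx[:n_y], idx[:n_y]] += s_ey
    v[idx[n_y:], idx[n_y:]] += s_eo
    return v


def restricted_loglik(theta, y, x, kyy, koo, kyo, n_y, n_o) -> float:
    """Restricted log-likelihood of the bivariate model (up to a constant)."""
    v = _assemble_v(theta, kyy, koo, kyo, n_y, n_o)
    try:
        cf = cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    vinv_x = cho_solve(cf, x)
    xtvx = x.T @ vinv_x
    try:
        cx = cholesky(xtvx, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_x = 2.0 * np.sum(np.log(np.diag(cx)))
    vinv_y = cho_solve(cf, y)
    beta = cho_solve((cx, True), x.T @ vinv_y)
    ypy = float(y @ vinv_y - (x.T @ vinv_y) @ beta)
    return -0.5 * (logdet_v + logdet_x + ypy)


def genetic_correlation(y, groups, grm: Kernel, n_pcs: int = 10,
                        max_iter: int = 50, tol: float = 1e-6,
                        trait: str = "") -> GeneticCorrelationResult:
    """Estimate the genetic correlation between young and old individuals.

    The phenotypes of the two disjoint groups are treated as two traits of
    a bivariate model whose covariance runs through the GRM cross-blocks;
    the 5 (co)variance parameters (sigma^2_gY, sigma^2_gO, sigma_gYO,
    sigma^2_eY, sigma^2_eO) are estimated by average-information REML with
    step halving.  Fixed effects are a per-group intercept plus the top
    ``n_pcs`` GRM eigenvectors; rG = sigma_gYO / sqrt(sigma^2_gY
    sigma^2_gO), with a delta-method standard error from the inverse
    average-information matrix and CI = rG +/- 2 SE.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    is_y = groups == "Y"
    is_o = groups == "O"
    if not is_y.any() or not is_o.any():
        raise ValidationError("both Y and O groups must be non-empty")
    if (is_y & is_o).any() or not (is_y | is_o).all():
        raise ValidationError("groups must partition individuals into Y and O")

    order = np.concatenate([np.flatnonzero(is_y), np.flatnonzero(is_o)])
    n_y, n_o = int(is_y.sum()), int(is_o.sum())
    n = n_y + n_o
    yy = y[order]
    k = grm.matrix[np.ix_(order, order)]
    kyy, koo, kyo = k[:n_y, :n_y], k[n_y:, n_y:], k[:n_y, n_y:]

    n_pcs = max(0, min(n_pcs, n - 3))
    x = np.zeros((n, 2 + n_pcs))
    x[:n_y, 0] = 1.0
    x[n_y:, 1] = 1.0
    if n_pcs > 0:
        # only the leading eigenvectors are needed; Lanczos with a fixed
        # start vector keeps this cheap and deterministic
        from scipy.sparse.linalg import eigsh

        vals, vecs = eigsh(grm.matrix, k=n_pcs, which="LA",
                           v0=np.full(grm.n, 1.0 / np.sqrt(grm.n)))
        vecs = vecs[:, np.argsort(vals)[::-1]]
        x[:, 2:] = vecs[order]

    vy_y = yy[:n_y].var(ddof=1)
    vy_o = yy[n_y:].var(ddof=1)
    theta = np.array([0.5 * vy_y, 0.5 * vy_o,
                      0.25 * np.sqrt(vy_y * vy_o), 0.5 * vy_y, 0.5 * vy_o])
    floor = 1e-8 * max(vy_y, vy_o)

    def _clamp(t):
        t = t.copy()
        t[[0, 1, 3, 4]] = np.maximum(t[[0, 1, 3, 4]], floor)
        lim = 0.99999 * np.sqrt(t[0] * t[1])
        t[2] = np.clip(t[2], -lim, lim)
        return t

    args = (yy, x, kyy, koo, kyo, n_y, n_o)
    ll = restricted_loglik(theta, *args)
    converged = False
    ai = np.eye(5)
    it = 0
    for it in range(1, max_iter + 1):
        v = _assemble_v(theta, kyy, koo, kyo, n_y, n_o)
        try:
            cf = cho_factor(v, lower=True)
        except np.linalg.LinAlgError:
            break
        vinv = cho_solve(cf, np.eye(n))
        vinv_x = vinv @ x
        xtvx_inv = np.linalg.inv(x.T @ vinv_x)
        p = vinv - vinv_x @ xtvx_inv @ vinv_x.T
        w = p @ yy

        w_y, w_o = w[:n_y], w[n_y:]
        t_vecs = np.zeros((5, n))
        t_vecs[0, :n_y] = kyy @ w_y
        t_vecs[1, n_y:] = koo @ w_o
        t_vecs[2, :n_y] = kyo @ w_o
        t_vecs[2, n_y:] = kyo.T @ w_y
        t_vecs[3, :n_y] = w_y
        t_vecs[4, n_y:] = w_o

        tr_pv = np.array([
            float(np.sum(p[:n_y, :n_y] * kyy)),
            float(np.sum(p[n_y:, n_y:] * koo)),
            2.0 * float(np.sum(p[:n_y, n_y:] * kyo)),
            float(np.trace(p[:n_y, :n_y])),
            float(np.trace(p[n_y:, n_y:])),
        ])
        quad = t_vecs @ w
        grad = -0.5 * (tr_pv - quad)
        pt = t_vecs @ p.T
        ai = 0.5 * (t_vecs @ pt.T)

        try:
            step = np.linalg.solve(ai, grad)
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.abs(np.diag(ai)), 1.0)
        improved = False
        for _ in range(12):
            cand = _clamp(theta + step)
            ll_new = restricted_loglik(cand, *args)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        delta_ll = ll_new - ll
        theta, ll = cand, ll_new
        if abs(delta_ll) < tol and np.max(np.abs(step)) < tol * (1 + np.max(np.abs(theta))):
            converged = True
            break
        if abs(delta_ll) < tol:
            converged = True
            break

    s_gy, s_go, s_gyo, s_ey, s_eo = theta
    rg = float(s_gyo / np.sqrt(s_gy * s_go))
    boundary = abs(rg) > 0.999
    rg = float(np.clip(rg, -1.0, 1.0))
    try:
        cov = np.linalg.inv(ai)
        g = np.array([-rg / (2 * s_gy), -rg / (2 * s_go),
                      1.0 / np.sqrt(s_gy * s_go)])
        se = float(np.sqrt(max(g @ cov[:3, :3] @ g, 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")
    return GeneticCorrelationResult(
        rg=rg, se=se, ci=(rg - 2 * se, rg + 2 * se),
        params={"s_gY": float(s_gy), "s_gO": float(s_go),
                "s_gYO": float(s_gyo), "s_eY": float(s_ey),
                "s_eO": float(s_eo)},
        loglik=float(ll), converged=converged, boundary=boundary,
        n_iter=it, trait=trait)
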