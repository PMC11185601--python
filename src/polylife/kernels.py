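"""Covariance kernels for the mixed models.

Builds the genomic relationship matrix (GRM) from SNP dosages, the lifestyle
kernels WW'/c from raw/predicted/residual lifestyle matrices, Hadamard
(elementwise) interaction kernels for genotype-by-lifestyle effects, the
truncated-PC GRM used as a population-structure control, and cumulative
eigenvalue summaries of kernel dimensionality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AlignmentError, GenotypeMatrix, Kernel, ValidationError


def compute_grm(g: GenotypeMatrix) -> Kernel:
    """SNP-derived genomic relationship matrix.

    G_ij = (1/p) sum_k (x_ik - 2 f_k)(x_jk - 2 f_k) / (2 f_k (1 - f_k)),
    with f_k the sample alternate-allele frequency.  Missing dosages are
    mean-imputed (they contribute 0 after centering); monomorphic variants
    are skipped.
    """
    x = g.dosages
    freq = g.allele_frequencies()
    poly = np.isfinite(freq) & (freq > 0) & (freq < 1)
    if not poly.any():
        raise ValidationError("no polymorphic variants available for the GRM")
    x = x[:, poly]
    f = freq[poly]
    w = x - 2.0 * f
    w[np.isnan(x)] = 0.0
    w /= np.sqrt(2.0 * f * (1.0 - f))
    p_used = int(poly.sum())
    mat = (w @ w.T) / p_used
    return Kernel(matrix=mat, ids=g.ids, label="G",
                  factor=w / np.sqrt(p_used))


def lifestyle_kernel(w, ids, label: str) -> Kernel:
    """Similarity kernel WW'/c from an n x c matrix of standardized columns."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[1] < 1:
        raise ValidationError("lifestyle matrix must be n x c with c >= 1")
    if not np.isfinite(w).all():
        raise ValidationError("lifestyle matrix contains non-finite entries")
    c = w.shape[1]
    return Kernel(matrix=(w @ w.T) / c, ids=np.asarray(ids), label=label,
                  factor=w / np.sqrt(c))


def hadamard(k1: Kernel, k2: Kernel, label: str | None = None) -> Kernel:
    """Elementwise product of two kernels (PSD by the Schur product theorem)."""
    if k1.n != k2.n or not np.array_equal(k1.ids, k2.ids):
        raise AlignmentError("kernels must share the same ids in the same order")
    if label is None:
        label = f"{k1.label}x{k2.label}"
    return Kernel(matrix=k1.matrix * k2.matrix, ids=k1.ids, label=label)


def truncated_grm(g: Kernel, r: int = 20) -> Kernel:
    """Spectral reconstruction of ``g`` from its top-r principal components.

    P = sum_{j<=r} d_j v_j v_j' keeps the eigenvalue scale of G; any residual
    variance absorbs into the model's variance component.
    """
    if r <= 0:
        raise ValidationError("r must be positive")
    if r > g.n:
        raise ValidationError("r cannot exceed the kernel dimension")
    d, v = g.eigen()
    d_r, v_r = d[:r], v[:, :r]
    return Kernel(matrix=(v_r * d_r) @ v_r.T, ids=g.ids, label="P")


def eigen_summary(k: Kernel) -> pd.DataFrame:
    """Cumulative proportion of variance per eigencomponent.

    Eigenvalues are sorted descending, negatives clipped to zero, and the
    partial sums normalized by the total so the final entry is 1.
    """
    k.require_psd()
    if k.factor is not None:
        d = np.sort(np.linalg.svd(k.factor, compute_uv=False) ** 2)[::-1]
        d = np.concatenate([d, np.zeros(k.n - d.size)])
    else:
        d = np.linalg.eigvalsh(k.matrix)[::-1]
    d = np.clip(d, 0.0, None)
    total = d.sum()
    if total <= 0:
        raise ValidationError("kernel has zero trace")
    return pd.DataFrame({
        "component": np.arange(1, d.size + 1),
        "cumulative_proportion": np.cumsum(d) / total,
    })
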