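"""Shared containers and error types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Invalid simulation or run configuration."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class AlignmentError(ValueError):
    """Objects that must share individual ids/ordering do not."""


class UsageError(RuntimeError):
    """Operation called in a state it does not support."""


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix (individuals x variants).

    ``dosages`` holds {0, 1, 2} with ``nan`` for missing calls.
    """

    dosages: np.ndarray = field(repr=False)
    ids: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.ids = np.asarray(self.ids)
        self.variant_ids = np.asarray(self.variant_ids)
        n, p = self.dosages.shape
        if self.ids.shape != (n,) or self.variant_ids.shape != (p,):
            raise ValidationError("id / variant_id lengths do not match dosages")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be in {0, 1, 2, nan}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


#: Relative eigenvalue tolerance below which a kernel counts as PSD.
PSD_RTOL = 1e-8


@dataclass
class Kernel:
    """Labelled symmetric positive-semidefinite similarity matrix.

    ``factor`` optionally stores F with ``matrix = F @ F.T`` (e.g. the
    scaled lifestyle matrix), which lets downstream eigendecompositions run
    on the low-rank factor instead of the n x n matrix.
    """

    matrix: np.ndarray = field(repr=False)
    ids: np.ndarray
    label: str
    factor: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.ids = np.asarray(self.ids)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValidationError("kernel matrix must be square")
        if self.ids.shape != (n,):
            raise ValidationError("kernel ids length must match matrix")
        if not np.isfinite(self.matrix).all():
            raise ValidationError("kernel contains non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValidationError("kernel matrix is not symmetric")
        self._eigen_cache = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eigen(self):
        """Eigendecomposition ``(d, V)`` in descending eigenvalue order.

        Computed once and cached.  When a low-rank ``factor`` is present the
        decomposition runs through its thin SVD (exact for the non-null
        spectrum; null directions are dropped downstream anyway).
        """
        if self._eigen_cache is None:
            if self.factor is not None:
                u, s, _ = np.linalg.svd(self.factor, full_matrices=False)
                self._eigen_cache = (s ** 2, u)
            else:
                d, v = np.linalg.eigh(self.matrix)
                self._eigen_cache = (d[::-1].copy(), v[:, ::-1].copy())
        return self._eigen_cache

    def min_eigenvalue_ratio(self) -> float:
        """min eigenvalue / max eigenvalue; >= -PSD_RTOL for a valid kernel."""
        d, _ = self.eigen() if self.factor is None else (np.linalg.eigvalsh(self.matrix), None)
        d = np.asarray(d)
        dmax = d.max()
        if dmax <= 0:
            return 0.0
        return float(d.min() / dmax)

    def require_psd(self):
        if self.min_eigenvalue_ratio() < -PSD_RTOL:
            raise ValidationError(f"kernel {self.label!r} is not PSD within tolerance")
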