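"""Minimal readers/writers for PLINK binary genotypes and GCTA GRM files.

PLINK .bed is SNP-major with magic bytes 0x6c 0x1b 0x01 and four 2-bit
genotype codes per byte (00 = homozygous A1, 01 = missing, 10 =
heterozygous, 11 = homozygous A2); dosages here count the A1 allele.  The
GCTA GRM triple stores the lower triangle (including the diagonal) of the
relationship matrix as little-endian float32 in ``.grm.bin``, the ids in
``.grm.id`` and the per-pair non-missing variant counts in ``.grm.N.bin``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, Kernel, ValidationError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> A1 dosage
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write .bed/.bim/.fam for a genotype matrix."""
    prefix = Path(prefix)
    n, p = g.dosages.shape
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        n_bytes = (n + 3) // 4
        for j in range(p):
            packed = np.zeros(n_bytes, dtype=np.uint8)
            col = g.dosages[:, j]
            for i in range(n):
                x = col[i]
                code = 0b01 if np.isnan(x) else _DOSAGE_TO_CODE[float(x)]
                packed[i // 4] |= code << (2 * (i % 4))
            fh.write(packed.tobytes())
    bim = pd.DataFrame({
        "chrom": 1, "variant_id": g.variant_ids, "cm": 0,
        "pos": np.arange(1, p + 1), "a1": "A", "a2": "B",
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": g.ids, "iid": g.ids, "father": 0, "mother": 0,
        "sex": 0, "phenotype": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triple into a GenotypeMatrix."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None)
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValidationError("not a SNP-major PLINK .bed file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != p * n_bytes:
        raise ValidationError(".bed size does not match .bim/.fam dimensions")
    dosages = np.empty((n, p))
    lut = np.array([_CODE_TO_DOSAGE[c] for c in range(4)])
    for j in range(p):
        chunk = body[j * n_bytes:(j + 1) * n_bytes]
        codes = np.repeat(chunk, 4)
        shifts = np.tile(np.arange(4) * 2, n_bytes)
        codes = (codes >> shifts) & 0b11
        dosages[:, j] = lut[codes[:n]]
    return GenotypeMatrix(dosages=dosages,
                          ids=fam[1].astype(str).to_numpy(),
                          variant_ids=bim[1].astype(str).to_numpy())


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    """Delimited dosage matrix with an IID column (missing as empty cells)."""
    df = pd.DataFrame(g.dosages, columns=g.variant_ids)
    df.insert(0, "IID", g.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.0f")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    return GenotypeMatrix(dosages=df.iloc[:, 1:].to_numpy(dtype=float),
                          ids=df["IID"].astype(str).to_numpy(),
                          variant_ids=np.asarray(df.columns[1:]))


def write_gcta_grm(kernel: Kernel, prefix, n_variants: int = 0) -> None:
    """Write the GCTA binary GRM triple (.grm.bin/.grm.id/.grm.N.bin)."""
    prefix = Path(prefix)
    n = kernel.n
    tri = kernel.matrix[np.tril_indices(n)]
    tri.astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(tri.size, float(n_variants), dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": kernel.ids, "iid": kernel.ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_gcta_grm(prefix, label: str = "G") -> Kernel:
    """Read a GCTA binary GRM triple back into a Kernel."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None)[1].astype(str).to_numpy()
    n = ids.size
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(float)
    if tri.size != n * (n + 1) // 2:
        raise ValidationError("GRM triangle size does not match id count")
    mat = np.zeros((n, n))
    mat[np.tril_indices(n)] = tri
    mat = mat + np.tril(mat, -1).T
    return Kernel(matrix=mat, ids=ids, label=label)
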