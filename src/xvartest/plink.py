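"""Reader/writer for PLINK 1 binary genotype filesets (bed/bim/fam).

The .bed file is SNP-major: after the three magic bytes (0x6c 0x1b 0x01),
each SNP occupies ceil(n_samples/4) bytes, two bits per sample, lowest
bits first.  Bit-pair meanings follow the PLINK 1 specification:

    00  homozygous for the first (.bim A1) allele
    01  missing
    10  heterozygous
    11  homozygous for the second (.bim A2) allele

Genotypes are returned as a samples x SNPs float array counting A1
alleles (2/1/0) with NaN for missing — A1 is conventionally the minor
allele, so the count matches the coding used by the association tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_plink", "write_plink", "read_phenotypes"]

_MAGIC = bytes((0x6C, 0x1B, 0x01))

# bit-pair value -> A1-allele count (NaN = missing)
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])

FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]
BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]


def read_plink(bed_path, bim_path, fam_path):
    """Read a PLINK bed/bim/fam fileset.

    Returns ``(genotypes, fam, bim)`` where ``genotypes`` is an
    (n_samples, n_snps) float array of A1-allele counts with NaN for
    missing calls, and fam/bim are DataFrames with the standard columns.

    Raises ``ValueError`` on a magic-number mismatch or when the .bed
    size is inconsistent with the .bim/.fam dimensions.
    """
    bed_path, bim_path, fam_path = Path(bed_path), Path(bim_path), Path(fam_path)
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, names=FAM_COLUMNS, dtype={"fid": str, "iid": str})
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, names=BIM_COLUMNS, dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError(f"{bed_path}: not a SNP-major PLINK .bed file (bad magic bytes)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ValueError(
            f"{bed_path}: size {len(raw)} inconsistent with "
            f"{n} samples x {m} SNPs (expected {expected})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    pairs = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        pairs[:, k::4] = (data >> shift) & 0b11
    geno = _DECODE[pairs[:, :n]].T.copy()
    return geno, fam, bim


def write_plink(prefix, genotypes, fam: pd.DataFrame, bim: pd.DataFrame) -> None:
    """Write genotypes plus metadata as a bed/bim/fam fileset at ``prefix``.

    ``genotypes`` is (n_samples, n_snps), values in {0, 1, 2, NaN},
    interpreted as A1-allele counts.
    """
    prefix = Path(prefix)
    geno = np.asarray(genotypes, dtype=float)
    n, m = geno.shape
    if n != len(fam):
        raise ValueError(f"genotypes have {n} rows but fam has {len(fam)} samples")
    if m != len(bim):
        raise ValueError(f"genotypes have {m} columns but bim has {len(bim)} SNPs")
    fam[FAM_COLUMNS].to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim[BIM_COLUMNS].to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    # code 2 -> 00, 1 -> 10, 0 -> 11, NaN -> 01
    pairs = np.full(geno.shape, 1, dtype=np.uint8)
    pairs[geno == 2.0] = 0b00
    pairs[geno == 1.0] = 0b10
    pairs[geno == 0.0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.ones((m, bytes_per_snp * 4), dtype=np.uint8) * 0b11  # pad = hom A2
    padded[:, :n] = pairs.T
    out = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        out |= padded[:, k::4] << shift
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(out.tobytes())


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-delimited phenotype table.

    Header row required; the first column holds sample IDs matching the
    .fam individual IDs, remaining columns are quantitative traits.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: phenotype table needs an ID column plus >= 1 trait")
    df = df.rename(columns={df.columns[0]: "sample_id"})
    df["sample_id"] = df["sample_id"].astype(str)
    return df
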