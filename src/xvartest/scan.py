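"""Chromosome-wide scan: QC, per-SNP testing, and power-comparison summaries.

Applies the four association tests SNP by SNP to a female cohort read
from a PLINK fileset, after standard genotype QC (individual
missingness, SNP missingness, minor-allele frequency, exact HWE in
females).  Per-SNP degeneracies are recorded as invalid results rather
than raised, so a scan never aborts on one site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    FemaleSample,
    TestResult,
    combined_test,
    standard_association_test,
    variance_test,
    weighted_association_test,
)
from .hwe import hwe_exact_test

__all__ = [
    "QCThresholds",
    "QCReport",
    "SnpRecord",
    "ScanTable",
    "apply_qc",
    "run_scan",
    "power_comparison_fraction",
    "inverse_normal_transform",
]

logger = logging.getLogger(__name__)

FEMALE_SEX_CODE = 2

# Filters are applied in this order; each excluded SNP is attributed to
# the first filter it fails.
SNP_FILTER_ORDER = ("snp_missingness", "maf", "hwe")


@dataclass(frozen=True)
class QCThresholds:
    """Genotype QC thresholds (defaults mirror common GWAS practice).

    SNPs are kept when MAF > ``maf``, SNP missing rate <= ``snp_missingness``
    and female HWE exact p > ``hwe_p``; individuals are kept when their
    missing rate is <= ``ind_missingness`` (rates strictly above the
    threshold are removed, the PLINK --geno/--mind convention).
    """

    maf: float = 0.05
    snp_missingness: float = 0.10
    ind_missingness: float = 0.10
    hwe_p: float = 5e-5


@dataclass(frozen=True)
class SnpRecord:
    """Per-SNP QC summary computed on the analyzed females."""

    snp_id: str
    chromosome: str
    position: int
    alleles: tuple[str, str]
    female_counts: tuple[int, int, int, int]  # (n0, n1, n2, n_missing)
    maf: float
    call_rate: float
    hwe_p: float
    qc_pass: bool
    fail_reason: str | None = None


@dataclass(frozen=True)
class QCReport:
    """Survivors and per-filter exclusion tallies of one QC pass."""

    kept_snps: np.ndarray        # indices into the input SNP axis
    kept_females: np.ndarray     # indices into the input sample axis
    records: list[SnpRecord]
    exclusions: dict[str, int]
    n_individuals_removed: int


@dataclass(frozen=True)
class ScanTable:
    """Per-(SNP, trait) results of all four tests.

    ``table`` has one row per SNP x trait with columns
    snp_id, chrom, pos, trait, maf, n0, n1, n2 and
    <test>_{stat,df,p,valid} for each of standard, variance, weighted,
    combined.  ``bonferroni_threshold`` is alpha / n_snps_tested.
    """

    table: pd.DataFrame
    bonferroni_threshold: float
    n_snps_tested: int
    alpha: float = 0.05


def _female_genotype_stats(col: np.ndarray):
    """(n0, n1, n2, n_missing, maf, call_rate) for one SNP column."""
    missing = np.isnan(col)
    observed = col[~missing]
    n0 = int(np.sum(observed == 0))
    n1 = int(np.sum(observed == 1))
    n2 = int(np.sum(observed == 2))
    n_obs = n0 + n1 + n2
    if n_obs:
        freq_a1 = (2 * n2 + n1) / (2 * n_obs)
        maf = min(freq_a1, 1.0 - freq_a1)
    else:
        maf = float("nan")
    call_rate = n_obs / col.size if col.size else float("nan")
    return n0, n1, n2, int(missing.sum()), maf, call_rate


def apply_qc(
    genotypes: np.ndarray,
    fam: pd.DataFrame,
    bim: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    female_code: int = FEMALE_SEX_CODE,
) -> QCReport:
    """Apply genotype QC to a PLINK-style dataset, females only.

    Males (and any sample whose sex code differs from ``female_code``)
    are set aside first.  Individuals with missing rate >=
    ``ind_missingness`` are then removed, and the SNP filters are
    evaluated on the retained females in the order: SNP missingness,
    MAF, female HWE.  Each excluded SNP is tallied under the first
    filter it fails.
    """
    geno = np.asarray(genotypes, dtype=float)
    female_idx = np.flatnonzero(fam["sex"].to_numpy() == female_code)
    if female_idx.size == 0:
        logger.warning("apply_qc: no samples with sex code %d", female_code)
    g_f = geno[female_idx]

    miss_rate = np.isnan(g_f).mean(axis=1) if g_f.size else np.zeros(0)
    keep_ind = miss_rate <= thresholds.ind_missingness
    n_removed = int((~keep_ind).sum())
    kept_females = female_idx[keep_ind]
    g_f = geno[kept_females]

    exclusions = {name: 0 for name in SNP_FILTER_ORDER}
    records: list[SnpRecord] = []
    kept_snps = []
    for j in range(geno.shape[1]):
        n0, n1, n2, n_miss, maf, call_rate = _female_genotype_stats(g_f[:, j])
        hwe_p = hwe_exact_test(n0, n1, n2) if (n0 + n1 + n2) else float("nan")
        fail = None
        if (1.0 - call_rate) > thresholds.snp_missingness:
            fail = "snp_missingness"
        elif not maf > thresholds.maf:
            fail = "maf"
        elif not hwe_p > thresholds.hwe_p:
            fail = "hwe"
        row = bim.iloc[j]
        records.append(
            SnpRecord(
                snp_id=str(row["snp"]),
                chromosome=str(row["chrom"]),
                position=int(row["pos"]),
                alleles=(str(row["a1"]), str(row["a2"])),
                female_counts=(n0, n1, n2, n_miss),
                maf=maf,
                call_rate=call_rate,
                hwe_p=hwe_p,
                qc_pass=fail is None,
                fail_reason=fail,
            )
        )
        if fail is None:
            kept_snps.append(j)
        else:
            exclusions[fail] += 1
    if not kept_snps:
        logger.warning("apply_qc: no SNPs survived QC")
    logger.info(
        "QC: removed %d individuals; SNP exclusions %s; %d SNPs kept",
        n_removed, exclusions, len(kept_snps),
    )
    return QCReport(
        kept_snps=np.asarray(kept_snps, dtype=int),
        kept_females=kept_females,
        records=records,
        exclusions=exclusions,
        n_individuals_removed=n_removed,
    )


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset 0.5), NaN-safe."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    ranks = stats.rankdata(x[ok])
    out[ok] = stats.norm.ppf((ranks - 0.5) / ok.sum())
    return out


_TESTS = ("standard", "variance", "weighted", "combined")


def _result_columns(res: TestResult, prefix: str) -> dict:
    return {
        f"{prefix}_stat": res.statistic if res.valid else np.nan,
        f"{prefix}_df": res.df if (res.valid and res.df is not None) else np.nan,
        f"{prefix}_p": res.p_value if res.valid else np.nan,
        f"{prefix}_valid": res.valid,
    }


def run_scan(
    genotypes: np.ndarray,
    bim: pd.DataFrame,
    phenotypes: pd.DataFrame,
    traits: list[str] | None = None,
    alpha: float = 0.05,
    two_sided_variance: bool = False,
) -> ScanTable:
    """Run all four tests per SNP per trait on QC'd female genotypes.

    ``genotypes`` is the (females x SNPs) matrix surviving QC, with rows
    aligned to ``phenotypes`` (one row per female, trait columns beyond
    ``sample_id``).  For each SNP x trait, samples with a missing
    genotype or phenotype are dropped pairwise, the genotype is recoded
    to count the minor allele among the analyzed females, and the four
    tests are applied.  Output rows are sorted by position.
    """
    geno = np.asarray(genotypes, dtype=float)
    if traits is None:
        traits = [c for c in phenotypes.columns if c != "sample_id"]
    if geno.shape[0] != len(phenotypes):
        raise ValueError(
            f"{geno.shape[0]} genotype rows vs {len(phenotypes)} phenotype rows"
        )
    n_snps = geno.shape[1]
    rows = []
    for j in range(n_snps):
        col = geno[:, j]
        n0, n1, n2, _, maf, _ = _female_genotype_stats(col)
        meta = bim.iloc[j]
        for trait in traits:
            y_all = phenotypes[trait].to_numpy(dtype=float)
            ok = ~np.isnan(col) & ~np.isnan(y_all)
            g = col[ok].astype(int)
            # Recode so the reference allele is the minor allele among the
            # females analyzed for this trait.
            if g.size and g.sum() > g.size:
                g = 2 - g
            row = {
                "snp_id": str(meta["snp"]),
                "chrom": str(meta["chrom"]),
                "pos": int(meta["pos"]),
                "trait": trait,
                "maf": maf,
                "n0": n0,
                "n1": n1,
                "n2": n2,
            }
            if g.size == 0:
                results = {name: TestResult(None, None, None, 0, False, "no data")
                           for name in _TESTS}
            else:
                sample = FemaleSample(g, y_all[ok])
                results = {
                    "standard": standard_association_test(sample),
                    "variance": variance_test(sample, two_sided=two_sided_variance),
                    "weighted": weighted_association_test(sample),
                    "combined": combined_test(sample, two_sided_variance),
                }
            for name in _TESTS:
                row.update(_result_columns(results[name], name))
            rows.append(row)
    table = pd.DataFrame(rows).sort_values(["pos", "trait"], kind="stable")
    table = table.reset_index(drop=True)
    return ScanTable(
        table=table,
        bonferroni_threshold=alpha / n_snps if n_snps else float("nan"),
        n_snps_tested=n_snps,
        alpha=alpha,
    )


def power_comparison_fraction(
    scan: ScanTable | pd.DataFrame, cutoffs
) -> dict[float, float]:
    """Fraction of top SNPs where the weighted test beats the standard test.

    For each p-value cutoff c, among rows where min(weighted p,
    standard p) < c (both tests valid), returns the fraction with the
    weighted p strictly smaller; exact ties count 0.5 so that identical
    tests give exactly 50%.  Cutoffs with an empty selection are omitted.
    """
    df = scan.table if isinstance(scan, ScanTable) else scan
    pw = df["weighted_p"].to_numpy(dtype=float)
    ps = df["standard_p"].to_numpy(dtype=float)
    both = ~np.isnan(pw) & ~np.isnan(ps)
    out: dict[float, float] = {}
    for c in cutoffs:
        sel = both & (np.minimum(pw, ps) < c)
        m = int(sel.sum())
        if m == 0:
            continue
        wins = float(np.sum(pw[sel] < ps[sel]))
        ties = float(np.sum(pw[sel] == ps[sel]))
        out[float(c)] = (wins + 0.5 * ties) / m
    return out
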