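"""Simulation of X-inactivation phenotypes and Monte-Carlo scenario runs.

The generative model is a single X-linked QTL with alleles Q/q in a
female-only cohort.  Genotypes are drawn under Hardy-Weinberg equilibrium
at a given minor-allele frequency.  Phenotypes follow

    y_i = mu + g_i + e_i,        e_i ~ N(0, sigma2)

with ``a`` the per-allele (additive) effect: genotypic value 0 for qq and
2a for QQ, so the regression slope on the 0/1/2 allele count is ``a``.
X-inactivation makes a heterozygote a mosaic expressing one of her two
alleles, so Qq receives the full genotypic value of one homozygote class:
2a with probability ``theta`` (the inactivation ratio), else 0.  The two
expressed states are therefore ``gap = 2a`` apart, heterozygotes have
mean 2a*theta and extra variance theta*(1-theta)*(2a)**2 — a**2 under
balanced inactivation (theta = 0.5).  Non-inactivation sources of
heterozygote over-dispersion (e.g. epistasis, expression homeostasis)
are emulated by injecting extra independent noise with variance
``extra_noise_frac * sigma2`` into heterozygotes only.

``run_scenario`` repeats simulation and testing to estimate type-I error
or power of the four tests at a nominal level, plus the joint rejection
rate of the standard and variance tests (to probe their independence
under the alternative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    _P_CEIL,
    _P_FLOOR,
    _mean_and_var,
    _variance_stat,
    _wls_stat,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "simulate_genotypes",
    "simulate_phenotypes",
    "expected_het_variance",
    "run_scenario",
    "run_grid",
    "load_scenarios",
    "make_qc_fixture",
    "make_variance_qtl_fixture",
]

logger = logging.getLogger(__name__)

TEST_NAMES = ("standard", "variance", "weighted", "combined")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulation scenario.

    Parameters
    ----------
    n
        Number of females per replicate.
    maf
        Minor (Q) allele frequency, in (0, 0.5].
    a
        Per-allele additive QTL effect in trait units; the homozygote
        classes (and the two mosaic expression states of a heterozygote)
        differ by ``2a``.
    theta
        Inactivation ratio: probability a heterozygote expresses Q.
        0.5 is balanced random inactivation; 0 or 1 is complete skew.
    extra_noise_frac
        Extra heterozygote noise variance as a fraction of sigma2.
    mu, sigma2
        Population mean and residual variance.  Defaults 0 and 1; all
        tests are location invariant so mu is immaterial.
    alpha
        Nominal significance level for rejection-rate estimates.
    replicates
        Monte-Carlo replicates.
    seed
        Root seed; replicate sub-streams are spawned from it so results
        are reproducible and order-independent.
    null_model
        If True, phenotypes are generated independently of genotype.
    variance_two_sided
        Use the two-sided variant of the heterozygote-variance test.
    """

    n: int
    maf: float
    a: float = 0.1
    theta: float = 0.5
    extra_noise_frac: float = 0.0
    mu: float = 0.0
    sigma2: float = 1.0
    alpha: float = 0.05
    replicates: int = 20_000
    seed: int = 0
    null_model: bool = False
    variance_two_sided: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.extra_noise_frac < 0.0:
            raise ValueError("extra_noise_frac must be >= 0")
        if self.sigma2 <= 0.0:
            raise ValueError("sigma2 must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ScenarioResult:
    """Rejection-rate summary of one scenario.

    ``rejection_rates`` holds, per test, the fraction of valid replicates
    with p < alpha; ``mc_se`` the binomial Monte-Carlo standard error
    sqrt(r(1-r)/m); ``joint_rate`` the fraction where the standard AND
    variance tests both reject; ``expected_joint`` the product of their
    marginal rates (equal to joint under independence).
    """

    spec: ScenarioSpec
    rejection_rates: dict[str, float]
    mc_se: dict[str, float]
    replicates_used: dict[str, int]
    invalid_counts: dict[str, int]
    joint_rate: float
    expected_joint: float


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n female genotype codes (minor-allele counts) under HWE.

    Each genotype is Binomial(2, maf), i.e. frequencies
    ((1-p)^2, 2p(1-p), p^2) for codes (0, 1, 2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    return rng.binomial(2, maf, size=n).astype(np.int8)


def simulate_phenotypes(
    genotypes: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Generate phenotypes for the given genotypes under ``spec``.

    Homozygotes receive genotypic value 0 (code 0) or ``2a`` (code 2);
    each heterozygote, being a mosaic expressing a single allele,
    receives the genotypic value of one homozygote class — ``2a`` with
    probability ``theta``, else 0 — plus optional extra noise.  Under
    ``null_model`` the phenotype is mu + residual error regardless of
    genotype.
    """
    g = np.asarray(genotypes)
    n = g.size
    gap = 2.0 * spec.a
    y = spec.mu + rng.normal(0.0, math.sqrt(spec.sigma2), size=n)
    if spec.null_model:
        return y
    het = g == 1
    gv = np.where(g == 2, gap, 0.0)
    n_het = int(het.sum())
    if n_het:
        expressed_q = rng.random(n_het) < spec.theta
        gv[het] = np.where(expressed_q, gap, 0.0)
        if spec.extra_noise_frac > 0.0:
            extra_sd = math.sqrt(spec.extra_noise_frac * spec.sigma2)
            y[het] += rng.normal(0.0, extra_sd, size=n_het)
    return y + gv


def expected_het_variance(
    gap: float, theta: float, sigma2: float, extra_noise_frac: float = 0.0
) -> float:
    """Analytic phenotypic variance of heterozygous females.

    ``gap`` is the phenotypic distance between the two mosaic expression
    states of a heterozygote — the difference between the homozygote
    genotypic values, i.e. ``2a`` for a scenario with per-allele effect
    ``a``.  Mosaic expression contributes theta*(1-theta)*gap**2 on top
    of the residual variance inflated by any extra heterozygote noise:
    ``theta*(1-theta)*gap**2 + sigma2*(1 + extra_noise_frac)``.
    """
    if sigma2 <= 0.0:
        raise ValueError("sigma2 must be > 0")
    return theta * (1.0 - theta) * gap * gap + sigma2 * (1.0 + extra_noise_frac)


def _replicate_raw(g: np.ndarray, y: np.ndarray):
    """Raw statistics of the four tests for one simulated dataset.

    Returns (t_var, df_var, t_wls, t_ols) with NaN marking an invalid
    test; p-values are attached later in one vectorized pass.
    """
    y0, y1, y2 = y[g == 0], y[g == 1], y[g == 2]
    groups = [(0, y0), (1, y1), (2, y2)]

    var_out = _variance_stat(y0, y1, y2)
    t_var, df_var = var_out if var_out is not None else (np.nan, np.nan)

    weights: dict[int, float] = {}
    ok = True
    present = 0
    for code, yj in groups:
        if yj.size == 0:
            continue
        present += 1
        if yj.size < 2:
            ok = False
            break
        vj = _mean_and_var(yj)[1]
        if vj <= 0.0:
            ok = False
            break
        weights[code] = 1.0 / vj
    t_wls = np.nan
    if ok and present >= 2:
        fit = _wls_stat(g, y, weights, groups=groups)
        if fit is not None:
            t_wls = fit[1]

    t_ols = np.nan
    fit = _wls_stat(g, y, None, groups=groups)
    if fit is not None:
        t_ols = fit[1]
    return t_var, df_var, t_wls, t_ols


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Estimate rejection rates of all four tests under one scenario.

    Each replicate draws fresh genotypes and phenotypes from its own
    spawned RNG sub-stream, applies the four tests, and records raw
    statistics; p-values and rejection indicators are computed in a
    single vectorized pass.  Replicates where a test is degenerate are
    excluded from that test's denominator and counted.
    """
    m = spec.replicates
    if m < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(m)
    t_var = np.empty(m)
    df_var = np.empty(m)
    t_wls = np.empty(m)
    t_ols = np.empty(m)
    for k in range(m):
        rng = np.random.default_rng(children[k])
        g = simulate_genotypes(spec.n, spec.maf, rng)
        y = simulate_phenotypes(g, spec, rng)
        t_var[k], df_var[k], t_wls[k], t_ols[k] = _replicate_raw(g, y)

    df_slope = spec.n - 2
    with np.errstate(invalid="ignore"):
        if spec.variance_two_sided:
            p_var = 2.0 * stats.t.sf(np.abs(t_var), df_var)
        else:
            p_var = stats.t.sf(t_var, df_var)
        p_wls = 2.0 * stats.t.sf(np.abs(t_wls), df_slope)
        p_ols = 2.0 * stats.t.sf(np.abs(t_ols), df_slope)
        z = stats.norm.isf(np.clip(p_var, _P_FLOOR, _P_CEIL)) + stats.norm.isf(
            np.clip(p_wls, _P_FLOOR, _P_CEIL)
        )
        p_comb = stats.norm.sf(z / math.sqrt(2.0))
        p_comb = np.where(np.isnan(p_var) | np.isnan(p_wls), np.nan, p_comb)

    p_by_test = {
        "standard": p_ols,
        "variance": p_var,
        "weighted": p_wls,
        "combined": p_comb,
    }
    rates: dict[str, float] = {}
    mc_se: dict[str, float] = {}
    used: dict[str, int] = {}
    invalid: dict[str, int] = {}
    for name, p in p_by_test.items():
        valid = ~np.isnan(p)
        n_valid = int(valid.sum())
        used[name] = n_valid
        invalid[name] = m - n_valid
        if invalid[name]:
            logger.info(
                "scenario n=%d maf=%.3g: %d/%d replicates invalid for %s test",
                spec.n, spec.maf, invalid[name], m, name,
            )
        r = float(np.mean(p[valid] < spec.alpha)) if n_valid else float("nan")
        rates[name] = r
        mc_se[name] = (
            math.sqrt(r * (1.0 - r) / n_valid) if n_valid else float("nan")
        )

    both = ~np.isnan(p_ols) & ~np.isnan(p_var)
    if both.any():
        joint = float(
            np.mean((p_ols[both] < spec.alpha) & (p_var[both] < spec.alpha))
        )
    else:
        joint = float("nan")
    expected = rates["standard"] * rates["variance"]
    return ScenarioResult(
        spec=spec,
        rejection_rates=rates,
        mc_se=mc_se,
        replicates_used=used,
        invalid_counts=invalid,
        joint_rate=joint,
        expected_joint=expected,
    )


# ---------------------------------------------------------------------------
# Scenario grids (plain-text config in, delimited table out)

_GRID_COLUMNS = [
    "n", "maf", "a", "theta", "noise", "alpha", "reps", "seed", "null",
]


def load_scenarios(path) -> list[ScenarioSpec]:
    """Read a scenario grid from a whitespace/tab-delimited config file.

    Expected header columns: n, maf, a, theta, noise, alpha, reps, seed
    and optionally null (0/1).  One scenario per row.
    """
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _GRID_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"scenario config is missing columns: {missing}")
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            ScenarioSpec(
                n=int(row.n),
                maf=float(row.maf),
                a=float(row.a),
                theta=float(row.theta),
                extra_noise_frac=float(row.noise),
                alpha=float(row.alpha),
                replicates=int(row.reps),
                seed=int(row.seed),
                null_model=bool(getattr(row, "null", 0)),
            )
        )
    return specs


def run_grid(specs: list[ScenarioSpec]) -> pd.DataFrame:
    """Run a list of scenarios and tabulate rejection rates (percent)."""
    rows = []
    for spec in specs:
        res = run_scenario(spec)
        row = {
            "n": spec.n,
            "maf": spec.maf,
            "a": spec.a,
            "theta": spec.theta,
            "noise": spec.extra_noise_frac,
            "null": int(spec.null_model),
        }
        for name in TEST_NAMES:
            row[name] = 100.0 * res.rejection_rates[name]
        row["shared"] = 100.0 * res.joint_rate
        row["shared_expected"] = 100.0 * res.expected_joint
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deterministic PLINK-style fixtures for the scan pipeline

def make_qc_fixture(n_females: int = 200, n_males: int = 20, seed: int = 7):
    """Small genotype panel with one planted violation of each QC filter.

    Returns ``(genotypes, fam, bim)``: 10 SNPs for n_females + n_males
    samples (males present only to exercise sex filtering).  Among
    females, SNP qc_maf fails the minor-allele-frequency filter, SNP
    qc_miss the SNP-missingness filter, SNP qc_hwe the female HWE filter
    (every female heterozygous); the remaining 7 SNPs pass all filters.
    Genotypes are float with NaN for missing.
    """
    rng = np.random.default_rng(seed)
    n = n_females + n_males
    n_snps = 10
    geno = np.empty((n, n_snps))
    # Clean SNPs: common, fully typed, drawn under HWE.
    for j in range(7):
        geno[:, j] = rng.binomial(2, 0.3, size=n)
    # Planted low-MAF SNP: a single heterozygous female.
    geno[:, 7] = 0.0
    geno[0, 7] = 1.0
    # Planted high-missingness SNP: 20% of females untyped.
    geno[:, 8] = rng.binomial(2, 0.3, size=n)
    drop = rng.choice(n_females, size=n_females // 5, replace=False)
    geno[drop, 8] = np.nan
    # Planted HWE violation: every female heterozygous.
    geno[:, 9] = 1.0
    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "father": "0",
            "mother": "0",
            "sex": [2] * n_females + [1] * n_males,
            "phenotype": -9,
        }
    )
    bim = pd.DataFrame(
        {
            "chrom": "X",
            "snp": [f"snp{j}" for j in range(7)]
            + ["qc_maf", "qc_miss", "qc_hwe"],
            "cm": 0.0,
            "pos": np.arange(1, n_snps + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    return geno, fam, bim


def make_variance_qtl_fixture(
    n_females: int = 500,
    n_snps: int = 10,
    planted_index: int | None = None,
    maf: float = 0.3,
    het_extra_var: float = 3.0,
    seed: int = 11,
):
    """Female cohort with one planted variance-heterogeneity QTL.

    All SNPs are drawn under HWE at ``maf``; the trait is standard normal
    plus, for heterozygotes at the planted SNP only, independent noise of
    variance ``het_extra_var`` — the group means stay equal, so only the
    variance test should flag the locus.  ``planted_index`` defaults to
    the middle SNP.  Returns ``(genotypes, fam, bim, phenotypes)`` with
    phenotypes as a DataFrame (sample_id, trait).
    """
    if planted_index is None:
        planted_index = n_snps // 2
    if not 0 <= planted_index < n_snps:
        raise ValueError("planted_index out of range")
    rng = np.random.default_rng(seed)
    geno = np.empty((n_females, n_snps))
    for j in range(n_snps):
        geno[:, j] = rng.binomial(2, maf, size=n_females)
    y = rng.normal(0.0, 1.0, size=n_females)
    het = geno[:, planted_index] == 1
    y[het] += rng.normal(0.0, math.sqrt(het_extra_var), size=int(het.sum()))
    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n_females)],
            "iid": [f"I{i}" for i in range(n_females)],
            "father": "0",
            "mother": "0",
            "sex": 2,
            "phenotype": -9,
        }
    )
    bim = pd.DataFrame(
        {
            "chrom": "X",
            "snp": [f"snp{j}" for j in range(n_snps)],
            "cm": 0.0,
            "pos": np.arange(1, n_snps + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    pheno = pd.DataFrame({"sample_id": fam["iid"], "trait": y})
    return geno, fam, bim, pheno
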