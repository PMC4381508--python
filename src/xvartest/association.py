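"""Association tests for X-linked quantitative traits in females.

X-inactivation silences one X copy per cell lineage at random, so a female
who is heterozygous for a quantitative trait locus (QTL) is a mosaic of
cells expressing either allele.  If the locus has an additive effect ``a``
and the inactivation ratio is ``theta``, heterozygotes carry an extra
phenotypic variance ``theta * (1 - theta) * a**2`` on top of the residual
variance shared by all genotype groups.  The tests in this module exploit
that signature:

``variance_test``
    A two-group Brown-Forsythe-type test contrasting the phenotypic
    variance of heterozygous females against the pooled homozygotes,
    using absolute deviations from per-group medians and a
    Welch-Satterthwaite t reference.
``weighted_association_test``
    A mean-effect test: weighted least-squares regression of phenotype on
    genotype code, each individual weighted by the inverse empirical
    variance of her genotype group, which absorbs the heterozygote
    variance inflation instead of testing it.
``standard_association_test``
    Ordinary least-squares regression of phenotype on the 0/1/2 genotype
    code, the conventional additive association test.
``combined_test``
    Stouffer Z-score combination of the variance and weighted tests,
    which are independent under the null and capture complementary
    signals under the alternative.

All tests operate on females only; genotype codes count copies of the
reference (conventionally minor) allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FemaleSample",
    "TestResult",
    "GroupSummary",
    "median_deviations",
    "variance_test",
    "weighted_association_test",
    "standard_association_test",
    "stouffer_combine",
    "combined_test",
]

logger = logging.getLogger(__name__)

# Clamping bounds applied to p-values before the normal-quantile transform,
# so Phi^-1 stays finite.
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class FemaleSample:
    """Paired genotype codes and phenotypes for the analyzed females.

    Parameters
    ----------
    genotypes
        Integer codes in {0, 1, 2}: copies of the reference allele.
    phenotypes
        Quantitative trait values, same length as ``genotypes``.

    Missing entries must be removed (pairwise) before construction.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        y = np.asarray(self.phenotypes, dtype=float)
        if g.ndim != 1 or y.ndim != 1:
            raise ValueError("genotypes and phenotypes must be 1-D vectors")
        if g.shape[0] != y.shape[0]:
            raise ValueError(
                f"length mismatch: {g.shape[0]} genotypes vs {y.shape[0]} phenotypes"
            )
        if g.shape[0] == 0:
            raise ValueError("empty sample")
        if not np.all(np.isin(g, (0, 1, 2))):
            raise ValueError("genotype codes must be 0, 1, or 2")
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotypes must be finite; drop missing values first")
        object.__setattr__(self, "genotypes", g.astype(np.int8))
        object.__setattr__(self, "phenotypes", y)

    def __len__(self) -> int:
        return int(self.genotypes.shape[0])


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test on one SNP/trait pair.

    ``valid`` is False when a degeneracy rule fires (group too small, zero
    variance where a weight is needed, monomorphic site); the statistic and
    p-value are then None so chromosome scans record rather than abort.
    """

    statistic: float | None
    df: float | None
    p_value: float | None
    direction: int
    valid: bool
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.valid and self.p_value is not None:
            if not (0.0 <= self.p_value <= 1.0):
                raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class GroupSummary:
    """Per-genotype-group moments entering the variance and weighted tests.

    ``mean_z_het`` / ``var_z_het`` are the moments of the absolute median
    deviations of heterozygotes; the ``hom`` counterparts pool both
    homozygote groups after centering each on its own median.  Sample
    variances use the n-1 denominator.  ``group_variances`` are the raw
    phenotype variances per genotype code (NaN when a group has < 2
    members); their inverses are the weights of the weighted test.
    """

    n0: int
    n1: int
    n2: int
    mean_z_het: float
    mean_z_hom: float
    var_z_het: float
    var_z_hom: float
    group_variances: tuple[float, float, float] = field(default=(float("nan"),) * 3)

    @property
    def n_hom(self) -> int:
        return self.n0 + self.n2


def _invalid(reason: str) -> TestResult:
    return TestResult(
        statistic=None, df=None, p_value=None, direction=0, valid=False, reason=reason
    )


def _group_views(g: np.ndarray, y: np.ndarray):
    return y[g == 0], y[g == 1], y[g == 2]


def _sample_var(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1)) if x.size >= 2 else float("nan")


def median_deviations(sample: FemaleSample):
    """Absolute deviations of each phenotype from its genotype-group median.

    Returns ``(z, summary)`` where ``z`` follows the input order and
    ``summary`` is a :class:`GroupSummary` with het vs pooled-homozygote
    z-moments.  Each homozygote group is centered on its own median before
    pooling, so a mean shift between the two homozygote classes does not
    masquerade as dispersion.
    """
    g, y = sample.genotypes, sample.phenotypes
    z = np.empty_like(y)
    for code in (0, 1, 2):
        mask = g == code
        if mask.any():
            z[mask] = np.abs(y[mask] - np.median(y[mask]))
    z_het = z[g == 1]
    z_hom = z[(g == 0) | (g == 2)]
    y0, y1, y2 = _group_views(g, y)
    summary = GroupSummary(
        n0=int(y0.size),
        n1=int(y1.size),
        n2=int(y2.size),
        mean_z_het=float(z_het.mean()) if z_het.size else float("nan"),
        mean_z_hom=float(z_hom.mean()) if z_hom.size else float("nan"),
        var_z_het=_sample_var(z_het),
        var_z_hom=_sample_var(z_hom),
        group_variances=(_sample_var(y0), _sample_var(y1), _sample_var(y2)),
    )
    return z, summary


def _fast_median(x: np.ndarray) -> float:
    """Median via partial sort; even-sized groups take the midpoint of the
    two central order statistics."""
    n = x.size
    h = n >> 1
    if n & 1:
        return float(np.partition(x, h)[h])
    part = np.partition(x, (h - 1, h))
    return 0.5 * (float(part[h - 1]) + float(part[h]))


def _mean_and_var(x: np.ndarray) -> tuple[float, float]:
    """Mean and n-1 sample variance in one pass (no dtype dispatch cost)."""
    n = x.size
    m = float(x.sum()) / n
    d = x - m
    return m, float(d @ d) / (n - 1)


def _variance_stat(y0: np.ndarray, y1: np.ndarray, y2: np.ndarray):
    """Raw heterozygote-variance statistic and Welch-Satterthwaite df.

    Returns ``(stat, df)`` or ``None`` when degenerate.  The statistic is
    the two-sample t contrast of mean absolute median deviations, het
    versus pooled homozygotes.
    """
    n1 = y1.size
    n02 = y0.size + y2.size
    if n1 < 2 or n02 < 2:
        return None
    z1 = np.abs(y1 - _fast_median(y1))
    parts = []
    if y0.size:
        parts.append(np.abs(y0 - _fast_median(y0)))
    if y2.size:
        parts.append(np.abs(y2 - _fast_median(y2)))
    z02 = np.concatenate(parts)
    m1, v1 = _mean_and_var(z1)
    m02, v02 = _mean_and_var(z02)
    if v1 <= 0.0 and v02 <= 0.0:
        return None
    se2_1 = v1 / n1
    se2_02 = v02 / n02
    denom = se2_1 + se2_02
    stat = (m1 - m02) / math.sqrt(denom)
    df = denom**2 / (se2_1**2 / (n1 - 1) + se2_02**2 / (n02 - 1))
    return stat, df


def variance_test(sample: FemaleSample, two_sided: bool = False) -> TestResult:
    """Test for inflated phenotypic variance in heterozygous females.

    A two-group Brown-Forsythe-type contrast: phenotypes are converted to
    absolute deviations from their genotype-group medians, and the mean
    deviation of heterozygotes is compared with that of the pooled
    homozygotes by a Welch t-statistic

    .. math::

        T = \\frac{\\bar Z_1 - \\bar Z_{0/2}}
                 {\\sqrt{s_1^2/n_1 + s_{0/2}^2/(n_0+n_2)}}

    with Welch-Satterthwaite degrees of freedom.  The default p-value is
    the upper one-sided tail, matching the alternative hypothesis that
    heterozygotes are over-dispersed; ``two_sided=True`` tests any variance
    difference.
    """
    y0, y1, y2 = _group_views(sample.genotypes, sample.phenotypes)
    out = _variance_stat(y0, y1, y2)
    if out is None:
        if y1.size < 2 or (y0.size + y2.size) < 2:
            return _invalid("heterozygote or pooled homozygote group has < 2 members")
        return _invalid("both z-variances are zero")
    stat, df = out
    p = float(stats.t.sf(stat, df))
    if two_sided:
        p = float(2.0 * stats.t.sf(abs(stat), df))
    return TestResult(
        statistic=stat,
        df=df,
        p_value=p,
        direction=int(np.sign(stat)),
        valid=True,
    )


def _wls_stat(g: np.ndarray, y: np.ndarray, weights_by_group, groups=None):
    """Slope t-statistic of a (weighted) regression of y on genotype code.

    ``weights_by_group`` maps code -> weight, or None for OLS.  Works from
    per-group sufficient statistics, so the cost is dominated by three
    group reductions.  ``groups`` optionally supplies the precomputed
    ``(code, y_group)`` views.  Returns ``(slope, tstat, df)``; ``tstat``
    is +/-inf for an exact fit.  Returns None if the design is degenerate
    (monomorphic site).
    """
    n = g.size
    if groups is None:
        groups = [(code, y[g == code]) for code in (0, 1, 2)]
    sw = swx = swxx = swy = swxy = swyy = 0.0
    for code, yj in groups:
        nj = yj.size
        if nj == 0:
            continue
        w = 1.0 if weights_by_group is None else weights_by_group[code]
        sy = float(yj.sum())
        syy = float(np.dot(yj, yj))
        sw += w * nj
        swx += w * nj * code
        swxx += w * nj * code * code
        swy += w * sy
        swxy += w * code * sy
        swyy += w * syy
    d = sw * swxx - swx * swx
    if d <= 0.0 or n < 3:
        return None
    slope = (sw * swxy - swx * swy) / d
    intercept = (swy - slope * swx) / sw
    # Weighted residual sum of squares from the same sufficient statistics.
    sse = (
        swyy
        - 2.0 * intercept * swy
        - 2.0 * slope * swxy
        + intercept * intercept * sw
        + 2.0 * intercept * slope * swx
        + slope * slope * swxx
    )
    sse = max(sse, 0.0)
    df = n - 2
    s2 = sse / df
    var_slope = s2 * sw / d
    if var_slope <= 0.0:
        tstat = math.copysign(math.inf, slope) if slope != 0.0 else 0.0
    else:
        tstat = slope / math.sqrt(var_slope)
    return slope, tstat, df


def _slope_result(fit, label: str) -> TestResult:
    slope, tstat, df = fit
    if math.isinf(tstat):
        logger.warning("%s: perfect fit (zero residual variance); reporting p = 0", label)
        p = 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(tstat), df))
    return TestResult(
        statistic=float(tstat),
        df=float(df),
        p_value=p,
        direction=int(np.sign(slope)),
        valid=True,
    )


def weighted_association_test(sample: FemaleSample) -> TestResult:
    """Weighted least-squares association test.

    Regresses phenotype on genotype code with each individual weighted by
    the inverse empirical phenotype variance of her genotype group,
    ``w_{i|g=j} = 1 / Var^hat(y_{g=j})``.  This accommodates the variance
    inflation of heterozygotes expected under X-inactivation rather than
    assuming homoscedasticity.  The slope is tested two-sided against a t
    distribution with n - 2 df.

    Every genotype group present must have >= 2 members and strictly
    positive variance (otherwise its weight is undefined) and at least two
    distinct genotype codes must occur; violations yield ``valid=False``.
    """
    g, y = sample.genotypes, sample.phenotypes
    weights: dict[int, float] = {}
    present = 0
    for code in (0, 1, 2):
        yj = y[g == code]
        if yj.size == 0:
            continue
        present += 1
        if yj.size < 2:
            return _invalid(f"genotype group {code} has a single member")
        vj = float(np.var(yj, ddof=1))
        if vj <= 0.0:
            return _invalid(f"genotype group {code} has zero phenotype variance")
        weights[code] = 1.0 / vj
    if present < 2:
        return _invalid("monomorphic site")
    fit = _wls_stat(g, y, weights)
    if fit is None:
        return _invalid("degenerate design")
    return _slope_result(fit, "weighted_association_test")


def standard_association_test(sample: FemaleSample) -> TestResult:
    """Ordinary least-squares association test on the 0/1/2 coding.

    The conventional additive model: phenotype regressed on the female
    genotype code with no allowance for variance heterogeneity; two-sided
    t-test on the slope with n - 2 df.
    """
    g, y = sample.genotypes, sample.phenotypes
    if y.size < 3:
        return _invalid("fewer than 3 observations")
    fit = _wls_stat(g, y, None)
    if fit is None:
        return _invalid("monomorphic site")
    return _slope_result(fit, "standard_association_test")


def _clamp_p(p: float, label: str) -> float:
    if p <= 0.0 or p >= 1.0:
        logger.warning("%s: p-value %g clamped before Z transform", label, p)
    return min(max(p, _P_FLOOR), _P_CEIL)


def stouffer_combine(p1: float, p2: float, w1: float = 1.0, w2: float = 1.0) -> float:
    """Combine two p-values by the (weighted) Stouffer Z-score method.

    Each p is mapped to a Z score by ``Z = Phi^-1(1 - p)``; the combined
    statistic is ``(w1*Z1 + w2*Z2) / sqrt(w1**2 + w2**2)`` and the returned
    p-value is its upper normal tail.  Equal weights give the classical
    ``(Z1 + Z2) / sqrt(2)`` combination.  Weights must be non-negative and
    not both zero.  p-values of exactly 0 or 1 are clamped to
    [1e-300, 1 - 1e-16] with a logged warning.
    """
    if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
        raise ValueError("weights must be non-negative and not both zero")
    z1 = stats.norm.isf(_clamp_p(p1, "stouffer_combine p1"))
    z2 = stats.norm.isf(_clamp_p(p2, "stouffer_combine p2"))
    z = (w1 * z1 + w2 * z2) / math.sqrt(w1 * w1 + w2 * w2)
    return float(stats.norm.sf(z))


def combined_test(sample: FemaleSample, two_sided_variance: bool = False) -> TestResult:
    """Stouffer combination of the variance and weighted association tests.

    The two component tests are independent under the null (one examines
    dispersion of median deviations, the other group means), so their
    equal-weight Z combination is a valid test that gains power whenever
    both carry signal.  Invalidity of either component propagates.
    """
    var_res = variance_test(sample, two_sided=two_sided_variance)
    wls_res = weighted_association_test(sample)
    if not var_res.valid:
        return _invalid(f"variance component invalid: {var_res.reason}")
    if not wls_res.valid:
        return _invalid(f"weighted component invalid: {wls_res.reason}")
    p = stouffer_combine(var_res.p_value, wls_res.p_value)
    z1 = stats.norm.isf(_clamp_p(var_res.p_value, "combined_test"))
    z2 = stats.norm.isf(_clamp_p(wls_res.p_value, "combined_test"))
    z = (z1 + z2) / math.sqrt(2.0)
    return TestResult(
        statistic=float(z),
        df=None,
        p_value=p,
        direction=int(np.sign(z)),
        valid=True,
    )
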