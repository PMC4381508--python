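"""Exact test of Hardy-Weinberg equilibrium for a biallelic site.

The test conditions on the observed allele counts: given N genotyped
individuals carrying n_A copies of the rarer allele, the number of
heterozygotes n_het under HWE follows the exact distribution

    P(n_het | N, n_A) = C(N, n_aa) C(N - n_aa, n_het) 2^n_het
                        / [ C(2N, n_A) ]   (suitably normalized)

supported on n_het in {n_A mod 2, n_A mod 2 + 2, ..., min(n_A, 2N - n_A)}.
The p-value is the summed probability of all heterozygote counts no more
probable than the observed one (the standard exact conditional test, no
mid-p adjustment), as used for genotype QC in GWAS toolkits.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["hwe_exact_test"]


def _log_prob_het(n_het: np.ndarray, n_total: int, n_minor: int) -> np.ndarray:
    """Unnormalized log-probability of each heterozygote count."""
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = n_total - n_het - n_hom_minor
    return (
        n_het * np.log(2.0)
        - gammaln(n_het + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(n_hom_major + 1)
    )


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact HWE p-value from the three genotype counts.

    Parameters are the counts of the two homozygote classes (n0, n2) and
    heterozygotes (n1), in any homozygote order.  Returns 1.0 for a
    monomorphic site.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n_total = n0 + n1 + n2
    if n_total < 1:
        raise ValueError("at least one genotyped individual required")
    n_minor = min(2 * n0 + n1, 2 * n2 + n1)
    if n_minor == 0:
        return 1.0
    # n_het shares the parity of the minor-allele count and cannot exceed
    # it; since n_minor <= n_total the major-homozygote count stays >= 0.
    support = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = _log_prob_het(support, n_total, n_minor)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[support == n1]
    if observed.size != 1:
        raise ValueError(f"heterozygote count {n1} impossible for allele count {n_minor}")
    # Sum over counts no more probable than observed; the tolerance keeps
    # ties together despite floating-point rounding.
    return float(min(1.0, probs[probs <= observed[0] * (1.0 + 1e-12)].sum()))
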