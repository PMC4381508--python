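# xvartest

Variance-informed association testing for X-linked quantitative trait
loci (QTLs) in females.

## Why

Random X-inactivation silences one X copy per cell lineage, so a female
heterozygous for an X-linked QTL is a mosaic of cells expressing either
allele.  For a locus with additive effect *a* this inflates the
phenotypic variance of heterozygotes by θ(1 − θ)Δ² (Δ the gap between
the two expressed states, θ the inactivation ratio) while leaving the
mean on the additive line.  Standard association tests look only at
means and ignore — or are hurt by — this heteroscedasticity.  This
package implements tests that exploit it:

* **variance** — a one-sided Brown–Forsythe-type test that heterozygous
  females are over-dispersed relative to pooled homozygotes, using
  absolute deviations from group medians and a Welch–Satterthwaite t
  reference:
  `T = (Z̄₁ − Z̄₀/₂) / √(s₁²/n₁ + s₀/₂²/(n₀+n₂))`;
* **weighted** — weighted least squares of trait on genotype code with
  inverse group-variance weights `w = 1/V̂ⱼ`, a mean-effect test that
  absorbs the variance heterogeneity instead of assuming it away;
* **combined** — Stouffer's Z-score combination
  `Z = (Z₁ + Z₂)/√2`, `Zₖ = Φ⁻¹(1 − pₖ)` of the two tests above, which
  are independent under the null;
* **standard** — ordinary least squares on the 0/1/2 coding, for
  comparison.

It also ships a simulator of X-inactivation phenotypes (type-I error
and power studies under Hardy–Weinberg genotypes), a PLINK bed/bim/fam
reader/writer, exact-HWE genotype QC, and a chromosome-wide scan
pipeline, all female-only by design.  Intended users are statistical
geneticists running X-chromosome-wide association studies (XWAS) on
quantitative traits.

## Worked example

```python
import numpy as np
from xvartest import (FemaleSample, variance_test, weighted_association_test,
                      standard_association_test, combined_test, stouffer_combine)

# 8 females: heterozygotes {0,2,6,8}, qq {0,2}, QQ {0,4}
s = FemaleSample(np.array([1,1,1,1,0,0,2,2]),
                 np.array([0.,2,6,8,0,2,0,4]))
v = variance_test(s)
print(f"T = {v.statistic:.4f}, df = {v.df:.3f}, one-sided p = {v.p_value:.4f}")
print(f"combined p = {combined_test(s).p_value:.4f}")
print(f"stouffer(1.1e-6, 0.45) = {stouffer_combine(1.1e-6, 0.45):.2e}")
```

prints

```
T = 2.3238, df = 4.412, one-sided p = 0.0373
combined p = 0.0851
stouffer(1.1e-6, 0.45) = 2.95e-04
```

The variance statistic contrasts the mean absolute median-deviation of
heterozygotes (3.0) with the pooled homozygotes (1.5); p = 0.037 says
such over-dispersion arises by chance under equal variances about 4% of
the time.  The last line combines a variance-test p of 1.1 × 10⁻⁶ with
a weighted-test p of 0.45 — a dispersion signal invisible to mean-based
testing survives combination at 2.9 × 10⁻⁴.

Simulation scenarios:

```python
from xvartest import ScenarioSpec, run_scenario
res = run_scenario(ScenarioSpec(n=1000, maf=0.3, a=0.1, replicates=20_000, seed=1))
print({k: round(100*v, 1) for k, v in res.rejection_rates.items()})
# {'standard': 53.1, 'variance': 6.0, 'weighted': 53.4, 'combined': 36.5}
```

i.e. at n = 1000 females, MAF 0.3 and per-allele effect 0.1, the
weighted test is slightly more powerful than the standard test while
the pure variance test has little power without extra heterozygote
noise.

## Command line

```sh
xvartest simulate --config grid.tsv --out rates.tsv   # scenario grid
xvartest simulate --fixture --out panel               # tiny PLINK fixture
xvartest scan --bed chrX.bed --bim chrX.bim --fam chrX.fam \
              --pheno traits.tsv --out scan.tsv       # QC + all four tests
xvartest combine --table scan.tsv --p1-col variance_p \
                 --p2-col weighted_p --out comb.tsv   # post-hoc Stouffer
```

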