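# genohap

Combined genotype- and haplotype-based association tests for genomic
regions.

In a region-based association study it is rarely known in advance whether
the signal is carried by individual variants or by haplotypes. `genohap`
runs both a **genotype SKAT** (rare variants collapsed into a capped burden
super-variant, common variants kept as columns; linear kernel, uniform
weights) and a **haplotype SKAT** (counts of each individual's haplotypes
per frequency group, rare haplotypes pooled, most common group as
reference), and combines their p-values `p1`, `p2`:

- **MinP-val** — statistic `min(p1, p2)`; with `y_k = Φ⁻¹(1 − p_k)` and
  `q = Φ⁻¹(1 − x)`, its null p-value is `1 − BVN(q, q; ρ)` where BVN is the
  standard bivariate normal CDF and ρ the correlation between `y1` and
  `y2`.
- **SumP-val** — statistic `y1 + y2`, distributed `N(0, 2 + 2ρ)` under the
  null.

ρ is estimated as the Pearson correlation of the inverse-normal-transformed
p-values over permutations of residuals under the reduced (covariates-only)
model, and a Shapiro–Wilk gate decides whether the closed-form p-values can
be trusted or permutation p-values are required. The package also includes
the two frameworks for studying these tests: a theoretical power model
(correlated noncentral chi-squared statistic pairs) and a coalescent
case-control simulator (msprime haplotype pools, logistic disease models
over causal rare/common variants or haplotypes). See `docs/methods.md` for
the full model description.

## Worked example

Simulate a region under the "Common"-variant disease model (odds ratio 2 on
one common variant, 1.5 on half the rare variants, prevalence 1%), then run
the four tests with permutation p-values:

```python
import genohap as gh
from genohap.popgen import analyze_replicate

pool = gh.generate_pool(seed=2)            # 40,000 chromosomes, 33 sites
model = gh.select_causal(pool, "genotype", "Common", 0.5, seed=3)
sample = gh.sample_case_control(pool, model, seed=4)   # 500 cases / 500 controls
print(analyze_replicate(sample, n_permutations=1000, seed=5))
```

```
{'p_genotype_skat': 0.000999000999000999,
 'p_haplotype_skat': 0.000999000999000999,
 'p_minp': 0.000999000999000999,
 'p_sump': 0.000999000999000999}
```

All four tests reject strongly (p = 1/1001, the smallest value 1000
permutations can produce — the observed statistics beat every permuted
one). Under a null model (`scenario="null"`) the same pipeline gives
uniform p-values; the calibration suite verifies that the empirical type-I
error of all four tests over 1000 null replicates stays below 0.067, the
one-sided 99% binomial quantile at nominal 0.05.

The file-based pipeline is available as a CLI over VCF input (phased GT for
the haplotype arm), phenotype/covariate tables, and a region table with
10 kb flanks:

```sh
genohap test --vcf data.vcf --phased-vcf phased.vcf \
    --pheno pheno.tsv --covar covar.tsv --regions genes.tsv --out results.tsv
genohap simulate-theory --out theory.tsv
genohap simulate-popgen --scenario genotype:Rare:0.5 --out power.tsv
```

Per region the output reports the number of SNPs, the four p-values, ρ̂,
the normality-gate decision, and the Bonferroni threshold 0.05/#regions.

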