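# Methods

## Problem and model

`genohap` tests the joint association of all variants in a genomic region
with a phenotype by running *two* region tests — one genotype-based, one
haplotype-based — and combining their p-values. Neither test dominates: a
genotype test is stronger when single variants carry the signal, a haplotype
test when haplotypes tag an unobserved causal allele or capture cis
interactions. The combined tests hedge across both disease architectures.

### Underlying tests

Both arms are variance-component score tests (SKAT) with a linear kernel and
uniform variant weights, applied to a design matrix `X` built from the
region:

- **Genotype arm.** Minor-allele dosages for each variant; all rare variants
  (sample MAF < 1% by default) are collapsed into one burden "super-variant"
  — the per-individual count of rare minor alleles, capped at 2 — while each
  common variant keeps its own column. No frequency weighting is applied:
  beta-density weights would suppress exactly the common-variant signal the
  genotype arm is meant to catch.
- **Haplotype arm.** Haplotypes are grouped: each common haplotype
  (frequency ≥ 1%) is its own group, all rare haplotypes are pooled into
  one group. If *no* haplotype is common, three frequency bins are used
  instead (< 0.05%, 0.05–0.1%, > 0.1%, empty bins dropped; boundary values
  fall in the middle bin). The most common group is the reference and is
  omitted; `R[i, j]` counts individual *i*'s haplotypes in group *j*, so
  each row sums to 2 minus the reference-group count. Ties for "most
  common" are broken deterministically (descending total frequency, then
  lexicographic label order).

With the reduced model `Y = a + Cc + ε` fitted by least squares (Gaussian
trait) or logistic maximum likelihood (binary trait), the statistic is
`Q = ε̂ᵀ X Xᵀ ε̂ / s`, `s = 2σ̂²` (Gaussian, ML variance) or 1 (binomial). Its
null distribution is a weighted sum of 1-df chi-squares whose weights are
the eigenvalues of the projected kernel (variance-weighted for the binomial
family). The tail probability is computed by numerical inversion of the
characteristic function (Imhof's integral, `scipy.integrate.quad`), falling
back to the Liu et al. four-moment approximation when the oscillatory
quadrature returns an unusable value (non-finite, > 1, or below 1e-10, where
cancellation dominates); the result records which path was used. A design
with no variance after projection yields p = 1 with a warning rather than an
error. Missing dosages are mean-imputed per variant before testing, which
preserves the sample MAF; with missing data the super-variant can therefore
be fractional in [0, 2].

### Combination

Write `y_k = Φ⁻¹(1 − p_k)` for the two tests' p-values. Under the null each
`y_k` is standard normal, and `(y1, y2)` is modelled as bivariate normal
with correlation ρ, estimated as the Pearson correlation of the transformed
p-values over permutation replicates (500 by default). The two combined
tests are

- **SumP-val**: statistic `y1 + y2 ~ N(0, 2 + 2ρ)` under the null; p-value
  is its upper tail (Stouffer-type combination corrected for dependence).
- **MinP-val**: statistic `x = min(p1, p2)`; with `q = Φ⁻¹(1 − x)` its null
  CDF is `1 − BVN(q, q; ρ)`, where BVN is the standard bivariate normal CDF
  (computed from Owen's T function, vectorized and accurate well beyond the
  1e-7 requirement).

p-values entering the transform are clamped to `[1e-12, 1 − 1e-12]` so
permutation p-values of 0 or 1 stay finite; ρ̂ is clamped to `[−0.999,
0.999]` (negative estimates are sampling noise but remain valid in both
formulas). For fixed p-values, MinP-val is bounded between `x` (ρ → 1) and
`2x − x²` (ρ = 0) and is non-increasing in ρ.

The bivariate-normal model is an approximation: the two statistics share
the same residual vector, so their joint upper tail can be heavier than any
Gaussian copula with the same margins allows. Because the margins remain
exactly normal, a marginal test cannot detect this, and the theoretical
SumP-val p-value can be mildly anti-conservative when the two designs
overlap pathologically (observed ≈ 0.068 at nominal 0.05 on an artificial
fixture whose haplotype design was a noisy copy of the genotype columns).
On realistic region designs — collapsed genotypes and haplotype-group
counts derived from one simulated region — all four tests calibrate inside
the 99% binomial band.

The bivariate-normal assumption is checked with a Shapiro–Wilk gate on the
transformed permutation replicates: per-margin tests with a Bonferroni
factor of 2, a transparent and conservative proxy for the multivariate
version. If the gate rejects at the genome-wide level (0.05 / #regions),
combined p-values are taken from permutations instead of the closed forms.

### Permutation engine

Null phenotype replicates use permutation of residuals under the reduced
model (Freedman–Lane): `Y* = μ̂ + π(ε̂)`, preserving the phenotype–covariate
relationship. The null fit is reused — covariate effects are not
re-estimated per replicate — and both statistics are recomputed on each
`Y*`. For a binary phenotype without covariates this is plain phenotype
permutation, which is exact. Replicate `r` is reproducible in isolation from
`(seed, r)` via a counter-based seed sequence. Empirical p-values use the
add-one convention `(#{replicate ≥ observed} + 1)/(B + 1)` with ties counted
toward rejection; this keeps permutation p-values strictly positive before
the inverse-normal transform. Per-replicate p-values for ρ̂ are analytic
mixture tails in the per-region pipeline; large calibration studies use
within-set rank p-values instead — a monotone transform of the same
statistics, so the Pearson correlation of the transforms is essentially
unchanged.

## Theoretical power model

The two statistics are modelled as 1-df chi-squares, central under the null
and noncentral with NCPs `a` (stronger test) and `b = a/2` by default under
the alternative. Dependence is induced by squaring a bivariate normal pair
with means `(√a, √b)`, unit variances and correlation ρ — the square-root
means make the marginals exactly noncentral chi-squared with NCPs `a` and
`b`, consistent with the anchor that NCP 10.5 gives 90% power at α = 0.05.
Power of the combined tests is the rejection share over 500,000 simulated
pairs per grid cell (closed-form power for the underlying tests); MinP-val
rejection uses the exact critical value `x*` solving
`1 − BVN(q*, q*; ρ) = α`.

One subtlety is worth recording: squaring folds away the sign of the
underlying normals, so under the *null* the inverse-normal transforms of the
two-sided chi-squared p-values are less correlated than the generating ρ.
Supplying the generating ρ to the combined tests (the model's construction)
therefore makes them conservative under the null for ρ > 0 (e.g. size
≈ 0.038 at ρ = 0.3, α = 0.05); at ρ = 0 the size is exact. Under the
alternative the means are positive and folding is negligible, so the power
surfaces are unaffected in substance. The default NCP grid is a ∈ {1,…,20}
with ρ ∈ {0, 0.3, 0.6, 0.9}; grids are configurable since no canonical axis
exists. On this grid the maximum MinP-val gain over the better underlying
test at ρ = 0 computes to ≈ 2.8 percentage points (peak near a = 8).

## Population-genetics simulator

Haplotype pools emulate large population samples over a short region:
40,000 chromosomes, ≈ 33 segregating sites, generated with msprime (neutral
coalescent over haploid lineages, binary mutation model, N = 10,000,
10 kb). The mutation rate starts slightly above the target and is raised and
re-run if too few segregating sites arise; surplus sites are down-sampled
uniformly, which preserves the frequency spectrum. The pools exhibit a
neutral-like spectrum — a majority of sites below 1% frequency at this pool
size — and coalescent LD. They are *not* calibrated to any demographic
model; absolute power numbers from this generator are not comparable to
simulations under a fitted human demography, and the harness is used for
calibration (type-I error, p-value uniformity) and qualitative power
ordering only. Multiplicities of distinct haplotypes are found by packing
each ≤ 64-site haplotype into one integer key.

Disease models: baseline prevalence 1%; causal rare items are a uniformly
chosen ⌈proportion · #rare⌉ subset (proportions 0.5 / 0.2 / 0.1) of items
with *pool* frequency < 1% (the analysis-side collapsing threshold is a
separate, sample-frequency parameter); scenarios attach odds ratios
(rare, common) = (4, —) "Rare", (3, 1.2) "Both", (1.5, 2) "Common", with one
uniformly chosen common causal item where required. Log-odds accumulate
additively over causal dosages (genotype basis) or over the two haplotypes'
causal-set memberships (haplotype basis). Haplotype identity is the full
site sequence; the analysis side is blind to causal status (the common
causal variant is not excluded from collapsing decisions). Sampling draws
haplotype pairs with replacement proportional to pool counts and keeps
Bernoulli(P(A)) phenotypes until the 500/500 case-control quotas fill
(abort with diagnostics after 1e8 draws).

The study harness runs the four tests with permutation p-values per
replicate: the two SKAT statistics are referred to their own permutation
distributions, and the combined statistics (min of rank p-values;
sum of inverse-normal-transformed rank p-values) are referred to theirs —
so no ρ estimate is needed on the permutation branch. Desk-scale defaults
are 100 replicates × 200 permutations per scenario (the full 1000 × 1000
design is behind a flag); the calibration suite uses 1000 null replicates
× 200 permutations at the default pool size, one fresh pool per replicate.
The one-sided 99% binomial quantile for 1000 replicates at nominal 0.05 is
0.067, the inflation flag used for null rows.

## I/O and pipeline

VCF in/out goes through pysam; coordinates are 1-based inclusive on the
external surface. Genotype columns are oriented to the sample minor allele;
haplotype reading requires phased GT fields and fails naming the first
offending sample and site. Regions are extended by a 10 kb flank on both
sides. Variant-to-region mapping resolves multi-gene hits by the functional
category priority (coding > intronic > 5'UTR > 3'UTR) when the region table
carries a category column; without one, the nearest gene body wins (with a
warning), since category information is not derivable from the inputs.
Variants outside every flank-extended gene are grouped into inter-gene
blocks named after their flanking genes; every variant is assigned to
exactly one region. Per-region failures in the genome-wide runner are
logged and reported as status rows, never aborting the run.

## Numerical choices and limitations

- Mixture-tail inversion: `quad` with 500 subdivision limit, absolute
  tolerance 1e-11; single-eigenvalue mixtures short-circuit to the exact
  scaled chi-squared. Eigenvalues below `max · 1e-12` are dropped.
- `minp_critical_value` brackets its root in `[α/2, α]`, the exact range of
  the null min-p quantile over ρ ∈ [0, 1].
- Rank-deficient covariate designs are rejected naming the collinear
  columns; degenerate regions (one distinct haplotype, or a grouping that
  collapses to one group) are errors, not silent skips.
- The permutation scheme for a binomial fit *with* covariates permutes
  response-scale residuals without refitting — an approximation mirroring
  the Gaussian scheme; exact only in the no-covariate case.
- The fallback haplotype bins (0.05%, 0.1%) are evaluated on sample
  frequencies, which is coarse at typical sample sizes (2n chromosomes);
  the grouping records which scheme was used.
- Passing calibration on the coalescent generator shows correct test
  behaviour under neutral-spectrum LD; it does not certify power under real
  human demography, genotyping error, or statistically phased (rather than
  known) haplotypes.
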