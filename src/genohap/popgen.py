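"""Case-control simulation over coalescent haplotype pools.

A haplotype pool is a large set of chromosomes (default 40,000) over a short
region with roughly 30-38 segregating sites, generated with msprime (neutral
coalescent, binary mutations) so that site frequencies follow a neutral
spectrum — a majority of sites rare (derived frequency < 1%) — and sites
carry coalescent linkage disequilibrium.  Disease models assign odds ratios
to causal rare variants/haplotypes (pool frequency < 1%) and optionally one
common causal variant/haplotype, with baseline prevalence 1%:

  genotype basis:  logit P(A) = logit(0.01) + sum_causal g_l * log(OR_l)
  haplotype basis: logit P(A) = logit(0.01)
                                + sum_{i=1,2} [1{h_i in H_r} log d_r
                                               + 1{h_i in H_c} log d_c]

Case-control samples (default 500/500) are drawn by repeatedly sampling two
haplotypes from the pool, computing P(A), and assigning the phenotype as
Bernoulli(P(A)) until both quotas fill.  The study harness runs the four
tests (genotype SKAT, haplotype SKAT, MinP-val, SumP-val) with permutation
p-values on replicate datasets and reports rejection shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    HaplotypePairSet,
    RegionGenotypes,
    build_haplotype_matrix,
    collapse_rare_variants,
    group_haplotypes,
)

__all__ = [
    "HaplotypePool",
    "DiseaseModel",
    "CaseControlSample",
    "generate_pool",
    "select_causal",
    "disease_probability_genotype",
    "disease_probability_haplotype",
    "sample_case_control",
    "analyze_replicate",
    "run_power_study",
    "binomial_type1_bound",
    "ODDS_RATIO_TABLE",
]

PREVALENCE = 0.01
# (rare OR, common OR) per disease scenario
ODDS_RATIO_TABLE = {"Rare": (4.0, None), "Both": (3.0, 1.2), "Common": (1.5, 2.0)}


@dataclass
class HaplotypePool:
    """Distinct haplotypes over L segregating sites with pool multiplicities."""

    haplotypes: np.ndarray  # K x L uint8, distinct rows
    counts: np.ndarray  # K multiplicities summing to pool_size
    site_freqs: np.ndarray  # derived allele frequency per site

    def __post_init__(self) -> None:
        if (self.counts < 1).any():
            raise ValueError("all multiplicities must be >= 1")
        if ((self.site_freqs <= 0) | (self.site_freqs >= 1)).any():
            raise ValueError("every site must be segregating in the pool")

    @property
    def pool_size(self) -> int:
        return int(self.counts.sum())

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def hap_freqs(self) -> np.ndarray:
        return self.counts / self.pool_size


@dataclass
class DiseaseModel:
    """Phenotype-generating model (Eq.-style log-odds accumulation)."""

    basis: str  # "genotype" | "haplotype"
    scenario: str  # "Rare" | "Both" | "Common" | "null"
    causal_rare: np.ndarray  # variant indices (genotype) or haplotype indices
    causal_common: int | None
    or_rare: float | None
    or_common: float | None
    baseline_prevalence: float = PREVALENCE


@dataclass
class CaseControlSample:
    genotypes: RegionGenotypes
    haplotype_pairs: HaplotypePairSet
    phenotype: np.ndarray
    hap_indices: np.ndarray  # n x 2 indices into the pool's distinct haplotypes
    derived_dosages: np.ndarray  # n x L in derived-allele coding (= h1 + h2)
    flipped: np.ndarray  # sites re-oriented to the minor allele


def _seed_int(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _unique_rows(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct rows of a binary matrix with counts, in row-sorted order.

    Rows with up to 64 sites are packed into one integer key, which is much
    faster than a lexicographic row sort on large pools.
    """
    if H.shape[1] <= 64:
        pb = np.packbits(H, axis=1)
        padded = np.zeros((H.shape[0], 8), dtype=np.uint8)
        padded[:, : pb.shape[1]] = pb
        codes = padded.view(np.uint64).ravel()
        _, first, counts = np.unique(codes, return_index=True, return_counts=True)
        return H[first], counts
    return np.unique(H, axis=0, return_counts=True)


def generate_pool(
    L_target: int = 33,
    pool_size: int = 40_000,
    seed: int | None = None,
    initial_rate: float = 2.0e-8,
) -> HaplotypePool:
    """Coalescent haplotype pool with approximately ``L_target`` sites.

    Simulates a neutral coalescent over ``pool_size`` haploid lineages
    (msprime) with binary mutations; the mutation rate starts at a value
    calibrated to overshoot the target slightly and is increased and retried
    if too few segregating sites arise; surplus sites are down-sampled
    uniformly so the spectrum is preserved.
    """
    if L_target < 5:
        raise ValueError("L_target must be >= 5")
    rng = np.random.default_rng(seed)
    ts = msprime.sim_ancestry(
        samples=pool_size,
        ploidy=1,
        population_size=10_000,
        sequence_length=10_000,
        random_seed=_seed_int(rng),
    )
    rate = initial_rate * (L_target / 33.0)
    for _ in range(10):
        mts = msprime.sim_mutations(
            ts, rate=rate, random_seed=_seed_int(rng),
            model=msprime.BinaryMutationModel(),
        )
        G = mts.genotype_matrix()  # sites x chromosomes, alleles 0/1
        freq = G.mean(axis=1)
        keep = (freq > 0) & (freq < 1)
        if keep.sum() >= L_target:
            break
        rate *= 1.8
    else:
        raise RuntimeError("could not reach the target number of segregating sites")
    idx = np.where(keep)[0]
    if idx.size > L_target:
        idx = np.sort(rng.choice(idx, size=L_target, replace=False))
    H = np.ascontiguousarray(G[idx].T.astype(np.uint8))  # chromosomes x sites
    distinct, counts = _unique_rows(H)
    site_freqs = (distinct * counts[:, None]).sum(axis=0) / pool_size
    return HaplotypePool(distinct, counts, site_freqs)


def select_causal(
    pool: HaplotypePool,
    basis: str,
    scenario: str,
    proportion: float,
    seed: int | None = None,
) -> DiseaseModel:
    """Choose causal rare items (ceil(proportion * #rare), pool frequency < 1%)
    and, for "Both"/"Common", one uniformly chosen common item; attach the
    scenario's odds ratios."""
    if scenario == "null":
        return DiseaseModel(basis, "null", np.empty(0, dtype=int), None, None, None)
    if scenario not in ODDS_RATIO_TABLE:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    if basis == "genotype":
        freqs = pool.site_freqs
    elif basis == "haplotype":
        freqs = pool.hap_freqs
    else:
        raise ValueError(f"unknown basis {basis!r}")
    rare_idx = np.where(freqs < 0.01)[0]
    common_idx = np.where(freqs >= 0.01)[0]
    if rare_idx.size == 0:
        raise ValueError("no rare items eligible as causal")
    k = math.ceil(proportion * rare_idx.size)
    causal_rare = np.sort(rng.choice(rare_idx, size=k, replace=False))
    or_rare, or_common = ODDS_RATIO_TABLE[scenario]
    causal_common = None
    if or_common is not None:
        if common_idx.size == 0:
            raise ValueError(f"scenario {scenario!r} requires a common causal item but none is eligible")
        causal_common = int(rng.choice(common_idx))
    return DiseaseModel(basis, scenario, causal_rare, causal_common, or_rare, or_common)


def disease_probability_genotype(g: np.ndarray, model: DiseaseModel) -> np.ndarray:
    """P(A) for derived-allele dosage vector(s) g under a genotype-basis model."""
    if model.basis != "genotype":
        raise ValueError("model basis must be 'genotype'")
    g = np.atleast_2d(np.asarray(g, dtype=float))
    logit = np.full(g.shape[0], np.log(model.baseline_prevalence / (1 - model.baseline_prevalence)))
    if model.or_rare is not None and model.causal_rare.size:
        logit = logit + g[:, model.causal_rare].sum(axis=1) * np.log(model.or_rare)
    if model.causal_common is not None:
        logit = logit + g[:, model.causal_common] * np.log(model.or_common)
    p = 1.0 / (1.0 + np.exp(-logit))
    return p if p.size > 1 else float(p[0])


def disease_probability_haplotype(h1, h2, model: DiseaseModel) -> np.ndarray:
    """P(A) for pool-haplotype indices (h1, h2) under a haplotype-basis model."""
    if model.basis != "haplotype":
        raise ValueError("model basis must be 'haplotype'")
    h1 = np.atleast_1d(np.asarray(h1, dtype=int))
    h2 = np.atleast_1d(np.asarray(h2, dtype=int))
    logit = np.full(h1.shape[0], np.log(model.baseline_prevalence / (1 - model.baseline_prevalence)))
    if model.or_rare is not None and model.causal_rare.size:
        rare_set = np.isin(h1, model.causal_rare).astype(float) + np.isin(h2, model.causal_rare)
        logit = logit + rare_set * np.log(model.or_rare)
    if model.causal_common is not None:
        common_count = (h1 == model.causal_common).astype(float) + (h2 == model.causal_common)
        logit = logit + common_count * np.log(model.or_common)
    p = 1.0 / (1.0 + np.exp(-logit))
    return p if p.size > 1 else float(p[0])


def _hap_label(h: np.ndarray) -> str:
    return "".join("1" if x else "0" for x in h)


def sample_case_control(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_cases: int = 500,
    n_controls: int = 500,
    seed: int | None = None,
    max_draws: int = 10**8,
) -> CaseControlSample:
    """Sample individuals (two pool haplotypes each) with phenotype
    Bernoulli(P(A)) until both case and control quotas are filled.  Cases come
    first in the returned arrays."""
    rng = np.random.default_rng(seed)
    w = pool.hap_freqs
    K = len(w)
    kept_idx: list[np.ndarray] = []
    kept_phen: list[np.ndarray] = []
    got_cases = got_controls = 0
    drawn = 0
    batch = max(4096, 4 * (n_cases + n_controls))
    while got_cases < n_cases or got_controls < n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control quotas unreachable after {drawn} draws "
                f"(cases {got_cases}/{n_cases}, controls {got_controls}/{n_controls})"
            )
        i1 = rng.choice(K, size=batch, p=w)
        i2 = rng.choice(K, size=batch, p=w)
        drawn += batch
        if model.basis == "genotype" and model.scenario != "null":
            g = pool.haplotypes[i1].astype(float) + pool.haplotypes[i2]
            pa = np.atleast_1d(disease_probability_genotype(g, model))
        elif model.basis == "haplotype" and model.scenario != "null":
            pa = np.atleast_1d(disease_probability_haplotype(i1, i2, model))
        else:
            pa = np.full(batch, model.baseline_prevalence)
        phen = (rng.random(batch) < pa).astype(float)
        need_case = n_cases - got_cases
        need_ctrl = n_controls - got_controls
        case_sel = np.where(phen == 1)[0][:need_case]
        ctrl_sel = np.where(phen == 0)[0][:need_ctrl]
        sel = np.concatenate([case_sel, ctrl_sel])
        kept_idx.append(np.column_stack([i1[sel], i2[sel]]))
        kept_phen.append(phen[sel])
        got_cases += case_sel.size
        got_controls += ctrl_sel.size
    idx = np.concatenate(kept_idx)
    phen = np.concatenate(kept_phen)
    order = np.argsort(-phen, kind="stable")  # cases first
    idx, phen = idx[order], phen[order]

    derived = pool.haplotypes[idx[:, 0]].astype(float) + pool.haplotypes[idx[:, 1]]
    sample_freq = derived.mean(axis=0) / 2.0
    flipped = sample_freq > 0.5
    dosages = derived.copy()
    dosages[:, flipped] = 2.0 - dosages[:, flipped]
    genotypes = RegionGenotypes(
        dosages, [f"site{j}" for j in range(pool.n_sites)]
    )
    labels = [_hap_label(h) for h in pool.haplotypes]
    pairs = [(labels[i], labels[j]) for i, j in idx]
    hap_set = HaplotypePairSet.from_pairs(pairs)
    return CaseControlSample(
        genotypes=genotypes,
        haplotype_pairs=hap_set,
        phenotype=phen,
        hap_indices=idx,
        derived_dosages=derived,
        flipped=flipped,
    )


# ---------------------------------------------------------------------------
# study harness
# ---------------------------------------------------------------------------


def binomial_type1_bound(n_replicates: int = 1000, alpha: float = 0.05, quantile: float = 0.99) -> float:
    """One-sided upper quantile of the empirical type-I-error estimate under
    no inflation: Binomial(n_replicates, alpha) quantile divided by n."""
    return float(stats.binom.ppf(quantile, n_replicates, alpha) / n_replicates)


def _perm_rank_sf(stats_perm: np.ndarray, values: np.ndarray) -> np.ndarray:
    """(#{perm >= value} + 1) / (B + 1) for each value, via sorted search."""
    s = np.sort(stats_perm)
    ge = stats_perm.size - np.searchsorted(s, values, side="left")
    return (ge + 1) / (stats_perm.size + 1)


def analyze_replicate(
    sample: CaseControlSample,
    n_permutations: int = 1000,
    seed: int | None = None,
    maf_threshold: float = 0.01,
    hap_freq_threshold: float = 0.01,
) -> dict[str, float]:
    """Permutation p-values of the four tests on one case-control replicate.

    The dichotomous phenotype has no covariates, so plain phenotype
    permutation (exact) is used.  MinP-val and SumP-val statistics are built
    from the permutation-rank p-values of the two underlying statistics and
    referred to their own permutation distributions.
    """
    rng = np.random.default_rng(seed)
    y = sample.phenotype
    n = y.size
    Xg = collapse_rare_variants(sample.genotypes, maf_threshold).matrix
    grouping = group_haplotypes(sample.haplotype_pairs, hap_freq_threshold)
    Xh = build_haplotype_matrix(sample.haplotype_pairs, grouping).matrix
    eps = y - y.mean()
    ug = Xg.T @ eps
    uh = Xh.T @ eps
    Qg, Qh = float(ug @ ug), float(uh @ uh)
    B = n_permutations
    # B permutations of the centered phenotype at once
    keys = rng.random((B, n))
    perm = np.argsort(keys, axis=1)
    E = eps[perm]  # B x n
    Sg = np.einsum("bn,nl->bl", E, Xg)
    Sh = np.einsum("bn,nl->bl", E, Xh)
    Sg = np.einsum("bl,bl->b", Sg, Sg)
    Sh = np.einsum("bl,bl->b", Sh, Sh)
    p_g = _perm_rank_sf(Sg, np.array([Qg]))[0]
    p_h = _perm_rank_sf(Sh, np.array([Qh]))[0]
    # combined statistics on the permutation-rank p-value scale
    r_g_obs, r_h_obs = p_g, p_h
    r_g = _perm_rank_sf(Sg, Sg)
    r_h = _perm_rank_sf(Sh, Sh)
    m_obs = min(r_g_obs, r_h_obs)
    m_perm = np.minimum(r_g, r_h)
    p_minp = (np.sum(m_perm <= m_obs) + 1) / (B + 1)
    z = stats.norm.isf
    s_obs = z(r_g_obs) + z(r_h_obs)
    s_perm = z(r_g) + z(r_h)
    p_sump = (np.sum(s_perm >= s_obs) + 1) / (B + 1)
    return {
        "p_genotype_skat": p_g,
        "p_haplotype_skat": p_h,
        "p_minp": p_minp,
        "p_sump": p_sump,
    }


def run_power_study(
    scenarios,
    n_replicates: int = 100,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n_cases: int = 500,
    n_controls: int = 500,
    pool_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Power / type-I error of the four tests over replicate datasets.

    ``scenarios`` is a sequence of (basis, scenario, proportion) triples;
    scenario "null" means no causal items (type-I error row, flagged against
    the one-sided 99% binomial bound).  One fresh haplotype pool is generated
    per replicate.
    """
    pool_kwargs = pool_kwargs or {}
    rows = []
    bound = binomial_type1_bound(n_replicates, alpha)
    for s_idx, (basis, scenario, proportion) in enumerate(scenarios):
        rej = {k: 0 for k in ("p_genotype_skat", "p_haplotype_skat", "p_minp", "p_sump")}
        for r in range(n_replicates):
            ss = np.random.SeedSequence((seed, s_idx, r))
            s1, s2, s3, s4 = ss.generate_state(4) % (2**31 - 1) + 1
            pool = generate_pool(seed=int(s1), **pool_kwargs)
            model = select_causal(pool, basis, scenario, proportion, seed=int(s2))
            sample = sample_case_control(
                pool, model, n_cases=n_cases, n_controls=n_controls, seed=int(s3)
            )
            pv = analyze_replicate(sample, n_permutations=n_permutations, seed=int(s4))
            for k in rej:
                rej[k] += pv[k] <= alpha
        for test, cnt in rej.items():
            rate = cnt / n_replicates
            rows.append(
                {
                    "basis": basis,
                    "scenario": scenario,
                    "proportion": proportion,
                    "test": test.removeprefix("p_"),
                    "rate": rate,
                    "n_replicates": n_replicates,
                    "n_permutations": n_permutations,
                    "alpha": alpha,
                    "binomial_bound": bound,
                    "within_bound": bool(rate <= bound) if scenario == "null" else None,
                }
            )
    return pd.DataFrame(rows)
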