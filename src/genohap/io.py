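"""Readers, writers, region mapping and the per-region analysis pipeline.

External surface conventions: VCF coordinates are 1-based inclusive; region
tables carry 1-based inclusive (name, chrom, start, end) rows and are
extended by a flank (default 10 kb) on both sides before variant lookup;
phenotype/covariate tables are delimited text with a header and a sample-id
column.  Genotypes are oriented to the minor allele on the analyzed sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .association import (
    HaplotypePairSet,
    RegionGenotypes,
    build_haplotype_matrix,
    collapse_rare_variants,
    fit_null_model,
    group_haplotypes,
    skat_test,
)
from .combine import (
    PValuePair,
    estimate_correlation,
    minp_pvalue,
    normality_gate,
    sump_pvalue,
    sump_statistic,
)
from .permutation import PermutationPlan, run_permutations

logger = logging.getLogger("genohap")

__all__ = [
    "RegionDefinition",
    "read_genotypes",
    "read_haplotypes",
    "read_region_table",
    "read_sample_table",
    "map_variants_to_regions",
    "write_sample_vcf",
    "run_region_test",
]

DEFAULT_FLANK = 10_000
_CATEGORY_PRIORITY = {"coding": 0, "intronic": 1, "5utr": 2, "3utr": 3}


@dataclass
class RegionDefinition:
    name: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    flank: int = DEFAULT_FLANK
    category: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")
        if self.flank < 0:
            raise ValueError("flank must be nonnegative")

    @property
    def query_start(self) -> int:
        return max(1, self.start - self.flank)

    @property
    def query_end(self) -> int:
        return self.end + self.flank


def _iter_region_records(vcf_path: str, region: RegionDefinition):
    vf = pysam.VariantFile(vcf_path)
    for rec in vf:
        if rec.chrom != region.chromosome:
            continue
        if not region.query_start <= rec.pos <= region.query_end:
            continue
        if rec.alts is None or len(rec.alts) != 1:
            warnings.warn(f"skipping non-biallelic record at {rec.chrom}:{rec.pos}")
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            warnings.warn(f"skipping non-SNP record at {rec.chrom}:{rec.pos}")
            continue
        yield rec


def read_genotypes(vcf_path: str, region: RegionDefinition) -> RegionGenotypes:
    """Minor-allele dosage matrix for the flank-extended region.

    ALT dosages are flipped to REF counts at sites where the ALT allele is
    the major allele, so every column counts the sample minor allele.
    Missing genotypes stay missing and are excluded from the MAF denominator.
    """
    cols, ids = [], []
    samples = None
    for rec in _iter_region_records(vcf_path, region):
        gts = []
        for s in rec.samples.values():
            alleles = s["GT"]
            if alleles is None or any(a is None for a in alleles):
                gts.append(np.nan)
            else:
                gts.append(float(sum(alleles)))
        if samples is None:
            samples = list(rec.samples)
        col = np.asarray(gts)
        alt_freq = np.nanmean(col) / 2.0
        if alt_freq > 0.5:
            col = 2.0 - col
        cols.append(col)
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
    if not cols:
        raise ValueError(
            f"no biallelic SNPs in {region.chromosome}:"
            f"{region.query_start}-{region.query_end} ({region.name})"
        )
    return RegionGenotypes(np.column_stack(cols), ids)


def read_haplotypes(phased_vcf_path: str, region: RegionDefinition) -> HaplotypePairSet:
    """Per-sample ordered haplotype allele strings over the region's sites.

    Every genotype must be phased ("|"); an unphased record raises naming the
    sample and site.
    """
    h1: dict[str, list[str]] = {}
    h2: dict[str, list[str]] = {}
    any_site = False
    for rec in _iter_region_records(phased_vcf_path, region):
        any_site = True
        for name, s in rec.samples.items():
            alleles = s["GT"]
            if alleles is None or any(a is None for a in alleles):
                raise ValueError(f"missing genotype for sample {name} at {rec.chrom}:{rec.pos}")
            if len(alleles) == 2 and not s.phased:
                raise ValueError(f"unphased genotype for sample {name} at {rec.chrom}:{rec.pos}")
            h1.setdefault(name, []).append(str(alleles[0]))
            h2.setdefault(name, []).append(str(alleles[1]))
    if not any_site:
        raise ValueError(
            f"no biallelic SNPs in {region.chromosome}:"
            f"{region.query_start}-{region.query_end} ({region.name})"
        )
    pairs = [("".join(h1[s]), "".join(h2[s])) for s in h1]
    return HaplotypePairSet.from_pairs(pairs)


def read_region_table(path: str, flank: int = DEFAULT_FLANK) -> list[RegionDefinition]:
    """Delimited region table with columns name, chrom, start, end
    [, category]; coordinates 1-based inclusive."""
    df = pd.read_csv(path, sep=None, engine="python")
    regions = []
    has_cat = "category" in df.columns
    for _, row in df.iterrows():
        regions.append(
            RegionDefinition(
                name=str(row["name"]),
                chromosome=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                flank=flank,
                category=str(row["category"]).lower() if has_cat else None,
            )
        )
    return regions


def read_sample_table(pheno_path: str, covar_path: str | None = None):
    """Phenotype (id, phenotype) and optional covariate table keyed by id.

    Returns (ids, phenotype vector, covariate matrix or None); samples with
    missing phenotype are dropped.
    """
    ph = pd.read_csv(pheno_path, sep=None, engine="python")
    id_col, ph_col = ph.columns[0], ph.columns[1]
    if ph[id_col].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    ph = ph.dropna(subset=[ph_col])
    if covar_path is not None:
        cv = pd.read_csv(covar_path, sep=None, engine="python")
        merged = ph.merge(cv, left_on=id_col, right_on=cv.columns[0], how="inner")
        C = merged[cv.columns[1:]].to_numpy(dtype=float)
        return merged[id_col].astype(str).tolist(), merged[ph_col].to_numpy(dtype=float), C
    return ph[id_col].astype(str).tolist(), ph[ph_col].to_numpy(dtype=float), None


def map_variants_to_regions(
    variants: pd.DataFrame, regions: list[RegionDefinition]
) -> pd.Series:
    """Assign each variant (columns chrom, pos) to exactly one region.

    Variants within one flank-extended gene go to that gene; multi-gene hits
    are resolved by the category priority (coding > intronic > 5'UTR > 3'UTR)
    when categories are present, otherwise by nearest gene body (with a
    warning).  Unassigned variants are grouped into inter-gene blocks named
    after the flanking genes.
    """
    have_cats = all(r.category for r in regions)
    if not have_cats and any(
        len([r for r in regions if r.chromosome == c]) > 1 for c in {r.chromosome for r in regions}
    ):
        warnings.warn(
            "no category column: multi-gene hits resolved by nearest gene body"
        )
    by_chrom: dict[str, list[RegionDefinition]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)
    names = []
    for _, row in variants.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        cands = [
            r for r in by_chrom.get(chrom, []) if r.query_start <= pos <= r.query_end
        ]
        if len(cands) == 1:
            names.append(cands[0].name)
        elif len(cands) > 1:
            if have_cats:
                cands.sort(
                    key=lambda r: (
                        _CATEGORY_PRIORITY.get(r.category, 99),
                        _body_distance(r, pos),
                        r.start,
                    )
                )
            else:
                cands.sort(key=lambda r: (_body_distance(r, pos), r.start))
            names.append(cands[0].name)
        else:
            left = [r for r in by_chrom.get(chrom, []) if r.end < pos]
            right = [r for r in by_chrom.get(chrom, []) if r.start > pos]
            lname = max(left, key=lambda r: r.end).name if left else f"{chrom}_start"
            rname = min(right, key=lambda r: r.start).name if right else f"{chrom}_end"
            names.append(f"{lname}|{rname}")
    return pd.Series(names, index=variants.index, name="region")


def _body_distance(r: RegionDefinition, pos: int) -> int:
    if r.start <= pos <= r.end:
        return 0
    return min(abs(pos - r.start), abs(pos - r.end))


def write_sample_vcf(sample, path: str, chrom: str = "1", start_pos: int = 1_000_000) -> None:
    """Write a simulated case-control sample as a phased uncompressed VCF.

    Sites are placed at consecutive positions from ``start_pos``; alleles are
    A (ancestral) / T (derived).  The file round-trips through
    ``read_genotypes`` / ``read_haplotypes``.
    """
    n = sample.phenotype.size
    header = pysam.VariantHeader()
    header.add_line("##source=genohap-popgen")
    header.contigs.add(chrom)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for i in range(n):
        header.add_sample(f"S{i:05d}")
    hap = sample.derived_dosages  # only used for shape
    with pysam.VariantFile(path, "w", header=header) as out:
        L = hap.shape[1]
        # per-site haplotype alleles come from the pool haplotype pair
        from_pool = sample.haplotype_pairs.pairs
        for j in range(L):
            rec = out.new_record(
                contig=chrom, start=start_pos + j - 1, alleles=("A", "T"), id=f"site{j}"
            )
            rec.stop = start_pos + j
            for i in range(n):
                a1 = int(from_pool[i][0][j])
                a2 = int(from_pool[i][1][j])
                rec.samples[i]["GT"] = (a1, a2)
                rec.samples[i].phased = True
            out.write(rec)


def write_phenotype_table(sample, path: str) -> None:
    n = sample.phenotype.size
    pd.DataFrame(
        {"id": [f"S{i:05d}" for i in range(n)], "phenotype": sample.phenotype.astype(int)}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_region_test(
    vcf_path: str,
    phased_vcf_path: str,
    regions: list[RegionDefinition],
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str | None = None,
    maf_threshold: float = 0.01,
    hap_freq_threshold: float = 0.01,
    perms_rho: int = 500,
    perms_empirical: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    pvalue_source: str | None = None,
) -> pd.DataFrame:
    """Full per-region pipeline over a region table.

    Per region: read genotypes and phased haplotypes -> collapse rare
    variants -> group haplotypes -> fit the reduced (covariates-only) model
    -> genotype and haplotype SKAT -> permutation-based rho -> normality gate
    -> MinP-val / SumP-val.  Failures are logged and emitted as status rows.
    The Bonferroni threshold 0.05 / #regions governs the gate level and is
    attached to every row.
    """
    y = np.asarray(phenotype, dtype=float)
    if family is None:
        family = "binomial" if np.isin(y, (0.0, 1.0)).all() else "gaussian"
    alpha_gw = 0.05 / len(regions)
    fit = fit_null_model(y, covariates, family)
    rows = []
    for k, region in enumerate(regions):
        try:
            rows.append(
                _one_region(
                    region, vcf_path, phased_vcf_path, fit,
                    maf_threshold, hap_freq_threshold,
                    perms_rho, perms_empirical, alpha_gw,
                    seed=int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % (2**31)),
                    pvalue_source=pvalue_source,
                )
            )
        except Exception as exc:  # keep the genome-wide run alive
            logger.warning("region %s failed: %s", region.name, exc)
            rows.append({"region": region.name, "status": f"failed: {exc}"})
    df = pd.DataFrame(rows)
    df.attrs["bonferroni_threshold"] = alpha_gw
    return df


def _one_region(
    region, vcf_path, phased_vcf_path, fit,
    maf_threshold, hap_freq_threshold, perms_rho, perms_empirical, alpha_gw,
    seed, pvalue_source,
):
    G = read_genotypes(vcf_path, region)
    H = read_haplotypes(phased_vcf_path, region)
    Xg = collapse_rare_variants(G, maf_threshold).matrix
    grouping = group_haplotypes(H, hap_freq_threshold)
    Xh = build_haplotype_matrix(H, grouping).matrix
    res_g = skat_test(Xg, fit)
    res_h = skat_test(Xh, fit)
    plan = PermutationPlan(perms_rho, seed)
    reps = run_permutations(Xg, Xh, fit, plan, pvalue_mode="analytic")
    rho = estimate_correlation(reps.pairs())
    from scipy import stats as _st

    yvals = _st.norm.isf(np.clip(reps.pairs(), 1e-12, 1 - 1e-12))
    source, gate_p = normality_gate(yvals, alpha_gw)
    if pvalue_source is not None:
        source = pvalue_source
    pair = PValuePair(res_g.p_value, res_h.p_value)
    if source == "theoretical":
        p_minp = minp_pvalue(pair, rho)
        p_sump = sump_pvalue(pair, rho)
    else:
        plan2 = PermutationPlan(perms_empirical, seed + 1)
        reps2 = run_permutations(Xg, Xh, fit, plan2, pvalue_mode="analytic")
        m_perm = np.minimum(reps2.pvals_genotype, reps2.pvals_haplotype)
        p_minp = float(
            (np.sum(m_perm <= min(pair.p1, pair.p2)) + 1) / (plan2.n_permutations + 1)
        )
        s_perm = sump_statistic(reps2.pvals_genotype, reps2.pvals_haplotype)
        p_sump = float(
            (np.sum(s_perm >= sump_statistic(pair.p1, pair.p2)) + 1)
            / (plan2.n_permutations + 1)
        )
    logger.info(
        "region %s: L=%d (rare %d), M=%d, rho=%.3f, gate=%s",
        region.name, G.n_variants, int((G.maf < maf_threshold).sum()),
        grouping.n_groups, rho.rho, source,
    )
    return {
        "region": region.name,
        "n_snps": G.n_variants,
        "p_genotype_skat": res_g.p_value,
        "p_haplotype_skat": res_h.p_value,
        "p_minp": p_minp,
        "p_sump": p_sump,
        "rho_hat": rho.rho,
        "pvalue_source": source,
        "normality_pvalue": gate_p,
        "status": "ok",
    }
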