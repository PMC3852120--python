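"""Genotype- and haplotype-based SKAT for a genomic region.

The genotype arm collapses rare variants (sample MAF below a threshold) into a
single burden "super-variant" — the per-individual count of rare minor
alleles, capped at 2 — and keeps each common variant as its own column.  The
haplotype arm groups observed haplotypes (each common haplotype its own group,
all rare haplotypes pooled; a three-frequency-bin fallback when no haplotype
is common), drops the most common group as reference, and counts each
individual's haplotypes per remaining group.  Both design matrices feed the
same variance-component score test (SKAT with linear kernel and uniform
weights) against a Gaussian or binomial phenotype adjusted for covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from ._qf import chi2_mixture_sf

__all__ = [
    "RegionGenotypes",
    "CollapsedGenotypes",
    "HaplotypePairSet",
    "HaplotypeGrouping",
    "HaplotypeDesignMatrix",
    "NullModelFit",
    "SkatResult",
    "collapse_rare_variants",
    "group_haplotypes",
    "build_haplotype_matrix",
    "fit_null_model",
    "skat_test",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RegionGenotypes:
    """Minor-allele dosage matrix for one region.

    ``dosages`` is n x L with entries in {0, 1, 2} or NaN for missing;
    ``maf`` holds per-variant sample minor-allele frequencies computed from
    non-missing entries only.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] < 1:
            raise ValueError("dosages must be an n x L matrix with L >= 1")
        if len(self.variant_ids) != self.dosages.shape[1]:
            raise ValueError("variant_ids length must match number of columns")
        obs = ~np.isnan(self.dosages)
        if not obs.any(axis=0).all():
            bad = [self.variant_ids[j] for j in np.where(~obs.any(axis=0))[0]]
            raise ValueError(f"variant(s) with all dosages missing: {bad}")
        vals = self.dosages[obs]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be in {0, 1, 2}")
        if self.maf is None:
            with np.errstate(invalid="ignore"):
                freq = np.nanmean(self.dosages, axis=0) / 2.0
            self.maf = np.minimum(freq, 1.0 - freq)
        self.maf = np.asarray(self.maf, dtype=float)
        if ((self.maf < 0) | (self.maf > 0.5)).any():
            raise ValueError("maf must lie in [0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean."""
        out = self.dosages.copy()
        miss = np.isnan(out)
        if miss.any():
            col_mean = np.nanmean(self.dosages, axis=0)
            out[miss] = np.take(col_mean, np.where(miss)[1])
        return out


@dataclass
class CollapsedGenotypes:
    """Region design matrix after rare-variant collapsing (matrix is n x L')."""

    matrix: np.ndarray
    variant_ids: list[str]
    has_super_variant: bool
    threshold: float


@dataclass
class HaplotypePairSet:
    """Ordered haplotype-identifier pairs, one pair per diploid individual."""

    pairs: list[tuple[str, str]]
    haplotype_freq: dict[str, float]

    def __post_init__(self) -> None:
        for h1, h2 in self.pairs:
            if h1 not in self.haplotype_freq or h2 not in self.haplotype_freq:
                raise ValueError("every haplotype in pairs must appear in haplotype_freq")
        total = sum(self.haplotype_freq.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"haplotype frequencies must sum to 1 (got {total})")

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "HaplotypePairSet":
        """Build with pooled sample frequencies computed from the pairs."""
        counts: dict[str, int] = {}
        for h1, h2 in pairs:
            counts[h1] = counts.get(h1, 0) + 1
            counts[h2] = counts.get(h2, 0) + 1
        tot = 2 * len(pairs)
        return cls(pairs, {h: c / tot for h, c in counts.items()})

    @property
    def n_samples(self) -> int:
        return len(self.pairs)


@dataclass
class HaplotypeGrouping:
    """Partition of observed haplotypes into groups H_1..H_M, H_M the reference."""

    groups: list[set[str]]
    scheme: str  # "common-vs-pooled-rare" | "three-bin-fallback"

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def reference(self) -> set[str]:
        """The most common group H_M (stored last), omitted from the design."""
        return self.groups[-1]


@dataclass
class HaplotypeDesignMatrix:
    """n x (M-1) matrix of per-group haplotype counts, reference group omitted."""

    matrix: np.ndarray


@dataclass
class NullModelFit:
    """Reduced model Y = a + Cc + eps (no genetic term), shared by the score
    tests and the permutation engine.  Residuals are on the response scale."""

    family: str  # "gaussian" | "binomial"
    intercept: float
    covariate_effects: np.ndarray
    fitted_values: np.ndarray
    residuals: np.ndarray
    dispersion: float
    design: np.ndarray  # n x (K+1) including the intercept column

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def phenotype(self) -> np.ndarray:
        return self.fitted_values + self.residuals


@dataclass
class SkatResult:
    Q: float
    eigenvalues: np.ndarray
    p_value: float
    method: str  # "davies" | "moment-matched" | "permutation"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def collapse_rare_variants(G: RegionGenotypes, threshold: float = 0.01) -> CollapsedGenotypes:
    """Collapse rare variants (sample MAF < threshold) into one super-variant.

    The super-variant is the per-individual sum of minor alleles across rare
    variants, capped at 2.  Common variants are copied unchanged.  Missing
    dosages are mean-imputed per variant first.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    X = G.imputed()
    rare = G.maf < threshold
    cols = [X[:, ~rare]] if (~rare).any() else []
    ids = [G.variant_ids[j] for j in np.where(~rare)[0]]
    if rare.any():
        super_var = np.minimum(2.0, X[:, rare].sum(axis=1))
        cols.append(super_var[:, None])
        ids.append("SUPER")
    matrix = np.hstack(cols)
    return CollapsedGenotypes(matrix, ids, bool(rare.any()), threshold)


_FALLBACK_LO = 0.0005  # 0.05 %
_FALLBACK_HI = 0.001  # 0.1 %


def group_haplotypes(H: HaplotypePairSet, common_threshold: float = 0.01) -> HaplotypeGrouping:
    """Group haplotypes: each common haplotype alone, all rare ones pooled.

    When no haplotype reaches ``common_threshold``, fall back to three
    frequency bins: < 0.05 %, [0.05 %, 0.1 %], > 0.1 % (empty bins dropped).
    The group with the largest total frequency becomes the reference H_M and
    is stored last.
    """
    freq = H.haplotype_freq
    if len(freq) < 2:
        raise ValueError("region is degenerate: fewer than 2 distinct haplotypes")
    common = sorted(h for h, f in freq.items() if f >= common_threshold)
    if common:
        groups = [{h} for h in common]
        rare = {h for h in freq if h not in set(common)}
        if rare:
            groups.append(rare)
        scheme = "common-vs-pooled-rare"
    else:
        lo = {h for h, f in freq.items() if f < _FALLBACK_LO}
        mid = {h for h, f in freq.items() if _FALLBACK_LO <= f <= _FALLBACK_HI}
        hi = {h for h, f in freq.items() if f > _FALLBACK_HI}
        groups = [g for g in (lo, mid, hi) if g]
        scheme = "three-bin-fallback"
    if len(groups) < 2:
        raise ValueError("haplotype grouping is degenerate: only one group formed")

    def group_key(g: set[str]):
        return (-sum(freq[h] for h in g), sorted(g))

    groups.sort(key=group_key)
    # reference = most common group, moved to the end
    groups = groups[1:] + groups[:1]
    return HaplotypeGrouping(groups, scheme)


def build_haplotype_matrix(
    H: HaplotypePairSet, grouping: HaplotypeGrouping
) -> HaplotypeDesignMatrix:
    """Count each individual's haplotypes in groups H_1..H_{M-1} (reference omitted)."""
    index: dict[str, int] = {}
    for j, g in enumerate(grouping.groups):
        for h in g:
            index[h] = j
    M = grouping.n_groups
    R = np.zeros((H.n_samples, M - 1))
    for i, (h1, h2) in enumerate(H.pairs):
        for h in (h1, h2):
            if h not in index:
                raise ValueError(f"haplotype {h!r} absent from grouping")
            j = index[h]
            if j < M - 1:
                R[i, j] += 1
    return HaplotypeDesignMatrix(R)


def _check_full_rank(D: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(D) < D.shape[1]:
        # identify columns that add no rank
        bad = []
        rank = 0
        kept: list[int] = []
        for j in range(D.shape[1]):
            r = np.linalg.matrix_rank(D[:, kept + [j]])
            if r > rank:
                rank = r
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"covariate design is rank-deficient; collinear column(s): {bad}")


def fit_null_model(
    Y: np.ndarray, C: np.ndarray | None = None, family: str = "gaussian"
) -> NullModelFit:
    """Fit the reduced model Y = a + Cc + eps (Gaussian least squares or
    binomial maximum likelihood) and keep response-scale residuals."""
    y = np.asarray(Y, dtype=float)
    n = y.shape[0]
    if C is None or (hasattr(C, "size") and np.asarray(C).size == 0):
        D = np.ones((n, 1))
        names = ["intercept"]
    else:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
        D = np.column_stack([np.ones(n), C])
        names = ["intercept"] + [f"covariate_{k}" for k in range(C.shape[1])]
    if n <= D.shape[1]:
        raise ValueError("need more samples than model parameters")
    _check_full_rank(D, names)
    if family == "gaussian":
        res = sm.OLS(y, D).fit()
        mu = res.fittedvalues
        eps = y - mu
        dispersion = float(eps @ eps / n)  # ML variance estimate under the null
    elif family == "binomial":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial family requires a 0/1 phenotype")
        res = sm.GLM(y, D, family=sm.families.Binomial()).fit()
        mu = res.fittedvalues
        eps = y - mu
        dispersion = 1.0
    else:
        raise ValueError(f"unknown family {family!r}")
    params = np.asarray(res.params, dtype=float)
    return NullModelFit(
        family=family,
        intercept=float(params[0]),
        covariate_effects=params[1:],
        fitted_values=np.asarray(mu, dtype=float),
        residuals=np.asarray(eps, dtype=float),
        dispersion=dispersion,
        design=D,
    )


def skat_null_eigenvalues(X: np.ndarray, fit: NullModelFit) -> np.ndarray:
    """Eigenvalue weights of the null chi-squared mixture for ``skat_statistic``."""
    X = np.asarray(X, dtype=float)
    D = fit.design
    if fit.family == "gaussian":
        XtD = X.T @ D
        A = X.T @ X - XtD @ np.linalg.solve(D.T @ D, XtD.T)
        lam = np.linalg.eigvalsh(A) / 2.0
    else:
        v = fit.fitted_values * (1.0 - fit.fitted_values)
        XtVD = (X * v[:, None]).T @ D
        A = (X * v[:, None]).T @ X - XtVD @ np.linalg.solve((D * v[:, None]).T @ D, XtVD.T)
        lam = np.linalg.eigvalsh(A)
    return lam[lam > max(lam.max(initial=0.0) * 1e-12, 0.0)]


def skat_statistic(X: np.ndarray, residuals: np.ndarray, fit: NullModelFit) -> float:
    """Variance-component score statistic Q for residuals under ``fit``."""
    u = np.asarray(X, dtype=float).T @ residuals
    q = float(u @ u)
    if fit.family == "gaussian":
        q /= 2.0 * fit.dispersion
    return q


def skat_test(X: np.ndarray, fit: NullModelFit) -> SkatResult:
    """SKAT with linear kernel and uniform weights.

    Q = eps' X X' eps / scale (scale = 2*sigma^2 for Gaussian, 1 with
    variance-weighted eigenvalues for binomial); the analytic p-value is the
    tail of the matching chi-squared mixture at Q.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != fit.n_samples:
        raise ValueError("X and null fit cover different numbers of samples")
    lam = skat_null_eigenvalues(X, fit)
    Q = skat_statistic(X, fit.residuals, fit)
    if lam.size == 0:
        warnings.warn("design matrix has no variance after projection; p-value set to 1")
        return SkatResult(Q=Q, eigenvalues=lam, p_value=1.0, method="davies")
    p, method = chi2_mixture_sf(Q, lam)
    return SkatResult(Q=Q, eigenvalues=lam, p_value=p, method=method)
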