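"""Permutation of residuals under the reduced model.

Null replicates of the phenotype are built as ``Y* = mu_hat + pi(eps_hat)``
for random permutations ``pi`` of the reduced-model residuals (the
Freedman-Lane scheme), which preserves the phenotype-covariate relationship
while breaking any phenotype-genotype association.  The two SKAT statistics
are recomputed on each replicate without refitting; replicates provide both
empirical p-values and the correlation estimate between the two underlying
tests.  For a binomial fit without covariates this reduces to plain phenotype
permutation, which is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._qf import chi2_mixture_sf
from .association import NullModelFit, skat_null_eigenvalues, skat_statistic
from .combine import CorrelationEstimate, estimate_correlation

__all__ = [
    "PermutationPlan",
    "PermutationReplicates",
    "permute_phenotype",
    "run_permutations",
    "empirical_pvalue",
]


@dataclass
class PermutationPlan:
    """Reproducible permutation stream: replicate r is determined by (seed, r)."""

    n_permutations: int
    seed: int = 0

    def rng(self, replicate_index: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, replicate_index)))

    def permutation(self, n: int, replicate_index: int) -> np.ndarray:
        return self.rng(replicate_index).permutation(n)


@dataclass
class PermutationReplicates:
    stats_genotype: np.ndarray
    stats_haplotype: np.ndarray
    pvals_genotype: np.ndarray = field(default=None)  # type: ignore[assignment]
    pvals_haplotype: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return len(self.stats_genotype)

    def pairs(self) -> np.ndarray:
        """(B, 2) array of per-replicate (genotype, haplotype) p-values."""
        return np.column_stack([self.pvals_genotype, self.pvals_haplotype])


def permute_phenotype(
    fit: NullModelFit, plan: PermutationPlan, replicate_index: int
) -> np.ndarray:
    """Y* = mu_hat + pi(eps_hat) with pi determined by (plan.seed, replicate_index)."""
    pi = plan.permutation(fit.n_samples, replicate_index)
    return fit.fitted_values + fit.residuals[pi]


def _rank_pvalues(stats_arr: np.ndarray) -> np.ndarray:
    """Within-set midrank p-values: p_r = (#{r': Q_r' >= Q_r} - 0.5) / B.

    The half-count offset keeps p strictly inside (0, 1), so the
    inverse-normal transform of the most extreme replicate stays finite and
    does not distort the correlation estimate.
    """
    B = len(stats_arr)
    sorted_vals = np.sort(stats_arr)
    ge_counts = B - np.searchsorted(sorted_vals, stats_arr, side="left")
    return (ge_counts - 0.5) / B


def run_permutations(
    Xg: np.ndarray,
    Xh: np.ndarray,
    fit: NullModelFit,
    plan: PermutationPlan,
    pvalue_mode: str = "analytic",
) -> PermutationReplicates:
    """Recompute both SKAT statistics on each permuted phenotype.

    The null fit is reused (no per-replicate refitting).  Per-replicate
    p-values are computed analytically from the null chi-squared mixture
    (``pvalue_mode="analytic"``), by within-set ranks (``"rank"``), or not at
    all (``"none"``).
    """
    B = plan.n_permutations
    if B == 0:
        empty = np.empty(0)
        return PermutationReplicates(empty, empty.copy(), empty.copy(), empty.copy())
    Xg = np.asarray(Xg, dtype=float)
    Xh = np.asarray(Xh, dtype=float)
    stats_g = np.empty(B)
    stats_h = np.empty(B)
    eps = fit.residuals
    for r in range(B):
        pi = plan.permutation(fit.n_samples, r)
        e = eps[pi]
        stats_g[r] = skat_statistic(Xg, e, fit)
        stats_h[r] = skat_statistic(Xh, e, fit)
        if not (np.isfinite(stats_g[r]) and np.isfinite(stats_h[r])):
            raise RuntimeError(f"non-finite permutation statistic at replicate {r}")
    if pvalue_mode == "analytic":
        lam_g = skat_null_eigenvalues(Xg, fit)
        lam_h = skat_null_eigenvalues(Xh, fit)
        pg = np.array([chi2_mixture_sf(q, lam_g)[0] for q in stats_g])
        ph = np.array([chi2_mixture_sf(q, lam_h)[0] for q in stats_h])
    elif pvalue_mode == "rank":
        pg = _rank_pvalues(stats_g)
        ph = _rank_pvalues(stats_h)
    elif pvalue_mode == "none":
        pg = ph = None
    else:
        raise ValueError(f"unknown pvalue_mode {pvalue_mode!r}")
    return PermutationReplicates(stats_g, stats_h, pg, ph)


def empirical_pvalue(observed: float, replicates: np.ndarray) -> float:
    """Add-one empirical p-value: (#{replicate >= observed} + 1) / (B + 1)."""
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size < 1:
        raise ValueError("need at least one replicate")
    return (np.sum(replicates >= observed) + 1) / (replicates.size + 1)


def estimate_rho(
    Xg: np.ndarray,
    Xh: np.ndarray,
    fit: NullModelFit,
    plan: PermutationPlan,
    pvalue_mode: str = "analytic",
) -> tuple[CorrelationEstimate, PermutationReplicates]:
    """Correlation between the two tests from permutation replicates."""
    reps = run_permutations(Xg, Xh, fit, plan, pvalue_mode=pvalue_mode)
    return estimate_correlation(reps.pairs()), reps
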