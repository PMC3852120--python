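"""Combined region tests: MinP-val and SumP-val.

Given p-values ``p1`` (genotype test) and ``p2`` (haplotype test), transform
each as ``y_k = Phi^{-1}(1 - p_k)``; under the null (y1, y2) is modelled as
standard bivariate normal with correlation rho estimated from permutation
replicates.  SumP-val uses the statistic y1 + y2 ~ N(0, 2 + 2*rho); MinP-val
uses min(p1, p2), whose null CDF at x is ``1 - BVN(q, q; rho)`` with
``q = Phi^{-1}(1 - x)``.  A Shapiro-Wilk gate on the transformed permutation
replicates decides whether these theoretical p-values are trusted or
permutation p-values are required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "PValuePair",
    "CorrelationEstimate",
    "CombinedResult",
    "inverse_normal",
    "bivariate_normal_cdf",
    "sump_statistic",
    "sump_pvalue",
    "minp_pvalue",
    "minp_critical_value",
    "estimate_correlation",
    "normality_gate",
    "combine_pvalues",
]

_EPS = 1e-12
_RHO_CLAMP = 0.999


@dataclass
class PValuePair:
    p1: float  # genotype-test p-value
    p2: float  # haplotype-test p-value

    def __post_init__(self) -> None:
        self.p1 = float(np.clip(self.p1, _EPS, 1 - _EPS))
        self.p2 = float(np.clip(self.p2, _EPS, 1 - _EPS))


@dataclass
class CorrelationEstimate:
    rho: float
    n_permutations: int

    @property
    def clamped_rho(self) -> float:
        return float(np.clip(self.rho, -_RHO_CLAMP, _RHO_CLAMP))


@dataclass
class CombinedResult:
    pair: PValuePair
    rho: CorrelationEstimate
    minp_stat: float
    minp_pvalue: float
    sump_stat: float
    sump_pvalue: float
    pvalue_source: str  # "theoretical" | "permutation"
    normality_pvalue: float


def inverse_normal(p):
    """Inverse standard normal transform ``Phi^{-1}(1 - p)``; large values
    correspond to small p.  Out-of-range p is clamped to [1e-12, 1 - 1e-12]."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-value(s) outside (0,1) clamped before transformation")
        p = np.clip(p, _EPS, 1 - _EPS)
    out = stats.norm.isf(p)
    return float(out) if out.ndim == 0 else out


def bivariate_normal_cdf(q1, q2, rho: float):
    """Standard bivariate normal ``P(Y1 <= q1, Y2 <= q2)`` with correlation rho.

    Computed from Owen's T function (vectorized, absolute accuracy well below
    1e-7).
    """
    if abs(rho) > _RHO_CLAMP:
        raise ValueError("|rho| must not exceed 0.999")
    h = np.asarray(q1, dtype=float)
    k = np.asarray(q2, dtype=float)
    if rho == 0.0:
        out = stats.norm.cdf(h) * stats.norm.cdf(k)
        return float(out) if out.ndim == 0 else out
    # Owen (1956): BVN(h,k,rho) = (Phi(h)+Phi(k))/2 - T(h,ah) - T(k,ak) - delta.
    # Exact zeros are nudged; the CDF is continuous so the error is O(1e-15).
    h = np.where(h == 0.0, 1e-15, h)
    k = np.where(k == 0.0, 1e-15, k)
    denom = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    delta = np.where(h * k > 0, 0.0, 0.5)
    out = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - delta
    )
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def sump_statistic(p1, p2):
    """SumP statistic ``y1 + y2`` on the inverse-normal scale."""
    return inverse_normal(p1) + inverse_normal(p2)


def sump_pvalue(pair, rho) -> float:
    """Theoretical SumP-val p-value: upper tail of N(0, 2 + 2*rho) at y1+y2."""
    p1, p2, r = _unpack(pair, rho)
    s = sump_statistic(p1, p2)
    var = 2.0 + 2.0 * r
    out = stats.norm.sf(s / np.sqrt(var))
    out = np.clip(out, _EPS, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def minp_pvalue(pair, rho) -> float:
    """Theoretical MinP-val p-value: with x = min(p1,p2), q = Phi^{-1}(1-x),
    p = 1 - BVN(q, q; rho)."""
    p1, p2, r = _unpack(pair, rho)
    x = np.minimum(p1, p2)
    q = stats.norm.isf(x)
    out = 1.0 - bivariate_normal_cdf(q, q, r)
    out = np.clip(out, _EPS, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def minp_critical_value(alpha: float, rho: float) -> float:
    """The x* with null P(min(p1,p2) < x*) = alpha; min-p below x* rejects."""
    r = float(np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP))

    def f(x: float) -> float:
        q = stats.norm.isf(x)
        return (1.0 - bivariate_normal_cdf(q, q, r)) - alpha

    return optimize.brentq(f, alpha / 2 * (1 - 1e-9), alpha * (1 + 1e-12))


def _unpack(pair, rho):
    if isinstance(pair, PValuePair):
        p1, p2 = pair.p1, pair.p2
    else:
        p1, p2 = pair
        p1 = np.clip(np.asarray(p1, dtype=float), _EPS, 1 - _EPS)
        p2 = np.clip(np.asarray(p2, dtype=float), _EPS, 1 - _EPS)
    r = rho.clamped_rho if isinstance(rho, CorrelationEstimate) else float(np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP))
    return p1, p2, r


def estimate_correlation(perm_pairs) -> CorrelationEstimate:
    """Pearson correlation of inverse-normal-transformed permutation p-values.

    ``perm_pairs`` is a sequence of (p1, p2) pairs (or an (B, 2) array) from
    permutation replicates of the two underlying tests.
    """
    arr = np.asarray(
        [(p.p1, p.p2) if isinstance(p, PValuePair) else tuple(p) for p in perm_pairs],
        dtype=float,
    )
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 permutation replicates")
    y = stats.norm.isf(np.clip(arr, _EPS, 1 - _EPS))
    if np.std(y[:, 0]) == 0 or np.std(y[:, 1]) == 0:
        raise ValueError("degenerate permutation p-values: zero variance in a margin")
    rho = float(np.corrcoef(y[:, 0], y[:, 1])[0, 1])
    return CorrelationEstimate(rho=rho, n_permutations=arr.shape[0])


def normality_gate(transformed_perm_pairs, alpha_genomewide: float) -> tuple[str, float]:
    """Shapiro-Wilk check of the bivariate-normal null model for (y1, y2).

    Applies Shapiro-Wilk to each margin with a Bonferroni factor of 2 (a
    conservative proxy for the multivariate test).  Returns
    ``(source, gate_pvalue)`` where source is "theoretical" when the adjusted
    p-value exceeds ``alpha_genomewide`` and "permutation" otherwise.
    """
    arr = np.asarray(
        [
            (p.p1, p.p2) if isinstance(p, PValuePair) else tuple(p)
            for p in transformed_perm_pairs
        ],
        dtype=float,
    )
    if arr.shape[0] < 20:
        raise ValueError("need at least 20 replicates for the normality gate")
    if np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
        raise ValueError("degenerate replicates: zero variance in a margin")
    p_w = min(stats.shapiro(arr[:, 0]).pvalue, stats.shapiro(arr[:, 1]).pvalue)
    gate_p = min(1.0, 2.0 * p_w)
    source = "theoretical" if gate_p > alpha_genomewide else "permutation"
    return source, gate_p


def combine_pvalues(
    p1: float,
    p2: float,
    perm_pairs,
    alpha_genomewide: float = 1.38e-6,
) -> CombinedResult:
    """Full combination step from observed p-values and permutation replicates.

    Estimates rho, runs the normality gate, and reports theoretical MinP-val
    and SumP-val p-values.  When the gate selects "permutation" the caller
    should replace the combined p-values with empirical ones from the
    permutation engine; the theoretical values are still reported here.
    """
    pair = PValuePair(p1, p2)
    rho = estimate_correlation(perm_pairs)
    y = stats.norm.isf(
        np.clip(
            np.asarray(
                [(p.p1, p.p2) if isinstance(p, PValuePair) else tuple(p) for p in perm_pairs],
                dtype=float,
            ),
            _EPS,
            1 - _EPS,
        )
    )
    source, gate_p = normality_gate(y, alpha_genomewide)
    return CombinedResult(
        pair=pair,
        rho=rho,
        minp_stat=min(pair.p1, pair.p2),
        minp_pvalue=minp_pvalue(pair, rho),
        sump_stat=sump_statistic(pair.p1, pair.p2),
        sump_pvalue=sump_pvalue(pair, rho),
        pvalue_source=source,
        normality_pvalue=gate_p,
    )
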