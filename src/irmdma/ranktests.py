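"""Rank-test primitives used by the differential screens.

Thin, contract-enforcing wrappers around scipy.stats with explicit
conventions: two-sided tests throughout, exact Wilcoxon null
distribution for small tie-free groups, tie-corrected approximations
otherwise, and defined behaviour for degenerate (all-equal) input where
scipy would raise or return NaN.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

#: Largest group size for which the exact Wilcoxon null distribution is used.
EXACT_CUTOFF = 8

#: Largest n for which the Spearman p-value is an exact permutation p.
SPEARMAN_EXACT_N = 9


def _check_group(values, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < min_n:
        raise ValidationError(f"group {name} needs >= {min_n} values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValidationError(f"group {name} contains non-finite values")
    return arr


def wilcoxon_rank_sum(
    a,
    b,
    exact_cutoff: int = EXACT_CUTOFF,
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns (U statistic of the first group, p). Uses the exact null
    distribution when both groups have <= ``exact_cutoff`` observations
    and there are no ties; otherwise the normal approximation with tie
    correction and (by default) continuity correction. All observations
    identical yields p = 1 by convention.
    """
    a = _check_group(a, "a")
    b = _check_group(b, "b")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size <= exact_cutoff and b.size <= exact_cutoff:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=continuity
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1 df) p.

    All observations identical across all groups is defined as H = 0,
    p = 1 rather than a zero-division in the tie correction.
    """
    if len(groups) < 2:
        raise ValidationError(f"Kruskal-Wallis needs >= 2 groups, got {len(groups)}")
    arrays = [_check_group(g, f"#{i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """P(|rho| >= |rho_obs|) over all n! pairings of the rank vectors."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    perms = np.array(list(permutations(ry_c)))
    rhos = perms @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= np.abs(rho_obs) - 1e-12))


def spearman_rho(x, y, exact_n: int = SPEARMAN_EXACT_N) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p.

    The p-value is an exact permutation p (all n! pairings) for
    n <= ``exact_n``, and the usual t-distribution approximation above
    that. Constant input has no defined rank correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 4:
        raise ValidationError(f"need >= 4 paired observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in correlation input")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if x.size <= exact_n:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
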