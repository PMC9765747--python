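"""Nonparametric tests and multiplicity correction.

The Mann-Whitney U test uses exact enumeration of the null distribution
when both groups have at most 8 observations and the pooled data contain no
ties; otherwise it falls back on the normal approximation with tie and
continuity corrections. The formulas intentionally reproduce the defaults
of the standard scientific Python stack so that results are comparable with
analyses run through it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy.stats import chi2, norm, rankdata

EXACT_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        if not np.isfinite(self.statistic):
            raise ValueError("non-finite test statistic")


def _exact_mwu_pvalue(ranks_x_sum: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    """Exact two-sided p by enumerating all C(n1+n2, n1) group labelings."""
    u1 = ranks_x_sum - n1 * (n1 + 1) / 2
    total = comb(n1 + n2, n1)
    m = n1 * n2
    lo, hi = min(u1, m - u1), max(u1, m - u1)
    count = 0
    ranks = rankdata(pooled)
    for combo in combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
        if u <= lo or u >= hi:
            count += 1
    return count / total


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test (rank-sum) for two independent samples.

    Returns the U statistic of the first sample, with average-rank tie
    handling. Exact p-values are computed by enumeration for small tie-free
    samples (both n <= 8); larger or tied samples use the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    m = n1 * n2
    has_ties = len(np.unique(pooled)) < n1 + n2

    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and not has_ties:
        if alternative == "two-sided":
            p = _exact_mwu_pvalue(r1, n1, n2, pooled)
        else:
            # one-sided exact tail
            total = comb(n1 + n2, n1)
            count = 0
            for combo in combinations(range(n1 + n2), n1):
                u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
                if (alternative == "greater" and u >= u1) or (
                    alternative == "less" and u <= u1
                ):
                    count += 1
            p = count / total
        method = "mann-whitney-exact"
    else:
        mu = m / 2
        ncomb = n1 + n2
        _, t = np.unique(pooled, return_counts=True)
        tie_term = float((t**3 - t).sum())
        sigma = sqrt(n1 * n2 / 12 * ((ncomb + 1) - tie_term / (ncomb * (ncomb - 1))))
        if sigma == 0:
            p = 1.0
        elif alternative == "two-sided":
            u_big = max(u1, m - u1)
            z = (u_big - mu - 0.5) / sigma
            p = min(1.0, 2 * norm.sf(z))
        elif alternative == "greater":
            p = min(1.0, float(norm.sf((u1 - mu - 0.5) / sigma)))
        else:
            p = min(1.0, float(norm.cdf((u1 - mu + 0.5) / sigma)))
        method = "mann-whitney-normal"
    p = max(p, np.finfo(float).tiny)
    return TestResult(float(u1), float(p), method, (n1, n2))


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    H is computed with average-rank tie correction; the p-value comes from
    the chi-squared distribution with k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = rankdata(pooled)
    offset = 0
    h = 0.0
    for a in arrays:
        r = ranks[offset : offset + len(a)]
        h += r.sum() ** 2 / len(a)
        offset += len(a)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    tie = 1 - float((t**3 - t).sum()) / (n**3 - n)
    if tie == 0:
        raise ValueError("all pooled values identical; H undefined")
    h /= tie
    df = len(groups) - 1
    p = max(float(chi2.sf(h, df)), np.finfo(float).tiny)
    return TestResult(float(h), p, "kruskal-wallis", tuple(len(a) for a in arrays))


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni correction: ``min(1, m * p)`` elementwise."""
    ps = list(p_values)
    if any(not (0 < p <= 1) for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = len(ps)
    return [min(1.0, m * p) for p in ps]


def major_phyla(mag_counts: dict[str, int], min_mags: int = 50) -> list[str]:
    """Phyla with strictly more than ``min_mags`` MAGs, sorted by count."""
    if any(v < 0 for v in mag_counts.values()):
        raise ValueError("negative MAG count")
    kept = [(phylum, n) for phylum, n in mag_counts.items() if n > min_mags]
    return [phylum for phylum, _ in sorted(kept, key=lambda kv: (-kv[1], kv[0]))]
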