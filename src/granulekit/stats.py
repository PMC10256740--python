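"""Rank and overlap statistics used across modules.

The Mann–Whitney U test is exact (full enumeration of group
assignments, midranks for ties) for combined sample sizes up to 12 and
otherwise uses the normal approximation with tie correction.  The
two-tailed exact p is 2·min(P(U ≤ u), P(U ≥ u)) capped at 1, so two
identical small groups give p = 1 and a complete separation of
{1,2,3} vs {10,11,12} gives the smallest attainable p, 2/C(6,3) = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str  # "exact" or "asymptotic"
    n_a: int
    n_b: int


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b, exact_max_n: int = 12) -> MannWhitneyResult:
    """Two-tailed Mann–Whitney U test.

    Exact enumeration over all C(n_a+n_b, n_a) group assignments when
    n_a + n_b <= ``exact_max_n``; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties

    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)

    if n_a + n_b <= exact_max_n:
        n = n_a + n_b
        us = np.array([
            _u_statistic(ranks[list(idx)], n_a, n_b)
            for idx in combinations(range(n), n_a)
        ])
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u_obs, float(p), "exact", n_a, n_b)

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue),
                             "asymptotic", n_a, n_b)


@dataclass
class OverlapResult:
    """Gene-set overlap: fold enrichment over independence plus Fisher p."""

    n_a: int
    n_b: int
    overlap: int
    universe: int
    fold: float
    p: float

    @property
    def expected(self) -> float:
        return self.n_a * self.n_b / self.universe


def overlap_enrichment(set_a, set_b, universe_size: int) -> OverlapResult:
    """Fold enrichment and two-tailed Fisher exact p for two gene sets.

    Fold = observed overlap / expected under independence
    (|A|·|B|/N).  The p-value comes from the 2×2 table
    (|A∩B|, |A\\B|, |B\\A|, neither).
    """
    set_a, set_b = set(set_a), set(set_b)
    n_a, n_b = len(set_a), len(set_b)
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("set sizes exceed the universe")
    k = len(set_a & set_b)
    expected = n_a * n_b / universe_size
    if expected == 0:
        raise ValueError("expected overlap is zero; fold undefined")
    table = [[k, n_a - k], [n_b - k, universe_size - n_a - n_b + k]]
    if min(min(row) for row in table) < 0:
        raise ValueError("sets are inconsistent with the stated universe size")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return OverlapResult(n_a, n_b, k, universe_size, k / expected, float(p))
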