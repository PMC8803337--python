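"""Cross-condition statistics: Spearman ranking, cumulative-overlap curves
with an area-vs-diagonal statistic, rank-sum tests, and overlap summaries.

The cumulative-overlap curve is a GSEA-like readout: rank the N reference
genes by fold change, walk down the ranking and count how many of the K query
genes have appeared; plotting y = C(i)/K against x = i/N gives a curve that
hugs the upper-left corner when the query concentrates at the top of the
ranking.  The area statistic is the discrete step sum

    area = (1/N) * sum_{i=1..N} (C(i)/K - i/N)

which lies in (-0.5, 0.5), is exactly negated when the reference ranking is
reversed, and is a linear function of the rank sum of the query members.  The
attached p-value is a Wilcoxon rank-sum test of query-member ranks versus
non-member ranks: exact enumeration (a subset-sum count over rank totals) when
min(group sizes) <= 10 and N <= 30, otherwise the normal approximation with
tie and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PairedVector, RankedVector, ValidationError

__all__ = [
    "CorrelationResult",
    "OverlapCurve",
    "OverlapSummary",
    "spearman_rho",
    "rank_comparisons",
    "cumulative_overlap",
    "rank_sum_test",
    "exact_rank_sum_cdf",
    "overlap_summary",
]

#: exact rank-sum enumeration limits: min(group sizes) and universe size
EXACT_MIN_GROUP = 10
EXACT_MAX_N = 30


@dataclass
class CorrelationResult:
    """Spearman correlation of one comparison, with its rank among many."""

    comparison_id: str
    rs: float
    n_genes: int
    rank: int | None = None


def spearman_rho(paired: PairedVector) -> float:
    """Spearman correlation (average ranks for ties) of the paired fold changes.

    Returns NaN when either vector is constant — the coefficient is undefined
    there, and NaN keeps that explicit rather than collapsing to 0.
    """
    if paired.n_pairs < 3:
        raise ValidationError("spearman_rho needs at least 3 pairs")
    a, b = paired.fc_a(), paired.fc_b()
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def rank_comparisons(results: list[CorrelationResult]) -> list[CorrelationResult]:
    """Assign ranks 1..n by descending rs (1 = strongest resemblance).

    Ties are broken by comparison_id (ascending lexicographic); undefined
    (NaN) coefficients sort after every defined one.  Returns a new list in
    rank order.
    """
    if not results:
        raise ValidationError("rank_comparisons needs at least one comparison")
    ids = [r.comparison_id for r in results]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate comparison_id(s): {dup}")

    def key(r: CorrelationResult):
        nan = np.isnan(r.rs)
        return (nan, -r.rs if not nan else 0.0, r.comparison_id)

    ordered = sorted(results, key=key)
    return [
        CorrelationResult(r.comparison_id, r.rs, r.n_genes, rank=i + 1)
        for i, r in enumerate(ordered)
    ]


@dataclass
class OverlapCurve:
    """Cumulative overlap of a query set with a ranked reference.

    ``curve`` holds one row per reference rank i with x = i/N and
    y = C(i)/K; ``n_dropped_query`` counts query genes absent from the
    reference universe (dropped, not imputed).
    """

    n_universe: int
    k_query: int
    curve: pd.DataFrame  # columns i, x, y
    area: float
    p_value: float
    direction: str  # "increased" (descending reference) or "decreased"
    n_dropped_query: int = 0
    member_ranks: tuple[int, ...] = field(default=(), repr=False)


def cumulative_overlap(
    reference: RankedVector,
    query: set[str],
    alternative: str = "two_sided",
) -> OverlapCurve:
    """Cumulative-overlap curve, area statistic and rank-sum p-value.

    Query genes outside the reference universe are dropped and counted.
    Positive area means the query concentrates at the top of the ranking.
    """
    positions = reference.positions()
    members = sorted(query & positions.keys())
    n_dropped = len(query) - len(members)
    if not members:
        raise ValidationError("query has no genes in the reference universe")
    n = len(reference)
    k = len(members)
    member_ranks = np.array(sorted(positions[g] for g in members))
    is_member = np.zeros(n, dtype=bool)
    is_member[member_ranks - 1] = True
    c = np.cumsum(is_member)
    i = np.arange(1, n + 1)
    x = i / n
    y = c / k
    area = float(np.mean(y - x))
    p = rank_sum_test(reference, set(members), alternative=alternative)
    return OverlapCurve(
        n_universe=n,
        k_query=k,
        curve=pd.DataFrame({"i": i, "x": x, "y": y}),
        area=area,
        p_value=p,
        direction="increased" if reference.order == "descending" else "decreased",
        n_dropped_query=n_dropped,
        member_ranks=tuple(int(r) for r in member_ranks),
    )


def exact_rank_sum_cdf(n: int, k: int) -> np.ndarray:
    """Null distribution of the sum of k ranks drawn from 1..n without
    replacement: entry s of the returned array is the number of k-subsets of
    {1..n} whose ranks sum to s (dynamic programming over a subset-sum
    table)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros((k + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        # iterate subset sizes downward so each rank is used at most once
        for j in range(min(k, r), 0, -1):
            counts[j, r:] += counts[j - 1, :-r]
    return counts[k]


def rank_sum_test(
    reference: RankedVector,
    query: set[str],
    alternative: str = "two_sided",
) -> float:
    """Wilcoxon rank-sum p-value for query-member ranks vs non-member ranks.

    ``top_enriched`` tests whether member ranks are smaller (concentrated at
    the top of the ranking), ``bottom_enriched`` the reverse.  Exact
    enumeration of the rank-sum null when min(group sizes) <= 10 and
    N <= 30; normal approximation with continuity correction otherwise.
    """
    if alternative not in ("two_sided", "top_enriched", "bottom_enriched"):
        raise ValidationError(f"unknown alternative '{alternative}'")
    positions = reference.positions()
    members = query & positions.keys()
    if not members:
        raise ValidationError("empty member group")
    n = len(reference)
    k = len(members)
    if k == n:
        raise ValidationError("query covers the whole universe: empty complement")
    member_ranks = np.array(sorted(positions[g] for g in members), dtype=float)
    other_ranks = np.array(
        sorted(set(range(1, n + 1)) - set(int(r) for r in member_ranks)),
        dtype=float,
    )
    if min(k, n - k) <= EXACT_MIN_GROUP and n <= EXACT_MAX_N:
        counts = exact_rank_sum_cdf(n, k)
        total = counts.sum()
        s = int(member_ranks.sum())
        p_top = counts[: s + 1].sum() / total
        p_bottom = counts[s:].sum() / total
        if alternative == "top_enriched":
            return float(p_top)
        if alternative == "bottom_enriched":
            return float(p_bottom)
        return float(min(1.0, 2.0 * min(p_top, p_bottom)))
    scipy_alt = {
        "two_sided": "two-sided",
        "top_enriched": "less",
        "bottom_enriched": "greater",
    }[alternative]
    res = stats.mannwhitneyu(
        member_ranks, other_ranks, alternative=scipy_alt,
        method="asymptotic", use_continuity=True,
    )
    return float(res.pvalue)


@dataclass
class OverlapSummary:
    """Intersection counts and percentages of two signatures' gene sets."""

    n_a: int
    n_b: int
    n_intersection: int
    pct_of_a: float
    pct_of_b: float


def overlap_summary(set_a: set[str], set_b: set[str]) -> OverlapSummary:
    """Counts and percentage overlap of set A with set B (A must be non-empty)."""
    if not set_a:
        raise ValidationError("set_a must be non-empty")
    inter = len(set_a & set_b)
    return OverlapSummary(
        n_a=len(set_a),
        n_b=len(set_b),
        n_intersection=inter,
        pct_of_a=100.0 * inter / len(set_a),
        pct_of_b=100.0 * inter / len(set_b) if set_b else float("nan"),
    )
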