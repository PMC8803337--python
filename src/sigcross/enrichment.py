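"""Gene-set enrichment: observed/expected ratios with hypergeometric tails,
directional transcription-factor-target enrichment, and projection of
single-cell marker sets onto bulk fold changes.

The similarity readout between a query signature and a reference set is the
observed/expected ratio: with a universe of N genes, K of them in the
reference set and a query of n genes, the expected overlap under uniform
sampling is n*K/N and the reported ratio is observed/expected.  Significance
is the one-sided hypergeometric upper tail P(X >= observed), adjusted across
the tested collection by Benjamini-Hochberg; sets with no members in the
universe are reported untestable and excluded from the adjustment.

The universe is a deliberate, visible choice.  By default it should be the
gene universe of the query's source DE table, optionally intersected with the
genes measurable in the reference experiment; both the pipeline and the CLI
record the universe actually used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import DETable, GeneSetCollection, ValidationError
from .signatures import bh_adjust

__all__ = [
    "EnrichmentResult",
    "TFEnrichmentResult",
    "CellStateProjection",
    "hypergeom_enrichment",
    "enrich_collection",
    "tf_enrichment",
    "project_cell_states",
]

_P_FLOOR = 1e-300  # guards -log10 against underflow


@dataclass
class EnrichmentResult:
    """Observed/expected overlap of a query with one reference set."""

    set_name: str
    n_universe: int
    set_in_universe: int  # K after restriction to the universe
    query_size: int
    observed: int
    expected: float
    ratio: float
    p_value: float
    adj_p: float = float("nan")
    significant: bool = False
    testable: bool = True


def hypergeom_enrichment(
    query: set[str],
    ref_set: set[str],
    universe: set[str],
    set_name: str = "",
) -> EnrichmentResult:
    """One-sided hypergeometric enrichment of ``query`` in ``ref_set``.

    The reference set is intersected with the universe before computing K;
    the query must be a subset of the universe.  K = 0 (or an empty query)
    leaves expected undefined: the result is returned untestable with NaN
    statistics rather than silently skipped.
    """
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValidationError(f"query genes outside the universe: {extra}")
    n_universe = len(universe)
    if n_universe == 0:
        raise ValidationError("empty universe")
    k_in = len(ref_set & universe)
    n_query = len(query)
    if k_in == 0 or n_query == 0:
        return EnrichmentResult(
            set_name, n_universe, k_in, n_query,
            observed=len(query & ref_set), expected=float("nan"),
            ratio=float("nan"), p_value=float("nan"), testable=False,
        )
    observed = len(query & ref_set & universe)
    expected = n_query * k_in / n_universe
    # P(X >= observed) for X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(observed - 1, n_universe, k_in, n_query))
    return EnrichmentResult(
        set_name, n_universe, k_in, n_query,
        observed=observed, expected=expected, ratio=observed / expected,
        p_value=min(1.0, max(p, 0.0)),
    )


def enrich_collection(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Enrich ``query`` against every set of the collection.

    BH adjustment runs across the testable sets of this call only (untestable
    sets do not inflate m); significance is adj_p < alpha.  Results come back
    in the collection's set-name order.
    """
    if len(collection) == 0:
        raise ValidationError("empty gene-set collection")
    results = [
        hypergeom_enrichment(query, collection[name].members, universe, name)
        for name in collection.names()
    ]
    testable = [r for r in results if r.testable]
    if testable:
        adj = bh_adjust([r.p_value for r in testable])
        for r, q in zip(testable, adj):
            r.adj_p = float(q)
            r.significant = bool(q < alpha)
    return results


@dataclass
class TFEnrichmentResult:
    """Directional enrichment of one TF's targets in up vs down genes.

    ``display_score`` is signed: positive when the up-side adjusted p is
    smaller (up-dominant), negative when the down side dominates, zero on a
    tie; magnitude is -log10 of the dominant adjusted p.
    """

    tf_name: str
    up_result: EnrichmentResult
    down_result: EnrichmentResult
    display_score: float


def _signed_score(adj_up: float, adj_down: float) -> float:
    up_nan, down_nan = math.isnan(adj_up), math.isnan(adj_down)
    if up_nan and down_nan:
        return 0.0
    if down_nan or (not up_nan and adj_up < adj_down):
        return -math.log10(max(adj_up, _P_FLOOR))
    if up_nan or adj_down < adj_up:
        return math.log10(max(adj_down, _P_FLOOR))
    return 0.0


def tf_enrichment(
    up: set[str],
    down: set[str],
    tf_targets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> list[TFEnrichmentResult]:
    """Enrich each TF's target set in the up and down signatures separately.

    BH adjustment runs within each direction across the TFs testable on that
    side.  Swapping the up and down sets negates every display_score.
    """
    if up & down:
        raise ValidationError("up and down sets must be disjoint")
    up_results = enrich_collection(up, tf_targets, universe, alpha=alpha) \
        if up else [
            hypergeom_enrichment(set(), tf_targets[n].members, universe, n)
            for n in tf_targets.names()
        ]
    down_results = enrich_collection(down, tf_targets, universe, alpha=alpha) \
        if down else [
            hypergeom_enrichment(set(), tf_targets[n].members, universe, n)
            for n in tf_targets.names()
        ]
    out = []
    for ur, dr in zip(up_results, down_results):
        out.append(
            TFEnrichmentResult(ur.set_name, ur, dr, _signed_score(ur.adj_p, dr.adj_p))
        )
    return out


@dataclass
class CellStateProjection:
    """Bulk fold changes of one cell state's marker genes.

    Summaries (median, quartiles) and the member-vs-non-member rank test are
    reported only when at least ``min_members`` markers are measured in the
    bulk table; otherwise the state is flagged untestable.
    """

    state_name: str
    n_markers: int
    n_found: int
    median: float
    q1: float
    q3: float
    p_value: float
    testable: bool


def project_cell_states(
    table: DETable,
    markers: GeneSetCollection,
    min_members: int = 3,
) -> list[CellStateProjection]:
    """Project marker gene sets onto a bulk DE table's fold changes.

    Per state: collect the log2fc of marker genes present in the table and
    report median and interquartile range plus a two-sided Mann-Whitney test
    of member vs non-member fold changes.
    """
    if len(markers) == 0:
        raise ValidationError("empty marker collection")
    fc = table.log2fc_by_gene()
    out = []
    for name in markers.names():
        members = markers[name].members
        found = sorted(members & set(fc.index))
        if len(found) < min_members:
            out.append(
                CellStateProjection(
                    name, len(members), len(found),
                    float("nan"), float("nan"), float("nan"), float("nan"),
                    testable=False,
                )
            )
            continue
        member_fc = fc.loc[found].to_numpy()
        other_fc = fc.drop(index=found).to_numpy()
        if other_fc.size == 0:
            p = float("nan")
        else:
            p = float(
                stats.mannwhitneyu(
                    member_fc, other_fc, alternative="two-sided", method="auto"
                ).pvalue
            )
        q1, med, q3 = np.percentile(member_fc, [25, 50, 75])
        out.append(
            CellStateProjection(
                name, len(members), len(found),
                float(med), float(q1), float(q3), p, testable=True,
            )
        )
    return out
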