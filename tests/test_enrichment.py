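"""Hypergeometric enrichment, TF-target direction, marker projection."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from sigcross import (
    DETable,
    GeneSetCollection,
    ValidationError,
    enrich_collection,
    hypergeom_enrichment,
    project_cell_states,
    tf_enrichment,
)


def hypergeom_tail_brute(N, K, n, obs):
    """Upper-tail P(X >= obs) by direct combinatorial summation."""
    return sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(obs, min(n, K) + 1)
        if n - j <= N - K
    ) / comb(N, n)


def make_universe(N):
    return [f"u{i:03d}" for i in range(N)]


def config_sets(N, K, n, obs):
    universe = make_universe(N)
    ref = set(universe[:K])
    query = set(universe[:obs]) | set(universe[K:K + (n - obs)])
    return query, ref, set(universe)


class TestHypergeomEnrichment:
    def test_worked_example(self):
        query, ref, universe = config_sets(10, 4, 5, 4)
        r = hypergeom_enrichment(query, ref, universe)
        assert r.expected == pytest.approx(2.0)
        assert r.ratio == pytest.approx(2.0)
        assert r.p_value == pytest.approx(6 / 252)

    def test_zero_observed_gives_p_one(self):
        query, ref, universe = config_sets(10, 3, 4, 0)
        assert hypergeom_enrichment(query, ref, universe).p_value \
            == pytest.approx(1.0)

    def test_tail_sum_example(self):
        query, ref, universe = config_sets(100, 10, 20, 5)
        r = hypergeom_enrichment(query, ref, universe)
        assert r.expected == pytest.approx(2.0) and r.ratio == pytest.approx(2.5)
        assert r.p_value == pytest.approx(hypergeom_tail_brute(100, 10, 20, 5))

    def test_query_outside_universe_is_error(self):
        with pytest.raises(ValidationError):
            hypergeom_enrichment({"zz"}, {"a"}, {"a", "b"})

    def test_empty_k_after_restriction_is_untestable(self):
        r = hypergeom_enrichment({"a"}, {"zz"}, {"a", "b"})
        assert not r.testable and np.isnan(r.p_value)

    def test_matches_brute_force_small_universes(self):
        for N in range(2, 16):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for obs in range(max(0, n + K - N), min(n, K) + 1):
                        query, ref, universe = config_sets(N, K, n, obs)
                        r = hypergeom_enrichment(query, ref, universe)
                        assert r.p_value == pytest.approx(
                            hypergeom_tail_brute(N, K, n, obs), abs=1e-12
                        ), (N, K, n, obs)

    def test_ratio_centered_at_one_under_uniform_queries(self):
        rng = np.random.default_rng(21)
        universe = make_universe(200)
        ref = set(universe[:40])
        n = 50
        ratios = []
        for _ in range(1000):
            query = set(rng.choice(universe, size=n, replace=False))
            ratios.append(
                hypergeom_enrichment(query, ref, set(universe)).ratio
            )
        # SE of the mean ratio under hypergeometric sampling
        var = (n * 0.2 * 0.8 * (200 - n) / 199) / (n * 40 / 200) ** 2
        assert np.mean(ratios) == pytest.approx(1.0, abs=3 * np.sqrt(var / 1000))


class TestEnrichCollection:
    def test_single_set_adj_equals_raw(self):
        universe = set(make_universe(20))
        coll = GeneSetCollection.from_dict({"S": set(make_universe(20)[:5])})
        res = enrich_collection(set(make_universe(20)[:3]), coll, universe)
        assert res[0].adj_p == pytest.approx(res[0].p_value)

    def test_untestable_sets_excluded_from_bh(self):
        universe = set(make_universe(10))
        coll = GeneSetCollection.from_dict(
            {"S": set(make_universe(10)[:4]), "empty": {"not_in_universe"}}
        )
        res = enrich_collection(set(make_universe(10)[:3]), coll, universe)
        by_name = {r.set_name: r for r in res}
        assert not by_name["empty"].testable
        assert by_name["S"].adj_p == pytest.approx(by_name["S"].p_value)

    def test_adding_p_one_set_never_decreases_adj_p(self):
        universe = set(make_universe(30))
        base = {"S1": set(make_universe(30)[:6]),
                "S2": set(make_universe(30)[6:12])}
        query = set(make_universe(30)[:5])
        res_before = enrich_collection(query, GeneSetCollection.from_dict(base),
                                       universe)
        # a set disjoint from the query has observed 0 and p = 1
        base["null_set"] = set(make_universe(30)[20:25])
        res_after = enrich_collection(query, GeneSetCollection.from_dict(base),
                                      universe)
        before = {r.set_name: r.adj_p for r in res_before}
        after = {r.set_name: r.adj_p for r in res_after}
        for name in before:
            assert after[name] >= before[name] - 1e-12


class TestTFEnrichment:
    def test_targets_equal_up_set_is_up_dominant(self):
        universe = set(make_universe(100))
        up = set(make_universe(100)[:10])
        coll = GeneSetCollection.from_dict({"TF1": up})
        res = tf_enrichment(up, set(), coll, universe)
        assert res[0].display_score > 0
        assert res[0].up_result.observed == 10

    def test_disjoint_targets_score_zero(self):
        universe = set(make_universe(30))
        coll = GeneSetCollection.from_dict({"TF1": set(make_universe(30)[20:])})
        res = tf_enrichment(set(make_universe(30)[:5]),
                            set(make_universe(30)[5:10]), coll, universe)
        assert res[0].up_result.p_value == pytest.approx(1.0)
        assert res[0].down_result.p_value == pytest.approx(1.0)
        assert res[0].display_score == 0.0

    def test_up_side_matches_hypergeom_example(self):
        universe = set(make_universe(100))
        targets = set(make_universe(100)[:10])
        up = set(make_universe(100)[:5]) | set(make_universe(100)[10:25])
        coll = GeneSetCollection.from_dict({"TF1": targets})
        res = tf_enrichment(up, set(), coll, universe)
        r = res[0].up_result
        assert r.expected == pytest.approx(2.0) and r.ratio == pytest.approx(2.5)
        assert r.p_value == pytest.approx(hypergeom_tail_brute(100, 10, 20, 5))

    def test_swapping_up_down_negates_scores(self):
        rng = np.random.default_rng(3)
        universe = make_universe(80)
        coll = GeneSetCollection.from_dict(
            {f"TF{i}": set(rng.choice(universe, size=12, replace=False))
             for i in range(5)}
        )
        up = set(universe[:15])
        down = set(universe[15:30])
        fwd = tf_enrichment(up, down, coll, set(universe))
        rev = tf_enrichment(down, up, coll, set(universe))
        for f, r in zip(fwd, rev):
            assert f.display_score == pytest.approx(-r.display_score)

    def test_overlapping_up_down_is_error(self):
        coll = GeneSetCollection.from_dict({"TF1": {"a"}})
        with pytest.raises(ValidationError):
            tf_enrichment({"a"}, {"a"}, coll, {"a", "b"})


def bulk_table(values: dict) -> DETable:
    return DETable(
        pd.DataFrame({"gene": list(values), "log2fc": list(values.values()),
                      "pvalue": 0.5}),
        label="bulk",
    )


class TestProjectCellStates:
    def test_median_and_exact_p(self):
        table = bulk_table({"g1": 2.0, "g2": 4.0, "g3": 0.0, "g4": -0.5})
        markers = GeneSetCollection.from_dict({"S1": {"g1", "g2"}})
        res = project_cell_states(table, markers, min_members=2)
        assert res[0].median == pytest.approx(3.0)
        # members hold the two largest of 4 values: two-sided exact MW p
        assert res[0].p_value == pytest.approx(2 / 6)

    def test_absent_markers_untestable(self):
        table = bulk_table({"g1": 1.0, "g2": 0.0, "g3": 2.0})
        markers = GeneSetCollection.from_dict({"S1": {"zz", "yy", "xx"}})
        res = project_cell_states(table, markers)
        assert not res[0].testable and np.isnan(res[0].median)

    def test_random_markers_center_on_global_median(self):
        rng = np.random.default_rng(17)
        values = {f"g{i}": float(v) for i, v in
                  enumerate(rng.normal(size=200))}
        table = bulk_table(values)
        global_median = np.median(list(values.values()))
        medians = []
        for _ in range(100):
            members = rng.choice(list(values), size=20, replace=False)
            markers = GeneSetCollection.from_dict({"S": set(members)})
            medians.append(project_cell_states(table, markers)[0].median)
        se = np.std(medians, ddof=1) / 10
        assert np.mean(medians) == pytest.approx(global_median, abs=3 * se)
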