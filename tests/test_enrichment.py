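import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raftdiff.datamodel import GeneSet, GeneSetCollection
from raftdiff.enrichment import (
    bh_adjust,
    bonferroni_adjust,
    enrich,
    fold_enrichment,
    ora_test,
    overlap_stats,
)
from raftdiff.io import ValidationError


def brute_force_upper_tail(N, K, n, k):
    """P(>= k term genes in the query) by exhaustive enumeration of draws."""
    population = list(range(N))
    term = set(range(K))
    hits = total = 0
    for draw in combinations(population, n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


def brute_force_bh(p):
    """Step-up definition: q(i) = min_{j>=i} min(1, m p(j)/j) on sorted p."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * p[i] / rank))
        q[i] = running
    return q


class TestOraTest:
    def test_saturated_case(self):
        pop = {"A", "B", "C"}
        k, p = ora_test(pop, pop, pop)
        assert k == 3 and p == pytest.approx(1.0)

    def test_zero_overlap_p_is_one(self):
        k, p = ora_test({"A"}, {"B"}, {"A", "B", "C"})
        assert k == 0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("N, K, n", [(20, 5, 5), (12, 4, 6), (10, 3, 3)])
    def test_equals_exhaustive_enumeration(self, N, K, n):
        population = {f"g{i}" for i in range(N)}
        term = {f"g{i}" for i in range(K)}
        for k in range(K + 1):
            query = {f"g{i}" for i in range(k)} | {
                f"g{K + i}" for i in range(n - k)}
            got_k, got_p = ora_test(query, term, population)
            assert got_k == k
            assert got_p == pytest.approx(brute_force_upper_tail(N, K, n, k),
                                          rel=1e-9)

    def test_query_outside_population_lists_offenders(self):
        with pytest.raises(ValidationError, match="Zzz1"):
            ora_test({"A", "Zzz1"}, {"A"}, {"A", "B"})

    def test_ease_variant_is_more_conservative(self):
        population = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        query = {f"g{i}" for i in range(3)} | {"g10", "g11"}
        _, p = ora_test(query, term, population)
        _, p_ease = ora_test(query, term, population, ease=True)
        assert p_ease > p


class TestFoldEnrichment:
    @pytest.mark.parametrize("k, n, K, N, expected", [
        (5, 50, 100, 1000, 1.0),
        (10, 50, 100, 10000, 20.0),
    ])
    def test_values(self, k, n, K, N, expected):
        assert fold_enrichment(k, n, K, N) == pytest.approx(expected)

    def test_zero_count_is_missing(self):
        assert math.isnan(fold_enrichment(0, 50, 100, 1000))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 100, 1000)


class TestCorrections:
    def test_bonferroni(self):
        assert bonferroni_adjust(0.01, 5) == pytest.approx(0.05)
        assert bonferroni_adjust(0.3, 5) == 1.0
        assert bonferroni_adjust(0.2, 1) == pytest.approx(0.2)

    def test_bh_hand_example(self):
        assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_bh_single_value_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @given(p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                      min_size=1, max_size=40))
    @settings(deadline=None, max_examples=200)
    def test_bh_matches_step_up_definition(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_bh_monotone_in_sorted_order(self):
        rng = np.random.default_rng(11)
        p = rng.random(30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestEnrich:
    def collection(self):
        population = frozenset(f"G{i}" for i in range(30))
        return GeneSetCollection([
            GeneSet("T1", "CC", "membrane", frozenset({"G0", "G1", "G2", "G3"})),
            GeneSet("T2", "CC", "synapse", frozenset({"G0", "G4"})),
            GeneSet("T3", "BP", "transport", frozenset({"G5", "G6", "G7"})),
        ], population)

    def test_rows_internally_consistent(self):
        query = {f"G{i}" for i in range(6)}
        rows = enrich(query, self.collection())
        for row in rows:
            assert row.percent == pytest.approx(100 * row.count / len(query))
            assert row.bonferroni >= row.p_value - 1e-15
            assert row.benjamini >= row.p_value - 1e-15
            assert row.bonferroni <= 1.0 and row.benjamini <= 1.0
            if row.count:
                term_size = len(next(
                    e.genes for e in self.collection().entries
                    if e.term_id == row.term_id))
                assert row.fold_enrichment == pytest.approx(
                    (row.count / len(query)) / (term_size / 30))

    def test_corrections_within_namespace(self):
        query = {f"G{i}" for i in range(6)}
        rows = {r.term_id: r for r in enrich(query, self.collection())}
        # CC has two terms, BP one: Bonferroni factors differ
        assert rows["T3"].bonferroni == pytest.approx(rows["T3"].p_value)
        assert rows["T1"].bonferroni == pytest.approx(
            min(1.0, 2 * rows["T1"].p_value))


class TestOverlap:
    def test_basic_counts(self):
        s = overlap_stats({"a", "b", "c"}, {"b", "c", "d"}, denominator=3)
        assert s.overlap_count == 2
        assert s.percent_of_query == pytest.approx(66.7, abs=0.1)

    def test_symbol_normalization(self):
        s = overlap_stats({"THY1", "Flot1"}, {"thy1"})
        assert s.overlap == {"Thy1"}

    def test_denominator_override(self):
        s = overlap_stats({"a"}, {"a"}, denominator=85)
        assert s.percent_of_query == pytest.approx(100 / 85)

    def test_bad_denominator(self):
        with pytest.raises(ValueError):
            overlap_stats({"a"}, {"a"}, denominator=0)
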