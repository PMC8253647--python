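"""Enrichment statistics checked against independent exact oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.core import GeneSet, NetpharmError
from netpharm.enrichment import bh_adjust, bubble_export, enrich, hypergeom_p


def exact_upper_tail(k, n, K, N):
    """Oracle: P(X >= k) as an exact rational from binomial counting."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    )
    return Fraction(hits, total)


def geneset(label, genes):
    return GeneSet(label, frozenset(genes))


class TestHypergeomP:
    def test_k_zero_is_one(self):
        assert hypergeom_p(0, 5, 5, 20) == 1.0

    def test_enumerated_draw_example(self):
        # all C(10,4) draws from a 10-element universe with a 5-element
        # pathway; the only draws with k=4 choose 4 of the 5 members
        universe = range(10)
        pathway = set(range(5))
        draws = list(itertools.combinations(universe, 4))
        hits = sum(1 for d in draws if len(pathway & set(d)) >= 4)
        assert Fraction(hits, len(draws)) == Fraction(5, 210)
        assert hypergeom_p(4, 4, 5, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_degenerate_universe(self):
        assert hypergeom_p(3, 3, 12, 12) == 1.0
        assert hypergeom_p(2, 5, 12, 12) == 1.0

    def test_infeasible_margins(self):
        with pytest.raises(ValueError):
            hypergeom_p(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_p(1, 5, 11, 10)

    def test_matches_exact_oracle_all_margins_up_to_12(self):
        # exhaustive agreement with the rational-arithmetic oracle
        for N in range(1, 13):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(n, K) + 1):
                        p = hypergeom_p(k, n, K, N)
                        oracle = float(exact_upper_tail(k, n, K, N))
                        assert p == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    def test_matches_one_sided_fisher(self):
        from scipy.stats import fisher_exact

        for k, n, K, N in [(4, 10, 12, 40), (0, 6, 9, 30), (7, 9, 10, 25)]:
            table = [[k, n - k], [K - k, N - K - n + k]]
            _, fisher_p = fisher_exact(table, alternative="greater")
            assert hypergeom_p(k, n, K, N) == pytest.approx(fisher_p, rel=1e-9)

    @given(st.integers(1, 25), st.data())
    @settings(max_examples=60, deadline=None)
    def test_non_increasing_in_k(self, N, data):
        n = data.draw(st.integers(0, N))
        K = data.draw(st.integers(0, N))
        ps = [hypergeom_p(k, n, K, N) for k in range(min(n, K) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_null_simulation_is_conservative(self):
        # queries drawn uniformly from the universe: the p-value
        # distribution must be stochastically >= uniform
        rng = np.random.default_rng(2024)
        N, K, n = 60, 20, 15
        reps = 1000
        pathway = set(range(K))
        hits = 0
        for _ in range(reps):
            query = rng.choice(N, size=n, replace=False)
            k = len(pathway & set(query.tolist()))
            if hypergeom_p(k, n, K, N) < 0.05:
                hits += 1
        se = math.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 2 * se


class TestBH:
    def test_hand_computed_stepup(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 -> all 0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_never_decreases_and_preserves_ranking(self, ps):
        adj = bh_adjust(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        ranked = [adj[i] for i in order]
        assert all(x <= y for x, y in zip(ranked, ranked[1:]))

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        _, expected, _, _ = multipletests(ps, method="fdr_bh")
        assert bh_adjust(ps) == pytest.approx(list(expected), rel=1e-9)


class TestEnrich:
    def _collection(self):
        return [
            geneset("HIT", {"A", "B", "C", "D"}),
            geneset("MISS1", {"E", "F", "G", "H"}),
            geneset("MISS2", {"I", "J", "K", "L"}),
        ]

    def test_identical_pathway_ranks_first(self):
        query = geneset("q", {"A", "B", "C", "D"})
        results = enrich(query, self._collection(), p_max=1.1, top_n=None)
        assert results[0].pathway == "HIT"
        assert results[0].k == 4

    def test_filter_and_truncation(self):
        query = geneset("q", {"A", "B", "C", "D"})
        results = enrich(query, self._collection(), p_max=0.05)
        assert [r.pathway for r in results] == ["HIT"]

    def test_query_genes_outside_universe_dropped(self, caplog):
        query = geneset("q", {"A", "B", "ZZZ"})
        with caplog.at_level("WARNING", logger="netpharm.enrichment"):
            results = enrich(query, self._collection(), p_max=1.1, top_n=None)
        assert results[0].n == 2
        assert "dropped" in caplog.text

    def test_empty_collection_errors(self):
        with pytest.raises(NetpharmError):
            enrich(geneset("q", {"A"}), [])

    def test_result_invariants(self):
        query = geneset("q", {"A", "B", "E"})
        for r in enrich(query, self._collection(), p_max=1.1, top_n=None):
            assert 0 < r.p <= 1
            assert r.k <= min(r.n, r.K)
            assert r.p_adj >= r.p - 1e-15
            assert 0 <= r.percentage <= 100

    def test_planted_pathway_first_across_seeds(self):
        from netpharm.synth import SimConfig, simulate_all

        wins = 0
        n_seeds = 200
        for seed in range(n_seeds):
            out = simulate_all(SimConfig(seed=seed))
            universe = GeneSet(
                "u", out.target_map.all_genes() | out.disease.genes
            )
            results = enrich(
                out.common, out.pathways, universe=universe, p_max=1.1, top_n=None
            )
            wins += results[0].pathway == out.truth["planted_pathway"]
        assert wins >= 0.95 * n_seeds


class TestBubbleExport:
    def test_percentage_arithmetic(self):
        from netpharm.enrichment import EnrichmentResult

        r = EnrichmentResult("P", k=12, n=48, K=20, N=100, p=0.01, p_adj=0.02)
        assert r.percentage == 25.0

    def test_empty_results_header_only(self, tmp_path):
        p = tmp_path / "bubble.tsv"
        bubble_export([], p)
        lines = p.read_text().splitlines()
        assert lines == ["pathway\tk\tpercentage\tp\tp_adj"]

    def test_round_trip_to_printed_precision(self, tmp_path):
        import pandas as pd

        query = geneset("q", {"A", "B", "C", "D"})
        collection = [
            geneset("HIT", {"A", "B", "C", "D"}),
            geneset("MISS", {"E", "F", "G", "H"}),
        ]
        results = enrich(query, collection, p_max=1.1, top_n=None)
        p = tmp_path / "bubble.tsv"
        bubble_export(results, p)
        back = pd.read_csv(p, sep="\t")
        for row, r in zip(back.itertuples(), results):
            assert row.pathway == r.pathway
            assert row.k == r.k
            assert row.percentage == pytest.approx(r.percentage)
            assert row.p == pytest.approx(r.p)
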