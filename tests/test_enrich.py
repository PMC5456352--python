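"""Hypergeometric enrichment, BH adjustment, Fisher tests, cohesion networks."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from riqtl import (
    GeneSetCollection,
    bh_adjust,
    build_cohesion_network,
    cohesion_fisher_p,
    fisher_exact_2x2,
    hypergeometric_enrichment,
    read_gmt,
    simulate_literature_similarity,
)
from riqtl.enrich import write_gmt


def hypergeom_tail_oracle(N, K, n, k):
    """Upper tail P(X >= k) by direct enumeration of draw counts."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeometric:
    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            N = int(rng.integers(8, 26))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            category = set(rng.choice(universe, size=K, replace=False))
            query = list(rng.choice(universe, size=n, replace=False))
            coll = GeneSetCollection(
                sets={"cat": frozenset(category)}, universe=frozenset(universe)
            )
            res = hypergeometric_enrichment(query, coll)
            k = len(category & set(query))
            assert res.loc["cat", "raw_p"] == pytest.approx(
                hypergeom_tail_oracle(N, K, n, k), abs=1e-12
            )

    def test_perfect_overlap_probability(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection(
            sets={"cat": frozenset(universe[:5])}, universe=frozenset(universe)
        )
        res = hypergeometric_enrichment(universe[:5], coll)
        assert res.loc["cat", "raw_p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert res.loc["cat", "raw_p"] == pytest.approx(6.4499e-5, rel=1e-4)

    def test_zero_overlap_gives_one(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection(
            sets={"cat": frozenset(universe[:5])}, universe=frozenset(universe)
        )
        res = hypergeometric_enrichment(universe[10:15], coll)
        assert res.loc["cat", "raw_p"] == 1.0

    def test_query_equals_universe_is_degenerate(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection(
            sets={"a": frozenset(universe[:3]), "b": frozenset(universe[3:8])},
            universe=frozenset(universe),
        )
        res = hypergeometric_enrichment(universe, coll)
        assert (res["raw_p"] == 1.0).all()
        assert (res["k"] == res["K"]).all()

    def test_outside_query_genes_dropped(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection(
            sets={"cat": frozenset(universe[:5])}, universe=frozenset(universe)
        )
        res = hypergeometric_enrichment(universe[:3] + ["alien"], coll)
        assert res.loc["cat", "n"] == 3


class TestBhAdjust:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_equal_values_unchanged(self):
        assert bh_adjust([0.2])[0] == 0.2
        assert np.allclose(bh_adjust([0.04] * 5), 0.04)

    def test_adjusted_values_dominate_and_stay_ordered(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFisherExact:
    def test_symmetric_table_two_sided_one(self):
        _, _, p_two = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p_two == 1.0

    def test_diagonal_table_enumeration(self):
        _, p_one, p_two = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p_one == pytest.approx(1 / 252, rel=1e-9)
        assert p_two == pytest.approx(2 / 252, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestCohesionNetwork:
    def test_complete_and_empty_graphs(self):
        genes = [f"g{i}" for i in range(20)]
        sim_hi = simulate_literature_similarity(genes, [genes], 1.0, 1.0, 0.0)
        assert build_cohesion_network(genes, sim_hi).graph.number_of_edges() == 190
        sim_lo = simulate_literature_similarity(genes, [], 0.0, 0.0, 0.0)
        assert build_cohesion_network(genes, sim_lo).graph.number_of_edges() == 0

    def test_block_fixture_edge_count_matches_pair_scan(self):
        genes = [f"g{i}" for i in range(30)]
        sim = simulate_literature_similarity(genes, [genes[:10]], 0.9, 0.1, 0.15, seed=4)
        net = build_cohesion_network(genes, sim, 0.6)
        brute = sum(
            1 for a, b in combinations(genes, 2) if sim.value(a, b) > 0.6
        )
        assert net.graph.number_of_edges() == brute

    def test_threshold_is_strict_and_isolated_nodes_kept(self):
        genes = ["a", "b", "c"]
        m = pd.DataFrame(
            [[1.0, 0.6, 0.1], [0.6, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=genes, columns=genes,
        )
        sim = type("S", (), {"genes": genes, "value": lambda s, x, y: float(m.loc[x, y])})()
        net = build_cohesion_network(genes, sim, 0.6)
        assert net.graph.number_of_edges() == 0  # 0.6 > 0.6 is false
        assert set(net.nodes) == set(genes)

    def test_unknown_gene_rejected(self):
        genes = [f"g{i}" for i in range(5)]
        sim = simulate_literature_similarity(genes, [], 0.5, 0.5, 0.0)
        with pytest.raises(ValueError, match="alien"):
            build_cohesion_network(["g0", "alien"], sim)


class TestCohesionFisher:
    def test_equal_rates_not_enriched(self):
        # one above-threshold pair in the set and one in the background:
        # identical cohesion rates, so no enrichment signal
        genes = [f"g{i}" for i in range(20)]
        sim = simulate_literature_similarity(
            genes, [genes[:2], genes[10:12]], 0.9, 0.1, 0.0
        )
        net = build_cohesion_network(genes[:10], sim, 0.6)
        p = cohesion_fisher_p(net, sim, background_genes=genes[10:])
        assert p >= 0.5

    def test_extreme_table_matches_hypergeometric_tail(self):
        # set: all 45 pairs above; background: all 45 pairs below
        # one-sided p = P(X >= 45), X ~ Hypergeom(N=90, K=45, n=45) = 1/C(90,45)
        genes = [f"g{i}" for i in range(20)]
        sim = simulate_literature_similarity(genes, [genes[:10]], 0.9, 0.1, 0.0)
        net = build_cohesion_network(genes[:10], sim, 0.6)
        p = cohesion_fisher_p(net, sim, background_genes=genes[10:])
        assert p == pytest.approx(hypergeom_tail_oracle(90, 45, 45, 45), rel=1e-10)
        assert p == pytest.approx(1 / math.comb(90, 45), rel=1e-10)

    def test_relabel_invariance(self):
        genes = [f"g{i}" for i in range(20)]
        sim = simulate_literature_similarity(genes, [genes[:8]], 0.85, 0.2, 0.1, seed=5)
        net = build_cohesion_network(genes[:8], sim, 0.6)
        p1 = cohesion_fisher_p(net, sim)
        relabel = {g: f"x{g}" for g in genes}
        sim2 = simulate_literature_similarity(
            [relabel[g] for g in genes], [[relabel[g] for g in genes[:8]]],
            0.85, 0.2, 0.1, seed=5,
        )
        net2 = build_cohesion_network([relabel[g] for g in genes[:8]], sim2, 0.6)
        assert cohesion_fisher_p(net2, sim2) == pytest.approx(p1, rel=1e-12)

    def test_p_decreases_with_rising_cohesion(self):
        from riqtl.panel import LiteratureSimilarity

        genes = [f"g{i}" for i in range(24)]
        ps = []
        for within in (0.55, 0.9):  # below vs above the threshold
            m = np.full((24, 24), 0.1)
            m[:10, :10] = within
            m[10:13, 10:13] = 0.9  # cohesive background block: table stays non-degenerate
            np.fill_diagonal(m, 1.0)
            sim = LiteratureSimilarity(genes, pd.DataFrame(m, index=genes, columns=genes))
            net = build_cohesion_network(genes[:10], sim, 0.6)
            ps.append(cohesion_fisher_p(net, sim, background_genes=genes[10:]))
        assert ps[1] < ps[0]

    def test_degenerate_set_rejected(self):
        genes = [f"g{i}" for i in range(6)]
        sim = simulate_literature_similarity(genes, [], 0.5, 0.5, 0.0)
        net = build_cohesion_network(genes[:1], sim, 0.6)
        with pytest.raises(ValueError):
            cohesion_fisher_p(net, sim)


class TestGmt:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            sets={"a": frozenset({"g1", "g2"}), "b": frozenset({"g2", "g3"})},
            descriptions={"a": "first", "b": "second"},
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match="members"):
            read_gmt(path)

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("a\td\tg1\na\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)
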