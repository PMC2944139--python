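import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import meionet as mn
from meionet.errors import UnannotatedGeneError
from meionet.evaluation import (
    EnrichmentQuery,
    compare_observed_random,
    go_term_enrichment,
    hypergeom_upper_tail,
    mean_semantic_similarity,
    node_property_fraction,
    overlap_fraction,
    pair_abundance_classes,
    permutation_baseline,
    precision_coverage,
    semantic_similarity_pair,
    term_probability,
)
def enumeration_upper_tail(t, n, m, k):
    """Oracle: enumerate all C(t, n) draws of n genes from a t-universe."""
    universe = range(t)
    query = set(range(m))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(query & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomUpperTail:
    def test_k_zero_is_certain(self):
        assert hypergeom_upper_tail(EnrichmentQuery(t=10, n=5, m=4, k=0)) == 1.0

    def test_hand_enumerated_value(self):
        q = EnrichmentQuery(t=10, n=5, m=4, k=3)
        assert hypergeom_upper_tail(q) == pytest.approx(66 / 252, abs=1e-12)
        assert hypergeom_upper_tail(q) == pytest.approx(
            enumeration_upper_tail(10, 5, 4, 3), abs=1e-12
        )

    def test_forced_overlap_is_one(self):
        assert hypergeom_upper_tail(EnrichmentQuery(t=5, n=5, m=5, k=5)) == pytest.approx(1.0)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentQuery(t=10, n=2, m=4, k=3)

    @pytest.mark.parametrize("t", [5, 8])
    def test_matches_enumeration_small_universes(self, t):
        for n in range(t + 1):
            for m in range(t + 1):
                for k in range(min(m, n) + 1):
                    got = hypergeom_upper_tail(EnrichmentQuery(t=t, n=n, m=m, k=k))
                    assert got == pytest.approx(
                        enumeration_upper_tail(t, n, m, k), abs=1e-10
                    ), (t, n, m, k)

    def test_point_masses_sum_to_one(self):
        for t, n, m in [(12, 5, 7), (9, 9, 3), (11, 4, 4)]:
            total = sum(
                math.comb(m, x) * math.comb(t - m, n - x)
                for x in range(max(0, n - (t - m)), min(m, n) + 1)
            )
            assert total == math.comb(t, n)
            masses = [
                hypergeom_upper_tail(EnrichmentQuery(t=t, n=n, m=m, k=k))
                - (
                    hypergeom_upper_tail(EnrichmentQuery(t=t, n=n, m=m, k=k + 1))
                    if k + 1 <= min(m, n)
                    else 0.0
                )
                for k in range(min(m, n) + 1)
            ]
            assert sum(masses) == pytest.approx(1.0, abs=1e-12)


class TestTermProbability:
    def test_single_gene_chain_all_one(self):
        dag = nx.DiGraph([("B", "A"), ("A", "root")])
        p = term_probability(dag, {"g": {"B"}}, {"g"})
        assert p == {"B": 1.0, "A": 1.0, "root": 1.0}

    def test_leaf_fraction(self):
        dag = nx.DiGraph([("L", "root")])
        annotations = {f"g{i}": {"L"} if i < 2 else {"root"} for i in range(10)}
        p = term_probability(dag, annotations, set(annotations))
        assert p["L"] == pytest.approx(0.2)
        assert p["root"] == 1.0

    def test_monotone_along_edges(self, six_term_resources):
        res = six_term_resources
        for child, parent in res.dag.edges:
            assert res.term_prob[parent] >= res.term_prob[child]

    def test_cycle_detected(self):
        dag = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError, match="cycle"):
            term_probability(dag, {}, set())


class TestSemanticSimilarity:
    def test_root_only_sharing_scores_zero(self, six_term_resources):
        # g1 (under A-branch) vs g4 (under B-branch): only root is shared
        assert semantic_similarity_pair("g1", "g4", six_term_resources) == 0.0

    def test_same_term_negative_log10(self):
        dag = nx.DiGraph([("L", "root")])
        annotations = {"a": frozenset({"L"}), "b": frozenset({"L"})}
        corpus = {"a", "b"} | {f"bg{i}" for i in range(198)}
        annotations.update({f"bg{i}": frozenset({"root"}) for i in range(198)})
        res = mn.build_go_resources(dag, annotations, corpus)
        assert res.term_prob["L"] == pytest.approx(0.01)
        assert semantic_similarity_pair("a", "b", res) == pytest.approx(2.0)

    def test_matches_bruteforce_ancestor_intersection(self, six_term_resources):
        res = six_term_resources
        genes = [f"g{i}" for i in range(1, 11)]

        def brute(g1, g2):
            def closure(g):
                out = set()
                for t in res.annotations[g]:
                    frontier = [t]
                    while frontier:
                        node = frontier.pop()
                        if node not in out:
                            out.add(node)
                            frontier.extend(res.dag.successors(node))
                return out

            shared = closure(g1) & closure(g2)
            return -math.log10(min(res.term_prob[t] for t in shared))

        for g1, g2 in itertools.combinations(genes, 2):
            expected = brute(g1, g2)
            got = semantic_similarity_pair(g1, g2, res)
            assert got == pytest.approx(expected, abs=1e-12), (g1, g2)
            assert got == semantic_similarity_pair(g2, g1, res)
            assert got >= 0

    def test_unannotated_gene_raises_and_mean_skips(self, six_term_resources):
        with pytest.raises(UnannotatedGeneError):
            semantic_similarity_pair("g1", "nope", six_term_resources)
        result = mean_semantic_similarity(
            [("g1", "g2"), ("g1", "nope")], six_term_resources
        )
        assert result.n_scored == 1 and result.n_skipped == 1

    def test_mean_of_two_scores(self, six_term_resources):
        res = six_term_resources
        s1 = semantic_similarity_pair("g1", "g2", res)
        s2 = semantic_similarity_pair("g1", "g4", res)
        got = mean_semantic_similarity([("g1", "g2"), ("g1", "g4")], res)
        assert got.mean == pytest.approx((s1 + s2) / 2)


class TestGoTermEnrichment:
    def test_term_matching_query_is_most_enriched(self, six_term_resources):
        universe = {f"g{i}" for i in range(1, 11)}
        table = go_term_enrichment({"g1", "g2"}, universe, six_term_resources)
        assert table.iloc[0]["term"] == "C"  # exactly the query genes
        assert table.iloc[0]["p"] == pytest.approx(1 / 45)  # C(2,2)/C(10,2)

    def test_root_term_p_is_one(self, six_term_resources):
        universe = {f"g{i}" for i in range(1, 11)}
        table = go_term_enrichment({"g1"}, universe, six_term_resources)
        root = table[table["term"] == "root"]
        assert root["p"].iloc[0] == pytest.approx(1.0)

    def test_terms_without_query_genes_absent(self, six_term_resources):
        universe = {f"g{i}" for i in range(1, 11)}
        table = go_term_enrichment({"g4"}, universe, six_term_resources)
        assert "C" not in set(table["term"])

    def test_empty_query_rejected(self, six_term_resources):
        with pytest.raises(ValueError):
            go_term_enrichment(set(), {"g1"}, six_term_resources)


def pairs_df(pairs, p_values=None):
    return pd.DataFrame(
        {
            "metagene_a": [a for a, b in pairs],
            "metagene_b": [b for a, b in pairs],
            "p_value": p_values or np.linspace(0.001, 0.5, len(pairs)),
        }
    )


class TestPrecisionCoverage:
    MEMBERS = {m: (f"{m}_y",) for m in "abcdefgh"}

    def test_all_metagenes_known_gives_precision_one(self):
        table = pairs_df([("a", "b"), ("c", "d")])
        known = {f"{m}_y" for m in "abcd"}
        curve = precision_coverage(table, known, self.MEMBERS, increment=2)
        assert curve["precision"].tolist() == [1.0]
        assert curve["coverage"].tolist() == [4]

    def test_no_known_genes_in_network(self):
        table = pairs_df([("a", "b"), ("c", "d")])
        curve = precision_coverage(table, {"zz"}, self.MEMBERS, increment=1)
        assert (curve["precision"] == 0).all()
        assert (curve["coverage"] == 0).all()

    def test_hand_counted_fixture(self):
        # top-1 pair: {a,b}, a known -> precision 1/2, coverage 1
        # top-2: {a,b,c,d}, a,d known -> 2/4, coverage 2
        # top-4: {a..f}, a,d known -> 2/6, coverage 2
        table = pairs_df([("a", "b"), ("c", "d"), ("a", "e"), ("e", "f")])
        known = {"a_y", "d_y"}
        curve = precision_coverage(table, known, self.MEMBERS, increment=1)
        assert curve["precision"].tolist() == pytest.approx([0.5, 0.5, 2 / 5, 2 / 6])
        assert curve["coverage"].tolist() == [1, 2, 2, 2]

    def test_precision_invariant_to_order_within_depth(self):
        table = pairs_df([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")])
        known = {"a_y", "e_y"}
        full = precision_coverage(table, known, self.MEMBERS, increment=4)
        swapped = pd.concat(
            [table.iloc[[2, 0, 3, 1]]], ignore_index=True
        )
        full2 = precision_coverage(swapped, known, self.MEMBERS, increment=4)
        assert full["precision"].tolist() == full2["precision"].tolist()

    def test_empty_known_set_rejected(self):
        with pytest.raises(ValueError):
            precision_coverage(pairs_df([("a", "b")]), set(), self.MEMBERS)


class TestPermutationBaseline:
    MEMBERS = {m: (f"{m}_y",) for m in "abcdefgh"}

    def test_all_known_gives_flat_one_sd_zero(self):
        table = pairs_df([("a", "b"), ("c", "d")])
        known = {f"{m}_y" for m in "abcd"}
        baseline, samples = permutation_baseline(
            table, known, self.MEMBERS, trials=5, seed=1, increment=1
        )
        assert (baseline["random_mean"] == 1.0).all()
        assert (baseline["random_sd"] == 0.0).all()

    def test_seeded_reproducibility(self):
        table = pairs_df([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")])
        known = {"a_y", "e_y"}
        b1, s1 = permutation_baseline(table, known, self.MEMBERS, trials=4, seed=9, increment=1)
        b2, s2 = permutation_baseline(table, known, self.MEMBERS, trials=4, seed=9, increment=1)
        assert np.array_equal(s1, s2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_concentrated_known_genes_beat_baseline(self, small_scenario, small_result):
        table = small_result.scored["Y-Mm"]
        members = small_result.metagene_members("yeast")
        known = small_scenario.truth.known_genes
        curve = precision_coverage(table, known, members, increment=100)
        baseline, _ = permutation_baseline(
            table, known, members, trials=20, seed=3, increment=100
        )
        assert curve["precision"].iloc[0] > baseline["random_mean"].iloc[0]


class TestCompareObservedRandom:
    def test_identical_samples_pooled_p_near_one(self):
        trials = np.tile([0.5, 0.5, 0.5], (10, 1))
        out = compare_observed_random([0.5, 0.5, 0.5], trials)
        assert out["pooled"] == pytest.approx(1.0)

    def test_separated_distributions_tiny_p(self):
        rng = np.random.default_rng(2)
        trials = rng.normal(0.1, 0.01, size=(50, 4))
        out = compare_observed_random([0.9, 0.92, 0.88, 0.91], trials)
        assert out["pooled"] < 1e-3
        assert all(p < 1e-3 for p in out["per_depth"])

    def test_single_depth_pools_only(self):
        trials = np.random.default_rng(0).normal(0.2, 0.05, size=(30, 1))
        out = compare_observed_random([0.8], trials)
        assert len(out["per_depth"]) == 1
        assert not math.isnan(out["per_depth"][0])


class TestOverlapFractions:
    MEMBERS = {m: (f"{m}_y",) for m in "abcdefgh"}
    PAIRS = pairs_df([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")])

    def test_full_relation_gives_one(self):
        relation = {(f"{a}_y", f"{b}_y") for a in "abcdefgh" for b in "abcdefgh" if a < b}
        table, _ = overlap_fraction(
            self.PAIRS, relation, self.MEMBERS, random_trials=3, increment=4
        )
        assert table["observed"].tolist() == [1.0]

    def test_disjoint_relation_gives_zero(self):
        table, _ = overlap_fraction(
            self.PAIRS, {("x_y", "z_y")}, self.MEMBERS, random_trials=3, increment=4
        )
        assert table["observed"].tolist() == [0.0]

    def test_half_overlap_by_hand(self):
        relation = {("a_y", "b_y"), ("e_y", "f_y")}
        table, _ = overlap_fraction(
            self.PAIRS, relation, self.MEMBERS, random_trials=3, increment=4
        )
        assert table["observed"].tolist() == [0.5]

    def test_co_group_mode(self):
        groups = {"a_y": "cpx1", "b_y": "cpx1", "c_y": "cpx2", "d_y": "cpx9"}
        table, _ = overlap_fraction(
            self.PAIRS, groups, self.MEMBERS, mode="co-group",
            random_trials=3, increment=4,
        )
        assert table["observed"].tolist() == [0.25]

    def test_node_property_fraction_extremes_and_mixed(self):
        everything = {f"{m}_y" for m in "abcdefgh"}
        t_all, _ = node_property_fraction(
            self.PAIRS, everything, self.MEMBERS, random_trials=3, increment=4
        )
        assert t_all["observed"].tolist() == [1.0]
        t_mixed, _ = node_property_fraction(
            self.PAIRS, {"a_y", "c_y", "e_y"}, self.MEMBERS, random_trials=3, increment=4
        )
        assert t_mixed["observed"].tolist() == [3 / 8]
        with pytest.raises(ValueError):
            node_property_fraction(self.PAIRS, set(), self.MEMBERS)


class TestPairAbundanceClasses:
    def network(self, edges):
        from meionet.orderstats import CoexpressionNetwork

        return CoexpressionNetwork(
            name="N",
            studies=("s1", "s2"),
            eligible_types=frozenset({"YMH"}),
            edges=pairs_df(edges),
        )

    def metagenes(self, ids):
        return {
            m: mn.Metagene(
                id=m, mtype="YMH", members={"yeast": (f"{m}_y",), "mouse": (f"{m}_m",)}
            )
            for m in ids
        }

    ORG = {"s1": "yeast", "s2": "mouse"}

    def test_all_high_single_cell(self):
        mgs = self.metagenes("ab")
        labels = {
            "s1": {"a_y": "high", "b_y": "high"},
            "s2": {"a_m": "high", "b_m": "high"},
        }
        out = pair_abundance_classes(self.network([("a", "b")]), mgs, self.ORG, labels)
        assert out["fractions"].loc["high,high", "high,high"] == 1.0

    def test_hand_labeled_contingency(self):
        mgs = self.metagenes("abcd")
        labels = {
            "s1": {"a_y": "high", "b_y": "low", "c_y": "low", "d_y": "low"},
            "s2": {"a_m": "high", "b_m": "high", "c_m": "high", "d_m": "low"},
        }
        out = pair_abundance_classes(
            self.network([("a", "b"), ("c", "d")]), mgs, self.ORG, labels
        )
        assert out["contingency"].loc["low,high", "high,high"] == 1
        assert out["contingency"].loc["low,low", "low,high"] == 1
        assert out["fractions"].to_numpy().sum() == pytest.approx(1.0)

    def test_missing_class_skips_edge(self):
        mgs = self.metagenes("ab")
        labels = {"s1": {"a_y": "high"}, "s2": {"a_m": "high", "b_m": "low"}}
        out = pair_abundance_classes(self.network([("a", "b")]), mgs, self.ORG, labels)
        assert out["n_skipped"] == 1
        assert len(out["per_edge"]) == 0
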