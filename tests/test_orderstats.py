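import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meionet.errors import ConfigError
from meionet.orderstats import (
    build_network,
    extract_seed_modules,
    joint_orderstat_cdf,
    network_intersection,
    score_conserved_pairs,
)


def monte_carlo_cdf(ratios, n_draws, rng):
    """Independent oracle: fraction of sorted uniform draws below bounds."""
    bounds = np.sort(np.asarray(ratios, dtype=float))
    u = np.sort(rng.uniform(size=(n_draws, len(bounds))), axis=1)
    return float((u <= bounds).all(axis=1).mean())


class TestJointOrderstatCdf:
    def test_full_support_is_one(self):
        for n in (1, 2, 3, 4, 6):
            assert joint_orderstat_cdf([1.0] * n) == pytest.approx(1.0)

    def test_single_uniform_is_identity(self):
        assert joint_orderstat_cdf([0.3]) == pytest.approx(0.3)

    def test_n2_closed_form(self):
        # analytic integration: P = 2 r1 r2 - r1^2
        assert joint_orderstat_cdf([0.5, 0.5]) == pytest.approx(0.25, abs=1e-15)
        rng = np.random.default_rng(11)
        for _ in range(100):
            r1, r2 = np.sort(rng.uniform(size=2))
            assert joint_orderstat_cdf([r1, r2]) == pytest.approx(
                2 * r1 * r2 - r1**2, abs=1e-12
            )

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(23)
        for n in (2, 3):
            for _ in range(5):
                ratios = np.sort(rng.uniform(size=n))
                exact = joint_orderstat_cdf(ratios)
                mc = monte_carlo_cdf(ratios, 20_000, rng)
                se = np.sqrt(max(exact * (1 - exact), 1e-12) / 20_000)
                assert abs(exact - mc) <= 4 * se + 1e-9

    def test_specific_three_study_value_against_oracle(self):
        ratios = (0.1, 0.2, 0.5)
        exact = joint_orderstat_cdf(ratios)
        rng = np.random.default_rng(99)
        mc = monte_carlo_cdf(ratios, 100_000, rng)
        se = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(exact - mc) <= 3 * se + 1e-9

    @given(
        ratios=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
        bump=st.floats(0.0, 0.5),
        idx=st.integers(0, 4),
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_each_coordinate_and_permutation_invariant(
        self, ratios, bump, idx
    ):
        p = joint_orderstat_cdf(ratios)
        assert 0.0 <= p <= 1.0
        shuffled = list(reversed(ratios))
        assert joint_orderstat_cdf(shuffled) == pytest.approx(p, abs=1e-12)
        bumped = list(ratios)
        i = idx % len(ratios)
        bumped[i] = min(1.0, bumped[i] + bump)
        assert joint_orderstat_cdf(bumped) >= p - 1e-12

    def test_vanishes_as_ratios_shrink(self):
        eps_ps = [joint_orderstat_cdf([eps] * 3) for eps in (0.1, 0.01, 0.001)]
        assert eps_ps[0] > eps_ps[1] > eps_ps[2]
        assert eps_ps[2] < 1e-8

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [-0.1]])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            joint_orderstat_cdf(bad)


def rank_table(study, pairs_ratios):
    rows = []
    for (a, b), ratio in pairs_ratios.items():
        rows.append(
            {"metagene_a": a, "metagene_b": b, "r": 1 - ratio, "rank_ratio": ratio}
        )
    return pd.DataFrame(rows)


class TestScoreConservedPairs:
    def test_hand_computed_two_study_ordering(self):
        t1 = rank_table("s1", {("a", "b"): 1 / 3, ("a", "c"): 2 / 3, ("b", "c"): 1.0})
        t2 = rank_table("s2", {("a", "b"): 1 / 3, ("a", "c"): 1.0, ("b", "c"): 2 / 3})
        scored = score_conserved_pairs({"s1": t1, "s2": t2}, ["s1", "s2"])

        def closed(r1, r2):
            r1, r2 = sorted((r1, r2))
            return 2 * r1 * r2 - r1 * r1

        expected = {
            ("a", "b"): closed(1 / 3, 1 / 3),
            ("a", "c"): closed(2 / 3, 1.0),
            ("b", "c"): closed(1.0, 2 / 3),
        }
        got = {
            (r.metagene_a, r.metagene_b): r.p_value
            for r in scored.itertuples(index=False)
        }
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, abs=1e-12)
        # best pair first; ties between (a,c) and (b,c) broken by pair id
        assert scored["metagene_a"].tolist() == ["a", "a", "b"]

    def test_all_ratio_one_pair_scores_one_and_ranks_last(self):
        t1 = rank_table("s1", {("a", "b"): 0.5, ("c", "d"): 1.0})
        t2 = rank_table("s2", {("a", "b"): 0.5, ("c", "d"): 1.0})
        scored = score_conserved_pairs({"s1": t1, "s2": t2}, ["s1", "s2"])
        assert scored.iloc[-1]["p_value"] == pytest.approx(1.0)
        assert tuple(scored.iloc[-1][["metagene_a", "metagene_b"]]) == ("c", "d")

    def test_pair_missing_in_one_study_dropped(self):
        t1 = rank_table("s1", {("a", "b"): 0.5, ("c", "d"): 0.2})
        t2 = rank_table("s2", {("a", "b"): 0.5})
        scored = score_conserved_pairs({"s1": t1, "s2": t2}, ["s1", "s2"])
        assert len(scored) == 1

    def test_missing_study_is_config_error(self):
        t1 = rank_table("s1", {("a", "b"): 0.5})
        with pytest.raises(ConfigError, match="s2"):
            score_conserved_pairs({"s1": t1}, ["s1", "s2"])


def scored_fixture(n=5):
    return pd.DataFrame(
        {
            "metagene_a": [f"a{i}" for i in range(n)],
            "metagene_b": [f"b{i}" for i in range(n)],
            "p_value": np.linspace(0.01, 0.9, n),
        }
    )


class TestBuildNetwork:
    def test_top_k_equal_all(self):
        net = build_network(scored_fixture(), top_k=5)
        assert len(net.edges) == 5

    def test_top_k_one_keeps_best(self):
        net = build_network(scored_fixture(), top_k=1)
        assert net.edges.iloc[0]["p_value"] == pytest.approx(0.01)

    def test_top_k_three_keeps_three_smallest(self):
        net = build_network(scored_fixture(), top_k=3)
        assert net.edges["p_value"].tolist() == pytest.approx([0.01, 0.2325, 0.455])

    def test_oversized_top_k_truncates_with_logged_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="meionet.orderstats"):
            net = build_network(scored_fixture(), top_k=99)
        assert len(net.edges) == 5
        assert any("truncating" in r.message for r in caplog.records)


def chain_network(edges):
    df = pd.DataFrame(
        {
            "metagene_a": [a for a, b in edges],
            "metagene_b": [b for a, b in edges],
            "p_value": np.linspace(0.01, 0.5, len(edges)),
        }
    )
    return build_network(df, top_k=len(edges))


class TestExtractSeedModules:
    MEMBERS = {m: (f"{m}_y",) for m in "abcdef"}

    def test_seed_anywhere_in_chain_returns_whole_chain(self):
        net = chain_network([("a", "b"), ("b", "c")])
        mods = extract_seed_modules(net, {"a_y"}, self.MEMBERS)
        assert len(mods) == 1
        assert set(mods[0].nodes) == {"a", "b", "c"}

    def test_only_seeded_component_returned(self):
        net = chain_network([("a", "b"), ("c", "d")])
        mods = extract_seed_modules(net, {"c_y"}, self.MEMBERS)
        assert [set(m.nodes) for m in mods] == [{"c", "d"}]

    def test_absent_seeds_give_empty_list(self):
        net = chain_network([("a", "b")])
        assert extract_seed_modules(net, {"zz"}, self.MEMBERS) == []


class TestNetworkIntersection:
    def test_identical_networks_flag_all_pairs(self):
        n1 = chain_network([("a", "b"), ("c", "d")])
        n2 = chain_network([("a", "b"), ("c", "d")])
        n1.name, n2.name = "N1", "N2"
        table = network_intersection([n1, n2])
        assert len(table) == 2
        assert table["n_networks"].tolist() == [2, 2]

    def test_disjoint_edge_sets_empty(self):
        n1, n2 = chain_network([("a", "b")]), chain_network([("c", "d")])
        n1.name, n2.name = "N1", "N2"
        assert len(network_intersection([n1, n2])) == 0

    def test_single_shared_pair(self):
        n1 = chain_network([("a", "b"), ("c", "d")])
        n2 = chain_network([("a", "b"), ("e", "f")])
        n1.name, n2.name = "N1", "N2"
        table = network_intersection([n1, n2])
        assert len(table) == 1
        assert (table.loc[0, "metagene_a"], table.loc[0, "metagene_b"]) == ("a", "b")
        assert bool(table.loc[0, "N1"]) and bool(table.loc[0, "N2"])
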