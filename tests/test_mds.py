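import itertools

import pytest

from cimds.collective_influence import collective_influence
from cimds.errors import (ConfigurationError, EmptyNetworkError, SizeCapError,
                          UnknownNodeError)
from cimds.graph_core import make_network
from cimds.mds import (domination_number, enumerate_all_mds, mds_overlap,
                       solve_ci_mds, solve_standard_mds, verify_dominating_set)
from cimds.synth_fixtures import FixtureSpec, random_network

from conftest import seeded_graphs
from oracles import brute_min_dominating, is_dominating, to_adj


class TestVerify:
    def test_path_examples(self):
        p3 = make_network([("a", "b"), ("b", "c")])
        assert verify_dominating_set(p3, {"b"})
        p4 = make_network([("a", "b"), ("b", "c"), ("c", "d")])
        assert not verify_dominating_set(p4, {"b"})  # d uncovered

    def test_unknown_member(self):
        with pytest.raises(UnknownNodeError):
            verify_dominating_set(make_network([("a", "b")]), {"zz"})

    def test_agrees_with_direct_constraint_evaluation(self):
        net = seeded_graphs(1, n_min=8, n_max=8, seed0=77)[0]
        adj = to_adj(net)
        nodes = sorted(net.nodes())
        for k in range(4):
            for cand in itertools.combinations(nodes, k):
                assert verify_dominating_set(net, set(cand)) == is_dominating(adj, set(cand))


class TestStandardMds:
    def test_path3_unique_optimum(self):
        res = solve_standard_mds(make_network([("a", "b"), ("b", "c")]))
        assert res.size == 1 and res.members == {"b"} and res.status == "optimal"

    def test_cycle4(self, cycle4):
        res = solve_standard_mds(cycle4)
        assert res.size == 2
        assert verify_dominating_set(cycle4, set(res.members))

    def test_star_center(self):
        star = make_network([("c", f"l{i}") for i in range(1, 6)])
        assert solve_standard_mds(star).members == {"c"}

    def test_isolated_node_is_forced(self):
        net = make_network([("a", "b"), ("b", "c"), ("a", "c")], singletons=["v"])
        res = solve_standard_mds(net)
        assert res.size == 2 and "v" in res.members

    def test_empty_network_and_bad_backend(self):
        with pytest.raises(EmptyNetworkError):
            solve_standard_mds(make_network())
        with pytest.raises(ConfigurationError):
            solve_standard_mds(make_network([("a", "b")]), backend="nope")

    def test_domination_number_matches_brute_force(self):
        for net in seeded_graphs(15, n_min=5, n_max=10, seed0=500):
            gamma, _ = brute_min_dominating(net)
            assert domination_number(net) == gamma


class TestEnumeration:
    def test_path3(self):
        assert enumerate_all_mds(make_network([("a", "b"), ("b", "c")])) == [frozenset("b")]

    def test_cycle4_all_six_pairs(self, cycle4):
        got = enumerate_all_mds(cycle4)
        assert len(got) == 6  # 4 adjacent + 2 opposite pairs
        assert got == sorted(got, key=lambda s: tuple(sorted(s)))

    def test_cap(self):
        big = random_network(FixtureSpec(seed=1, n_nodes=20, edge_prob=0.2))
        with pytest.raises(SizeCapError):
            enumerate_all_mds(big)


class TestCiMds:
    def test_five_cycle_all_optima_tie(self):
        c5 = make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")])
        ci = collective_influence(c5, 1)
        all_mds = enumerate_all_mds(c5)
        totals = {ci.total(s) for s in all_mds}
        assert len(totals) == 1  # vertex-transitive: all configurations tie
        shared_total = totals.pop()
        for backend in ("highs", "highs-permuted"):
            res = solve_ci_mds(c5, 1, backend)
            assert res.size == 2
            assert res.total_ci == shared_total == ci.total(res.members)

    @pytest.mark.parametrize("ell", [0, 1, 2])
    def test_total_ci_equals_enumeration_maximum(self, ell):
        for net in seeded_graphs(10, n_min=6, n_max=10, seed0=600):
            ci = collective_influence(net, ell)
            best = max(ci.total(s) for s in enumerate_all_mds(net))
            for backend in ("highs", "highs-permuted", "enumerate"):
                res = solve_ci_mds(net, ell, backend)
                assert res.total_ci == best
                assert res.size == domination_number(net)
                assert verify_dominating_set(net, set(res.members))

    def test_enumerate_backend_canonical_choice(self):
        c5 = make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")])
        res = solve_ci_mds(c5, 1, "enumerate")
        all_mds = enumerate_all_mds(c5)
        ci = collective_influence(c5, 1)
        best = max(ci.total(s) for s in all_mds)
        expected = min((s for s in all_mds if ci.total(s) == best),
                       key=lambda s: tuple(sorted(s)))
        assert res.members == expected


class TestProperties:
    def test_gamma_backend_invariant(self, small_ensemble):
        for net in small_ensemble[:12]:
            sizes = {solve_standard_mds(net, b).size for b in ("highs", "highs-permuted")}
            assert len(sizes) == 1

    def test_adding_edge_never_increases_gamma(self):
        for net in seeded_graphs(8, n_min=6, n_max=9, seed0=700):
            gamma = domination_number(net)
            nodes = sorted(net.nodes())
            non_edges = [(u, v) for u, v in itertools.combinations(nodes, 2)
                         if not net.has_edge(u, v)]
            for u, v in non_edges[:3]:
                aug = net.copy()
                aug.add_edge(u, v)
                assert domination_number(aug) <= gamma


class TestOverlap:
    def test_examples(self):
        assert mds_overlap({"1", "2"}, {"1", "2"}) == 1.0
        assert mds_overlap({"1"}, {"2"}) == 0.0
        assert mds_overlap({"1", "2", "3"}, {"2", "3", "4"}) == 0.5

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            mds_overlap(set(), set())
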