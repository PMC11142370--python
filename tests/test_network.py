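import itertools

import networkx as nx
import numpy as np
import pytest

from epinet.loci import SnpLocus
from epinet.network import (
    EpistaticNetwork,
    _modularity_fast,
    build_network,
    detect_communities,
    modularity,
    network_metrics,
    sweep_threshold,
)
from epinet.scan import EpistasisPair

from conftest import (
    clique_edges,
    cycle_edges,
    exhaustive_best_partition,
    loci_on,
    make_network,
)


def pair(a, b, w, enc="xor"):
    return EpistasisPair(snp_a=a, snp_b=b, p_raw=w, p_adj=w, encoding=enc)


class TestBuildNetwork:
    def setup_method(self):
        self.loci = loci_on(1, (100, 200, 300, 400))

    def test_saturating_threshold_keeps_every_pair(self):
        a, b, c, d = self.loci
        pairs = [pair(a, b, 0.01), pair(b, c, 0.03), pair(c, d, 0.05)]
        net = build_network(pairs, tau=0.05)
        assert net.n_edges == 3 and net.n_nodes == 4

    def test_threshold_is_inclusive(self):
        a, b, c, _ = self.loci
        pairs = [pair(a, b, 0.0434), pair(b, c, 0.0435)]
        net = build_network(pairs, tau=0.0434)
        assert net.n_edges == 1

    def test_below_min_weight_gives_empty_network(self):
        a, b, *_ = self.loci
        net = build_network([pair(a, b, 0.01)], tau=0.001)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_duplicates_collapse_to_min_weight(self):
        a, b, *_ = self.loci
        net = build_network([pair(a, b, 0.02), pair(b, a, 0.01)], tau=0.05)
        assert net.n_edges == 1
        assert list(net.edges.values()) == [0.01]

    def test_negative_tau_rejected(self):
        a, b, *_ = self.loci
        with pytest.raises(ValueError):
            build_network([pair(a, b, 0.01)], tau=-0.1)

    def test_no_isolated_nodes_invariant(self):
        a, b, c, d = self.loci
        net = build_network([pair(a, b, 0.01), pair(c, d, 0.2)], tau=0.05)
        assert net.nodes == {a, b}


class TestNetworkMetrics:
    def test_two_disjoint_cycles(self, two_cycles_net):
        net, _, _ = two_cycles_net
        m = network_metrics(net)
        assert (m.n_nodes, m.n_edges, m.n_components) == (6, 6, 2)
        assert m.largest_component_ratio == pytest.approx(0.5)
        assert m.n_triangles == 2

    def test_complete_graph_k4_has_four_triangles(self):
        net = make_network(clique_edges(loci_on(1, (1, 2, 3, 4))))
        assert network_metrics(net).n_triangles == 4

    def test_path_has_no_triangles(self):
        nodes = loci_on(1, range(1, 6))
        net = make_network(list(zip(nodes, nodes[1:])))
        m = network_metrics(net)
        assert m.n_triangles == 0 and m.n_components == 1

    def test_triangle_count_matches_brute_force(self):
        rng = np.random.default_rng(5)
        nodes = loci_on(1, range(1, 41))
        edges = [
            (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :] if rng.random() < 0.15
        ]
        if not edges:
            pytest.skip("degenerate draw")
        net = make_network(edges)
        eset = set(net.edges)

        def has(a, b):
            return ((a, b) in eset) or ((b, a) in eset)

        brute = sum(
            1
            for x, y, z in itertools.combinations(sorted(net.nodes, key=lambda s: s.sort_key), 3)
            if has(x, y) and has(x, z) and has(y, z)
        )
        assert network_metrics(net).n_triangles == brute


class TestModularity:
    def test_whole_graph_partition_is_zero(self, two_cycles_net):
        net, c1, c2 = two_cycles_net
        q = modularity(net, {v: 0 for v in c1 + c2})
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_cycles_partition_is_half(self, two_cycles_net):
        net, c1, c2 = two_cycles_net
        q = modularity(net, {**{v: 0 for v in c1}, **{v: 1 for v in c2}})
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_single_cut_edge_is_minus_half(self):
        a, b = loci_on(1, (1, 2))
        net = make_network([(a, b)])
        assert modularity(net, {a: 0, b: 1}) == pytest.approx(-0.5, abs=1e-12)

    def test_matches_networkx(self, bridged_cliques_net):
        net, c1, c2 = bridged_cliques_net
        part = {**{v: 0 for v in c1}, **{v: 1 for v in c2}}
        expected = nx.community.modularity(net.to_networkx(), [set(c1), set(c2)])
        assert modularity(net, part) == pytest.approx(expected, abs=1e-12)

    def test_definition_equals_per_community_form(self, bridged_cliques_net):
        # Q from the ordered-pair definition == sum_c [l_c/m - gamma (d_c/2m)^2]
        net, c1, c2 = bridged_cliques_net
        rng = np.random.default_rng(0)
        nodes = sorted(net.nodes, key=lambda s: s.sort_key)
        for gamma in (0.5, 1.0, 2.0):
            for _ in range(5):
                part = {v: int(c) for v, c in zip(nodes, rng.integers(0, 3, len(nodes)))}
                assert modularity(net, part, gamma) == pytest.approx(
                    _modularity_fast(net.edges.keys(), part, gamma), abs=1e-12
                )

    def test_missing_node_rejected(self, two_cycles_net):
        net, c1, c2 = two_cycles_net
        with pytest.raises(ValueError):
            modularity(net, {v: 0 for v in c1})


class TestDetectCommunities:
    def test_two_cycles_found_exactly(self, two_cycles_net):
        net, c1, c2 = two_cycles_net
        part = detect_communities(net)
        assert part.q == pytest.approx(0.5, abs=1e-12)
        groups = part.communities()
        assert {frozenset(g) for g in groups} == {frozenset(c1), frozenset(c2)}

    def test_single_triangle_is_one_community(self):
        net = make_network(cycle_edges(loci_on(1, (1, 2, 3))))
        part = detect_communities(net)
        assert part.n_communities == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_bridged_cliques_split_at_bridge(self, bridged_cliques_net):
        net, c1, c2 = bridged_cliques_net
        part = detect_communities(net)
        assert {frozenset(g) for g in part.communities()} == {frozenset(c1), frozenset(c2)}

    @pytest.mark.parametrize("fixture", ["two_cycles_net", "bridged_cliques_net"])
    def test_greedy_matches_exhaustive_optimum(self, fixture, request):
        net = request.getfixturevalue(fixture)[0]
        best_q, _ = exhaustive_best_partition(net)
        part = detect_communities(net)
        assert part.q == pytest.approx(best_q, abs=1e-12)

    def test_greedy_never_beats_exhaustive(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            nodes = loci_on(1, range(1, 8))
            edges = [
                (a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
                if rng.random() < 0.4
            ]
            if not edges:
                continue
            net = make_network(edges)
            best_q, _ = exhaustive_best_partition(net)
            assert detect_communities(net).q <= best_q + 1e-12

    def test_reported_q_consistent_with_modularity(self, bridged_cliques_net):
        net, _, _ = bridged_cliques_net
        part = detect_communities(net)
        assert part.q == pytest.approx(modularity(net, part), abs=1e-12)

    def test_community_ids_ordered_by_descending_size(self):
        big = loci_on(1, (1, 2, 3, 4))
        small = loci_on(2, (1, 2, 3))
        net = make_network(clique_edges(big) + cycle_edges(small))
        part = detect_communities(net)
        sizes = [len(g) for g in part.communities()]
        assert sizes == sorted(sizes, reverse=True)
        assert sorted(set(part.assignment.values())) == list(range(part.n_communities))

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(EpistaticNetwork(edges={}, tau=0.0))


class TestSweep:
    def test_single_pair_tau_star_is_zero(self):
        a, b = loci_on(1, (1, 2))
        res = sweep_threshold([pair(a, b, 0.01)])
        assert all(p.q == 0.0 for p in res.grid)
        assert res.tau_star == 0.0
        assert res.tau_triangle_onset is None

    def test_planted_communities_exclude_bridges(self):
        # intra-community weights <= 0.01, inter-community bridges at 0.04:
        # the modularity optimum must fall below the bridge weight
        c1 = loci_on(1, (10, 20, 30, 40, 50))
        c2 = loci_on(2, (10, 20, 30, 40, 50))
        rng = np.random.default_rng(1)
        pairs = []
        for grp in (c1, c2):
            for a, b in clique_edges(grp):
                pairs.append(pair(a, b, round(float(rng.uniform(0.001, 0.01)), 4)))
        pairs.append(pair(c1[0], c2[0], 0.04))
        pairs.append(pair(c1[1], c2[1], 0.04))
        res = sweep_threshold(pairs)
        assert res.tau_star < 0.04

    def test_metrics_monotone_in_tau(self):
        rng = np.random.default_rng(2)
        nodes = loci_on(1, range(10, 200, 10))
        pairs = [
            pair(a, b, round(float(rng.uniform(0.0005, 0.03)), 4))
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
            if rng.random() < 0.25
        ]
        res = sweep_threshold(pairs)
        edges = [p.metrics.n_edges for p in res.grid]
        nodes_n = [p.metrics.n_nodes for p in res.grid]
        tris = [p.metrics.n_triangles for p in res.grid]
        for seq in (edges, nodes_n, tris):
            assert all(x <= y for x, y in zip(seq, seq[1:]))

    def test_grid_covers_all_pairs_and_is_uniform(self):
        a, b, c = loci_on(1, (1, 2, 3))
        res = sweep_threshold([pair(a, b, 0.0123), pair(b, c, 0.00005)])
        taus = [p.tau for p in res.grid]
        assert taus[0] == 0.0
        assert taus[-1] >= 0.0123
        steps = np.diff(taus)
        assert np.allclose(steps, 0.0001)
        assert res.grid[-1].metrics.n_edges == 2

    def test_tau_star_is_smallest_argmax(self):
        c1 = loci_on(1, (1, 2, 3))
        pairs = [pair(a, b, 0.001) for a, b in cycle_edges(c1)]
        res = sweep_threshold(pairs)
        q_max = max(p.q for p in res.grid)
        assert res.tau_star == min(p.tau for p in res.grid if p.q == q_max)

    def test_triangle_onset_recorded(self):
        c1 = loci_on(1, (1, 2, 3))
        pairs = [
            pair(c1[0], c1[1], 0.001),
            pair(c1[1], c1[2], 0.001),
            pair(c1[0], c1[2], 0.005),
        ]
        res = sweep_threshold(pairs)
        assert res.tau_triangle_onset == pytest.approx(0.005)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            sweep_threshold([])
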