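"""TOM/LTOM score matrices, the co-localization gates, and edge imputation."""

import itertools

import numpy as np
import pytest

from conftest import random_localization, random_network
from loctom import (
    MAJOR_LOCATIONS,
    LocalizationTable,
    Network,
    impute_network,
    impute_top_k,
    ltom_matrix,
    sigma,
    sigma_prime,
    tom_matrix,
)
from oracles import ltom_brute, tom_brute


def as_dict(om):
    return {(u, v): om.scores[i, j]
            for i, u in enumerate(om.nodes) for j, v in enumerate(om.nodes)}


class TestTomMatrix:
    def test_isolated_dyad_scores_one(self):
        net = Network.from_edges([("A", "B")])
        assert tom_matrix(net).score("A", "B") == 1.0

    def test_path_graph_hand_values(self):
        net = Network.from_edges([("A", "B"), ("B", "C")])
        om = tom_matrix(net)
        assert om.score("A", "C") == 0.5   # one shared partner, no direct edge
        assert om.score("A", "B") == 1.0   # direct edge between degree-1/2 ends

    def test_triangle_all_pairs_one(self, triangle):
        om = tom_matrix(triangle)
        assert np.allclose(om.scores, 1.0)

    def test_isolated_node_scores_zero_off_diagonal(self):
        net = Network.from_edges([("A", "B")])
        net.add_node("Z")
        om = tom_matrix(net)
        assert om.score("A", "Z") == 0.0 and om.score("Z", "Z") == 1.0

    def test_exhaustive_small_graphs_match_brute_force(self):
        for n in range(2, 6):
            nodes = [f"v{i}" for i in range(n)]
            pairs = list(itertools.combinations(nodes, 2))
            for mask in range(1 << len(pairs)):
                edges = [p for b, p in enumerate(pairs) if mask >> b & 1]
                net = Network.from_edges(edges, nodes=nodes)
                expected = tom_brute(nodes, edges)
                got = as_dict(tom_matrix(net))
                for key, val in expected.items():
                    assert got[key] == pytest.approx(val, abs=1e-12)

    def test_random_n7_graphs_match_brute_force(self):
        rng = np.random.default_rng(17)
        nodes = [f"v{i}" for i in range(7)]
        pairs = list(itertools.combinations(nodes, 2))
        for _ in range(250):
            edges = [p for p in pairs if rng.random() < rng.uniform(0.1, 0.9)]
            net = Network.from_edges(edges, nodes=nodes)
            expected = tom_brute(nodes, edges)
            got = as_dict(tom_matrix(net))
            for key, val in expected.items():
                assert got[key] == pytest.approx(val, abs=1e-12)


class TestLtomMatrix:
    def test_shared_single_location_reduces_to_tom(self):
        rng = np.random.default_rng(23)
        net = random_network(rng, 20, 0.25)
        loc = LocalizationTable({n: frozenset({"cytoplasm"}) for n in net.nodes})
        assert np.allclose(ltom_matrix(net, loc).scores, tom_matrix(net).scores)

    def test_toy_network_gated_value(self, fig2):
        net, loc = fig2
        om = ltom_matrix(net, loc)
        assert om.score("A", "B") == 0.75
        assert tom_matrix(net).score("A", "B") == 1.0

    def test_pairwise_disjoint_locations_zero_off_diagonal(self):
        net = Network.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        loc = LocalizationTable(
            {
                "A": frozenset({"nucleus"}),
                "B": frozenset({"membrane"}),
                "C": frozenset({"extracellular"}),
            }
        )
        om = ltom_matrix(net, loc)
        off = om.scores[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.0)

    def test_random_annotated_n7_graphs_match_brute_force(self):
        rng = np.random.default_rng(31)
        nodes = [f"v{i}" for i in range(7)]
        pairs = list(itertools.combinations(nodes, 2))
        for _ in range(250):
            edges = [p for p in pairs if rng.random() < rng.uniform(0.1, 0.9)]
            net = Network.from_edges(edges, nodes=nodes)
            loc = random_localization(rng, nodes)
            expected = ltom_brute(nodes, edges, {n: set(loc.get(n)) for n in nodes})
            got = as_dict(ltom_matrix(net, loc))
            for key, val in expected.items():
                assert got[key] == pytest.approx(val, abs=1e-12)

    def test_bound_ltom_le_tom_le_one(self):
        rng = np.random.default_rng(37)
        for _ in range(200):
            n = int(rng.integers(3, 61))
            net = random_network(rng, n, float(rng.uniform(0.05, 0.4)))
            loc = random_localization(rng, net.nodes)
            lt = ltom_matrix(net, loc).scores
            tm = tom_matrix(net).scores
            assert np.all(lt <= tm + 1e-12)
            assert np.all(tm <= 1.0 + 1e-12)
            assert np.all(lt >= 0.0)

    def test_all_six_locations_everywhere_gives_exact_equality(self):
        rng = np.random.default_rng(41)
        net = random_network(rng, 25, 0.2)
        loc = LocalizationTable({n: frozenset(MAJOR_LOCATIONS) for n in net.nodes})
        assert np.array_equal(ltom_matrix(net, loc).scores, tom_matrix(net).scores)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(43)
        net = random_network(rng, 12, 0.3)
        loc = random_localization(rng, net.nodes)
        perm = list(rng.permutation(net.nodes))
        net2 = Network.from_edges(list(net.edges()), nodes=perm)
        d1 = as_dict(ltom_matrix(net, loc))
        d2 = as_dict(ltom_matrix(net2, loc))
        assert d1 == d2

    def test_unannotated_nodes_lenient_zero_strict_error(self):
        net = Network.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        loc = LocalizationTable({"A": frozenset({"nucleus"}), "B": frozenset({"nucleus"})})
        om = ltom_matrix(net, loc)  # lenient: C gates closed
        assert om.score("A", "C") == 0.0 and om.score("A", "B") > 0
        with pytest.raises(ValueError, match="lack localization"):
            ltom_matrix(net, loc, strict=True)


class TestSigma:
    def test_three_way_and_two_way_gates(self):
        loc = LocalizationTable(
            {
                "i": frozenset({"nucleus"}),
                "u": frozenset({"nucleus", "membrane"}),
                "j": frozenset({"nucleus"}),
                "w": frozenset({"membrane"}),
            }
        )
        assert sigma("i", "u", "j", loc) == 1
        assert sigma("i", "w", "j", loc) == 0
        assert sigma_prime("i", "j", loc) == 1
        assert sigma_prime("i", "w", loc) == 0

    def test_random_triples_match_set_intersection(self):
        rng = np.random.default_rng(47)
        nodes = [f"p{i}" for i in range(12)]
        loc = random_localization(rng, nodes)
        for _ in range(300):
            i, u, j = rng.choice(nodes, 3, replace=False)
            expected3 = int(bool(loc.get(i) & loc.get(u) & loc.get(j)))
            expected2 = int(bool(loc.get(i) & loc.get(j)))
            assert sigma(i, u, j, loc) == expected3
            assert sigma_prime(i, j, loc) == expected2
            assert sigma(i, i, j, loc) == sigma_prime(i, j, loc)


class TestImputation:
    def test_tau_above_max_changes_nothing(self):
        net = Network.from_edges([("A", "B"), ("B", "C")])
        out = impute_network(net, tom_matrix(net), tau=1.0)
        # A-C scores exactly 0.5; tau=1.0 leaves only pairs scoring 1.0
        assert not out.has_edge("A", "C")
        assert out.n_edges == net.n_edges

    def test_path_closure_at_half(self):
        net = Network.from_edges([("A", "B"), ("B", "C")])
        out = impute_network(net, tom_matrix(net), tau=0.5)
        assert out.has_edge("A", "C")
        assert out.edge_data("A", "C") == {"imputed": True}
        assert out.n_edges == 3 and out.n_nodes == 3

    def test_random_graph_matches_score_scan(self):
        rng = np.random.default_rng(53)
        net = random_network(rng, 40, 0.12)
        om = tom_matrix(net)
        tau = 0.4
        out = impute_network(net, om, tau=tau)
        nodes = net.nodes
        expected_added = {
            frozenset((nodes[i], nodes[j]))
            for i in range(40)
            for j in range(i + 1, 40)
            if not net.has_edge(nodes[i], nodes[j]) and om.scores[i, j] >= tau
        }
        added = {frozenset(e) for e in out.edges()} - {frozenset(e) for e in net.edges()}
        assert added == expected_added
        assert set(out.nodes) == set(net.nodes)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(59)
        net = random_network(rng, 30, 0.15)
        om = tom_matrix(net)
        loose = {frozenset(e) for e in impute_network(net, om, tau=0.3).edges()}
        tight = {frozenset(e) for e in impute_network(net, om, tau=0.6).edges()}
        assert tight <= loose

    def test_nonpositive_tau_rejected(self):
        net = Network.from_edges([("A", "B")])
        with pytest.raises(ValueError, match="tau"):
            impute_network(net, tom_matrix(net), tau=0.0)

    def test_top_k_adds_exactly_k_best(self):
        rng = np.random.default_rng(61)
        net = random_network(rng, 25, 0.15)
        om = tom_matrix(net)
        out = impute_top_k(net, om, k=5)
        assert out.n_edges == net.n_edges + 5
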