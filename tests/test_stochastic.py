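import numpy as np
import networkx as nx
import pytest

import oracles
from lpstopo.graphs import BinaryGraph
from lpstopo.stochastic import (
    lattice_reference,
    largest_component,
    modularity,
    randomize_degree_preserving,
    small_worldness_both,
    small_worldness_omega,
    small_worldness_omega_eff,
    structural_consistency,
)
from lpstopo.topology import clustering_coefficient

from conftest import make_graph, random_graph


def from_nx(g: nx.Graph) -> BinaryGraph:
    adj = nx.to_numpy_array(g, dtype=int)
    return BinaryGraph(nodes=list(range(adj.shape[0])), adjacency=adj, pt=100.0)


RING = from_nx(nx.watts_strogatz_graph(50, 4, 0.0, seed=1))
ER_DENSE = from_nx(nx.gnp_random_graph(50, 0.3, seed=2))
WS = from_nx(nx.watts_strogatz_graph(84, 8, 0.1, seed=3))


class TestRewiring:
    @pytest.mark.parametrize("seed", range(20))
    def test_degree_sequence_preserved(self, seed):
        g = random_graph(20, 0.3, seed)
        for null in (randomize_degree_preserving(g, seed=seed),
                     lattice_reference(g, seed=seed)):
            np.testing.assert_array_equal(null.degrees(), g.degrees())
            assert np.all(np.diag(null.adjacency) == 0)

    def test_triangle_is_rigid_under_swaps(self):
        k3 = make_graph(3, [(0, 1), (1, 2), (0, 2)])
        null = randomize_degree_preserving(k3, seed=0)
        np.testing.assert_array_equal(null.adjacency, k3.adjacency)

    def test_randomization_matches_er_ensemble_clustering(self):
        # degree-preserving nulls of an ER graph have ER-level clustering ~ p
        g = from_nx(nx.gnp_random_graph(20, 0.3, seed=4))
        accs = [clustering_coefficient(randomize_degree_preserving(g, seed=s))[1]
                for s in range(50)]
        assert np.mean(accs) == pytest.approx(0.3, abs=0.08)

    def test_latticization_nearly_idempotent_on_ring_lattice(self):
        acc_in = clustering_coefficient(RING)[1]
        acc_out = clustering_coefficient(lattice_reference(RING, seed=5))[1]
        assert abs(acc_out - acc_in) <= 0.05 * acc_in

    def test_latticization_raises_clustering_above_random_null(self):
        g = from_nx(nx.gnp_random_graph(30, 0.2, seed=6))
        wins = 0
        for s in range(10):
            acc_latt = clustering_coefficient(lattice_reference(g, seed=s))[1]
            acc_rand = clustering_coefficient(randomize_degree_preserving(g, seed=s))[1]
            wins += acc_latt > acc_rand
        assert wins >= 9

    def test_rewired_edge_set_differs_for_nontrivial_graphs(self):
        g = random_graph(30, 0.2, 7)
        null = randomize_degree_preserving(g, seed=8)
        assert not np.array_equal(null.adjacency, g.adjacency)


class TestSmallWorldness:
    def test_ring_lattice_is_lattice_like(self):
        assert small_worldness_omega(RING, n_null=8, seed=1).value < -0.4

    def test_dense_er_is_random_like(self):
        assert small_worldness_omega(ER_DENSE, n_null=8, seed=2).value > 0.3

    def test_watts_strogatz_is_small_world(self):
        assert abs(small_worldness_omega(WS, n_null=8, seed=3).value) < 0.3

    def test_complete_graph_omega_eff_is_zero(self):
        k8 = make_graph(8, [(i, j) for i in range(8) for j in range(i + 1, 8)])
        assert small_worldness_omega_eff(k8, n_null=4, seed=4).value == pytest.approx(0.0)

    def test_omega_eff_signs_match_omega_regimes(self):
        assert small_worldness_omega_eff(RING, n_null=8, seed=5).value < 0
        assert small_worldness_omega_eff(ER_DENSE, n_null=8, seed=6).value > 0

    def test_combined_call_matches_separate_structure(self):
        omega, omega_eff = small_worldness_both(WS, n_null=6, seed=7)
        for r in (omega, omega_eff):
            assert r.n_realizations == 6
            assert r.null_random_se > 0 and r.null_lattice_se > 0
        assert omega.observed["ACC"] == clustering_coefficient(WS)[1]

    def test_reproducible_under_seed(self):
        a = small_worldness_omega(WS, n_null=5, seed=11).value
        b = small_worldness_omega(WS, n_null=5, seed=11).value
        assert a == b

    def test_disconnected_graph_uses_largest_component(self):
        g = make_graph(8, [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4),
                           (5, 6), (6, 7)])
        comp, coverage = largest_component(g)
        assert comp.nodes == [0, 1, 2, 3, 4]
        assert coverage == pytest.approx(5 / 8)
        result = small_worldness_omega(g, n_null=4, seed=12)
        assert result.component_coverage == pytest.approx(5 / 8)


class TestModularity:
    def test_two_cliques_planted_partition_value_and_optimizer(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i + 5, j + 5) for i, j in edges]
        edges.append((0, 5))
        g = make_graph(10, edges)
        planted_q = oracles.modularity_of_partition(
            np.asarray(g.adjacency, dtype=float), [set(range(5)), set(range(5, 10))])
        assert planted_q == pytest.approx(20 / 21 - 0.5, abs=1e-12)
        result = modularity(g, seed=1)
        assert result.q >= planted_q - 1e-12

    def test_disjoint_cliques_q_half(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i + 4, j + 4) for i, j in edges]
        g = make_graph(8, edges)
        planted_q = oracles.modularity_of_partition(
            np.asarray(g.adjacency, dtype=float), [set(range(4)), set(range(4, 8))])
        assert planted_q == pytest.approx(0.5, abs=1e-12)
        assert modularity(g, seed=2).q == pytest.approx(0.5, abs=1e-12)

    def test_complete_graph_has_no_community_structure(self):
        k6 = make_graph(6, [(i, j) for i in range(6) for j in range(i + 1, 6)])
        assert modularity(k6, seed=3).q == pytest.approx(0.0, abs=1e-12)

    def test_best_q_reproducible_and_bounded(self):
        g = random_graph(20, 0.2, 9)
        r1 = modularity(g, seed=4)
        r2 = modularity(g, seed=4)
        assert r1.q == r2.q
        assert -0.5 <= r1.q <= 1.0
        assert len(r1.q_per_restart) == r1.n_restarts


class TestStructuralConsistency:
    def test_sigma_c_is_a_proportion(self):
        g = random_graph(30, 0.3, 10)
        result = structural_consistency(g, seed=1)
        assert np.all((result.values >= 0) & (result.values <= 1))
        assert 0 <= result.mean <= 1

    def test_lattice_more_predictable_than_degree_matched_random(self):
        lat = from_nx(nx.watts_strogatz_graph(40, 6, 0.0, seed=11))
        wins = 0
        for s in range(10):
            rand = randomize_degree_preserving(lat, seed=100 + s)
            sc_lat = structural_consistency(lat, n_rep=5, seed=s).mean
            sc_rand = structural_consistency(rand, n_rep=5, seed=s).mean
            wins += sc_lat > sc_rand
        assert wins >= 9

    def test_single_link_removal_gives_binary_outcomes(self):
        g = random_graph(12, 0.3, 12)
        frac = 1.0 / g.n_edges
        result = structural_consistency(g, perturb_fraction=frac, n_rep=6, seed=2)
        assert set(np.unique(result.values)) <= {0.0, 1.0}

    def test_removing_no_edge_rejected(self):
        g = random_graph(12, 0.3, 13)
        with pytest.raises(ValueError, match="removes no edge"):
            structural_consistency(g, perturb_fraction=1e-6)

    def test_reproducible_under_seed(self):
        g = random_graph(25, 0.25, 14)
        a = structural_consistency(g, seed=5)
        b = structural_consistency(g, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
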