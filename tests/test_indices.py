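import math

import networkx as nx
import numpy as np
import pytest

from hiercomplex import (
    assortativity,
    characteristic_path_length,
    clustering_and_density,
    compute_index_report,
    degree_range_complexity,
    degree_variance,
    hierarchical_complexity,
    mean_rich_club,
)
from hiercomplex import BinaryNetwork
from conftest import brute_force_R, net_from_edges, random_net


def from_nx(g):
    return BinaryNetwork(nx.to_numpy_array(g, dtype=int))


class TestHierarchicalComplexity:
    def test_g5_raw_value(self, g5):
        # only the degree-2 class contributes: deviations 2/3, /(2*2), /D=3
        assert hierarchical_complexity(g5, scaled=False) == pytest.approx(1 / 18)

    def test_g5_scaled_value(self, g5):
        # raw class term 1/6 further divided by slots p*|Kp| = 6
        assert hierarchical_complexity(g5, scaled=True) == pytest.approx(1 / 108)

    @pytest.mark.parametrize("maker", [
        lambda: nx.path_graph(4),
        lambda: nx.cycle_graph(7),
        lambda: nx.complete_graph(6),
        lambda: nx.star_graph(5),
        lambda: nx.hypercube_graph(3),
        lambda: nx.random_regular_graph(4, 10, seed=3),
    ], ids=["P4", "C7", "K6", "star", "Q3", "4-regular"])
    def test_zero_for_homogeneous_graphs(self, maker):
        """Vertex-transitive graphs, stars and paths have identical
        neighbourhood sequences within every degree class."""
        net = from_nx(nx.convert_node_labels_to_integers(maker()))
        assert hierarchical_complexity(net, scaled=False) == 0.0
        assert hierarchical_complexity(net, scaled=True) == 0.0

    @pytest.mark.parametrize("scaled", [True, False], ids=["scaled", "raw"])
    def test_matches_brute_force_oracle(self, scaled):
        """Main implementation agrees with explicit enumeration to 1e-12
        on random graphs with up to 12 nodes."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            net = random_net(int(rng.integers(2, 13)), rng.uniform(0.1, 0.95), rng)
            expected = brute_force_R([list(r) for r in net.a], scaled=scaled)
            assert hierarchical_complexity(net, scaled=scaled) == pytest.approx(
                expected, abs=1e-12)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(7)
        net = random_net(12, 0.4, rng)
        perm = rng.permutation(12)
        relabeled = BinaryNetwork(net.a[np.ix_(perm, perm)])
        assert hierarchical_complexity(net) == pytest.approx(
            hierarchical_complexity(relabeled), abs=1e-12)


class TestDegreeRangeComplexity:
    def test_g5_single_class(self, g5):
        assert degree_range_complexity(g5, {2}, scaled=False) == pytest.approx(1 / 6)

    def test_singleton_classes_undefined(self, g5):
        assert math.isnan(degree_range_complexity(g5, {1, 3}))

    def test_regular_graph(self):
        cycle = net_from_edges([(i, (i + 1) % 5) for i in range(5)], 5)
        assert degree_range_complexity(cycle, {2}) == 0.0
        assert math.isnan(degree_range_complexity(cycle, {3}))


class TestDegreeVariance:
    def test_regular_graph_zero(self):
        assert degree_variance(from_nx(nx.cycle_graph(8))) == 0.0

    def test_g5(self, g5):
        assert degree_variance(g5) == pytest.approx(0.5)


class TestAssortativity:
    def test_p4(self, p4):
        assert assortativity(p4) == pytest.approx(-0.5)

    def test_regular_graph_undefined(self):
        assert math.isnan(assortativity(from_nx(nx.cycle_graph(5))))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_networkx(self, seed):
        g = nx.gnm_random_graph(20, 60, seed=seed)
        assert assortativity(from_nx(g)) == pytest.approx(
            nx.degree_assortativity_coefficient(g), abs=1e-10)


class TestClusteringAndDensity:
    def test_complete_graph(self):
        C, gamma, P = clustering_and_density(from_nx(nx.complete_graph(4)))
        assert (C, gamma, P) == (1.0, 1.0, 1.0)

    def test_g5(self, g5):
        # one triangle; triples = sum k(k-1)/2 = 6
        C, gamma, P = clustering_and_density(g5)
        assert C == pytest.approx(0.5)
        assert P == pytest.approx(0.5)
        assert gamma == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_networkx_transitivity(self, seed):
        g = nx.gnm_random_graph(15, 40, seed=seed)
        C, _, _ = clustering_and_density(from_nx(g))
        assert C == pytest.approx(nx.transitivity(g), abs=1e-12)


class TestPathLength:
    def test_complete_graph(self):
        assert characteristic_path_length(from_nx(nx.complete_graph(5))) == 1.0

    def test_g5(self, g5):
        # pair distances: 1,1,2,3,1,2,3,1,2,1 -> 17 over 10 pairs
        assert characteristic_path_length(g5) == pytest.approx(1.7)

    def test_five_cycle(self):
        assert characteristic_path_length(from_nx(nx.cycle_graph(5))) == pytest.approx(1.5)

    def test_disconnected_uses_largest_component(self):
        net = net_from_edges([(0, 1), (1, 2), (3, 4)], 5)
        with pytest.warns(UserWarning, match="disconnected"):
            L = characteristic_path_length(net)
        assert L == pytest.approx(4 / 3)


class TestMeanRichClub:
    def test_complete_graph(self):
        assert mean_rich_club(from_nx(nx.complete_graph(5))) == 1.0

    def test_g5(self, g5):
        # only k=1 eligible: 4 nodes of degree>1 with 4 edges among them
        assert mean_rich_club(g5) == pytest.approx(2 / 3)

    def test_five_cycle(self):
        assert mean_rich_club(from_nx(nx.cycle_graph(5))) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_phi_agrees_with_networkx(self, seed):
        g = nx.gnm_random_graph(20, 70, seed=seed)
        net = from_nx(g)
        phi_nx = nx.rich_club_coefficient(g, normalized=False)
        k = net.degrees()
        ours = []
        for level in range(1, int(k.max())):
            if (k > level).sum() >= 2 and level in phi_nx:
                ours.append((level, phi_nx[level]))
        expected = float(np.mean([v for _, v in ours]))
        assert mean_rich_club(net) == pytest.approx(expected, abs=1e-12)


def test_index_report_consistency(g5):
    rep = compute_index_report(g5)
    assert rep.P == pytest.approx(2 * g5.m / (g5.n * (g5.n - 1)))
    assert rep.gamma == pytest.approx(rep.C / rep.P)
    assert rep.R >= 0
    d = rep.as_dict()
    assert list(d) == ["R", "V", "r", "C", "gamma", "P", "L", "rc_mean"]
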