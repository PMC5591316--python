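"""Dynamical-network operations against hand calculations and brute force."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ribofret import network, simulate


def _static_traj(positions, masses=None, n_frames=5, ids=None):
    pos = np.asarray(positions, dtype=float)
    coords = np.repeat(pos[None, :, :], n_frames, axis=0)
    n = pos.shape[0]
    return network.NodeTrajectory(
        ids=ids if ids is not None else list(range(n)),
        kinds=["amino_acid"] * n,
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        coords=coords,
    )


class TestComDistance:
    def test_three_four_five(self):
        traj = _static_traj([[0, 0, 0], [3, 4, 0]])
        np.testing.assert_allclose(network.com_distance(traj, [0], [1]), 5.0)

    def test_overlapping_groups_rejected(self):
        traj = _static_traj([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            network.com_distance(traj, [0, 1], [1])

    def test_mass_weighted_centroid_hand_computed(self):
        # group A: nodes at x=0 (m=2) and x=3 (m=1) -> centroid x=1
        traj = _static_traj(
            [[0, 0, 0], [3, 0, 0], [10, 0, 0]], masses=[2.0, 1.0, 5.0]
        )
        d = network.com_distance(traj, [0, 1], [2])
        np.testing.assert_allclose(d, 9.0, atol=1e-12)

    def test_unknown_node_rejected(self):
        traj = _static_traj([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(KeyError):
            network.com_distance(traj, [0], [7])


class TestContactEdges:
    def test_fixed_pair_within_cutoff(self):
        traj = _static_traj([[0, 0, 0], [3, 0, 0]])
        edges = network.contact_edges(traj)
        assert len(edges) == 1
        assert edges.iloc[0]["occupancy"] == 1.0

    @pytest.mark.parametrize("frac,expect_edge", [(0.5, False), (0.75, False), (0.8, True)])
    def test_occupancy_threshold_strict(self, frac, expect_edge):
        n = 20
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = 3.0
        coords[int(n * frac):, 1, 0] = 10.0  # out of cutoff for the rest
        traj = network.NodeTrajectory(
            ids=[0, 1], kinds=["amino_acid"] * 2, masses=np.ones(2), coords=coords
        )
        assert (len(network.contact_edges(traj)) == 1) == expect_edge

    def test_exact_planted_occupancy_fraction(self):
        n = 40
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = 3.0
        coords[33:, 1, 0] = 10.0
        traj = network.NodeTrajectory(
            ids=["a", "b"], kinds=["amino_acid"] * 2, masses=np.ones(2), coords=coords
        )
        edges = network.contact_edges(traj, occupancy=0.5)
        assert edges.iloc[0]["occupancy"] == pytest.approx(33 / 40)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 3, (200, 5, 3))
        traj = network.NodeTrajectory(
            ids=list(range(5)),
            kinds=["amino_acid"] * 5,
            masses=np.ones(5),
            coords=coords,
        )
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = network.NodeTrajectory(
            ids=list(range(5)),
            kinds=["amino_acid"] * 5,
            masses=np.ones(5),
            coords=coords @ rot.T + np.array([5.0, -2.0, 1.0]),
        )
        a = network.contact_edges(traj, cutoff=5.0, occupancy=0.1)
        b = network.contact_edges(moved, cutoff=5.0, occupancy=0.1)
        assert a.to_dict() == b.to_dict()


class TestGeneralizedCorrelation:
    def test_symmetric_with_unit_diagonal(self):
        pos = np.random.default_rng(1).normal(0, 5, (4, 3))
        traj = simulate.generate_node_trajectory(pos, np.eye(4), 500, seed=1)
        c = network.generalized_correlation(traj).matrix
        np.testing.assert_allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.8])
    def test_planted_correlation_recovered(self, target):
        corr = np.eye(2)
        corr[0, 1] = corr[1, 0] = target
        traj = simulate.generate_node_trajectory(
            np.zeros((2, 3)), corr, 10_000, seed=int(target * 10)
        )
        c = network.generalized_correlation(traj).matrix
        assert abs(c[0, 1] - target) < 0.05

    def test_zero_variance_node_zeroed(self):
        coords = np.random.default_rng(2).normal(0, 1, (300, 3, 3))
        coords[:, 2, :] = 0.0
        traj = network.NodeTrajectory(
            ids=[0, 1, 2], kinds=["amino_acid"] * 3, masses=np.ones(3), coords=coords
        )
        c = network.generalized_correlation(traj).matrix
        assert c[0, 2] == 0.0 and c[2, 1] == 0.0 and c[2, 2] == 1.0

    def test_estimator_recorded(self):
        traj = simulate.generate_node_trajectory(np.zeros((2, 3)), np.eye(2), 200)
        assert network.generalized_correlation(traj).estimator == "gaussian_mi"


class TestEdgeWeight:
    def test_perfect_correlation_zero_distance(self):
        assert network.edge_weight(1.0) == 0.0

    def test_direct_evaluation(self):
        assert network.edge_weight(0.1) == pytest.approx(2.302585092994046)

    def test_monotone_decreasing(self):
        c = np.linspace(0.05, 1.0, 50)
        w = network.edge_weight(c)
        assert (np.diff(w) < 0).all()

    def test_zero_maps_to_infinity(self):
        assert network.edge_weight(0.0) == np.inf


def _random_graph(rng, n):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.5:
            g.add_edge(i, j, d=float(rng.integers(1, 10)))
    return g


def _brute_shortest(g, s, t):
    best = None
    for path in nx.all_simple_paths(g, s, t):
        w = sum(g.edges[u, v]["d"] for u, v in zip(path, path[1:]))
        if best is None or w < best[1] - 1e-12 or (abs(w - best[1]) < 1e-12 and path < best[0]):
            best = (path, w)
    return best


class TestCentralNode:
    def test_three_node_chain(self):
        g = nx.Graph()
        g.add_edge("a", "b", d=1.0)
        g.add_edge("b", "c", d=1.0)
        assert network.central_node(g, ["a", "b", "c"]) == "b"

    def test_star_hub(self):
        g = nx.Graph()
        for leaf in "bcde":
            g.add_edge("a", leaf, d=2.0)
        assert network.central_node(g, list("abcde")) == "a"

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(40):
            g = _random_graph(rng, 8)
            if not nx.is_connected(g):
                continue
            checked += 1
            found = network.central_node(g, list(g.nodes))
            lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="d"))
            totals = {u: sum(lengths[u].values()) for u in g.nodes}
            best = min(totals.values())
            assert found == min(u for u, t in totals.items() if t <= best + 1e-12)
        assert checked >= 20

    def test_disconnected_subset_reports_components(self):
        g = nx.Graph()
        g.add_edge("a", "b", d=1.0)
        g.add_node("z")
        with pytest.raises(ValueError, match="disconnected"):
            network.central_node(g, ["a", "b", "z"])


class TestShortestPath:
    def test_chain(self):
        g = nx.Graph()
        g.add_edge("a", "b", d=1.0)
        g.add_edge("b", "c", d=1.0)
        assert network.shortest_path(g, "a", "c") == (["a", "b", "c"], 2.0)

    def test_zero_weight_edge_preferred(self):
        g = nx.Graph()
        g.add_edge("a", "b", d=0.0)  # C = 1 edge
        g.add_edge("b", "c", d=0.0)
        g.add_edge("a", "c", d=0.1)
        path, w = network.shortest_path(g, "a", "c")
        assert path == ["a", "b", "c"]
        assert w == 0.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(4, 9))
            g = _random_graph(rng, n)
            if not nx.has_path(g, 0, n - 1):
                continue
            checked += 1
            p, w = network.shortest_path(g, 0, n - 1)
            bp, bw = _brute_shortest(g, 0, n - 1)
            assert w == pytest.approx(bw)
            assert p == bp  # lexicographic tie-break agrees with brute force
        assert checked >= 30

    def test_no_path_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", d=1.0)
        g.add_node("z")
        with pytest.raises(ValueError):
            network.shortest_path(g, "a", "z")


class TestEdgeCorrelationDelta:
    @staticmethod
    def _graph(c01):
        g = nx.Graph()
        g.add_edge(0, 1, C=c01, d=float(network.edge_weight(c01)), occupancy=1.0)
        g.add_edge(1, 2, C=0.5, d=float(network.edge_weight(0.5)), occupancy=1.0)
        return g

    def test_identical_graphs_zero_deltas(self):
        df = network.edge_correlation_delta(self._graph(0.9), self._graph(0.9))
        assert (df["abs_delta"] == 0).all()

    def test_planted_change_ranks_first(self):
        df = network.edge_correlation_delta(self._graph(0.9), self._graph(0.2))
        assert (df.iloc[0]["u"], df.iloc[0]["v"]) == (0, 1)
        assert df.iloc[0]["abs_delta"] == pytest.approx(0.7)

    def test_symmetric_ranking_under_order_swap(self):
        a = network.edge_correlation_delta(self._graph(0.9), self._graph(0.2))
        b = network.edge_correlation_delta(self._graph(0.2), self._graph(0.9))
        assert list(a["abs_delta"]) == list(b["abs_delta"])
        assert list(a["u"]) == list(b["u"])


class TestSeparatingGroups:
    def test_monotone_com_distance_trend(self):
        # two node groups drifting apart over time: the centroid distance
        # series should trend upward (isotonic slope > 0)
        rng = np.random.default_rng(5)
        n_frames = 400
        drift = np.linspace(0, 10, n_frames)
        coords = np.zeros((n_frames, 4, 3))
        coords[:, 0, 0] = 0 + rng.normal(0, 0.5, n_frames)
        coords[:, 1, 0] = 1 + rng.normal(0, 0.5, n_frames)
        coords[:, 2, 0] = 10 + drift + rng.normal(0, 0.5, n_frames)
        coords[:, 3, 0] = 11 + drift + rng.normal(0, 0.5, n_frames)
        traj = network.NodeTrajectory(
            ids=[0, 1, 2, 3],
            kinds=["nucleobase"] * 4,
            masses=np.ones(4),
            coords=coords,
        )
        d = network.com_distance(traj, [0, 1], [2, 3])
        t = np.arange(n_frames)
        slope = np.polyfit(t, d, 1)[0]
        assert slope > 0


class TestTrajectoryIO:
    def test_roundtrip(self, tmp_path):
        traj = simulate.generate_node_trajectory(
            np.random.default_rng(6).normal(0, 5, (4, 3)), np.eye(4), 20, seed=6
        )
        network.write_trajectory(traj, tmp_path / "c.tsv", tmp_path / "n.csv")
        back = network.read_trajectory(tmp_path / "c.tsv", tmp_path / "n.csv")
        np.testing.assert_allclose(back.coords, traj.coords)
        assert back.ids == traj.ids
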