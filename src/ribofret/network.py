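"""Dynamical-network reanalysis of coarse-grained trajectories.

A trajectory is coarse-grained into nodes (amino acids, nucleobases,
nucleotide sugars).  Contact edges are kept where the inter-node distance
stays below a cutoff for more than an occupancy threshold of the frames;
edges are weighted by the generalized correlation ``C_ij`` of the node
motions mapped through ``d = -log|C_ij|`` so that strongly correlated pairs
are "close".  Allosteric communication is then read off closeness centers
and shortest paths in this weighted graph.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NodeTrajectory",
    "CorrelationResult",
    "com_distance",
    "contact_edges",
    "generalized_correlation",
    "edge_weight",
    "build_correlation_graph",
    "central_node",
    "shortest_path",
    "edge_correlation_delta",
    "write_trajectory",
    "read_trajectory",
]

NODE_KINDS = ("amino_acid", "nucleobase", "sugar")


@dataclass
class NodeTrajectory:
    """Per-frame 3D coordinates of coarse-grained nodes plus node metadata.

    ``coords`` has shape ``(n_frames, n_nodes, 3)`` in angstroms.
    """

    ids: list
    kinds: list[str]
    masses: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_nodes, 3)")
        n = self.coords.shape[1]
        if not (len(self.ids) == len(self.kinds) == len(self.masses) == n):
            raise ValueError("node metadata length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if (self.masses <= 0).any():
            raise ValueError("node masses must be > 0")
        self._index = {nid: i for i, nid in enumerate(self.ids)}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[1]

    def indices(self, node_ids) -> np.ndarray:
        missing = [nid for nid in node_ids if nid not in self._index]
        if missing:
            raise KeyError(f"unknown node id(s): {missing}")
        return np.array([self._index[nid] for nid in node_ids], dtype=int)

    def displacements(self) -> np.ndarray:
        """Coordinates minus the per-node trajectory mean."""
        return self.coords - self.coords.mean(axis=0, keepdims=True)


def com_distance(traj: NodeTrajectory, group_a, group_b) -> np.ndarray:
    """Per-frame distance between the mass-weighted centroids of two node
    groups (angstroms)."""
    ia = traj.indices(list(group_a))
    ib = traj.indices(list(group_b))
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("groups must be non-empty")
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")

    def com(idx: np.ndarray) -> np.ndarray:
        m = traj.masses[idx]
        return (traj.coords[:, idx, :] * m[None, :, None]).sum(axis=1) / m.sum()

    return np.linalg.norm(com(ia) - com(ib), axis=1)


def contact_edges(
    traj: NodeTrajectory, cutoff: float = 4.5, occupancy: float = 0.75
) -> pd.DataFrame:
    """Occupancy-filtered contacts between node pairs.

    Occupancy is the fraction of frames with inter-node distance strictly
    below ``cutoff`` (angstroms); a pair becomes an edge only when its
    occupancy is strictly greater than the ``occupancy`` threshold.
    Distances use the coarse-grained node positions.
    """
    if traj.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rows = []
    for i, j in itertools.combinations(range(traj.n_nodes), 2):
        d = np.linalg.norm(traj.coords[:, i, :] - traj.coords[:, j, :], axis=1)
        occ = float(np.mean(d < cutoff))
        if occ > occupancy:
            rows.append((traj.ids[i], traj.ids[j], occ))
    return pd.DataFrame(rows, columns=["u", "v", "occupancy"])


@dataclass
class CorrelationResult:
    """Generalized correlation matrix plus the estimator that produced it."""

    matrix: np.ndarray
    estimator: str
    node_ids: list = field(default_factory=list)


def _gaussian_mi_correlation(disp: np.ndarray) -> np.ndarray:
    """Mutual-information generalized correlation under a Gaussian model.

    For 3D displacement vectors the MI is estimated from the 6x6 joint
    covariance, ``MI = 0.5 * ln(det(S_ii) det(S_jj) / det(S))``, and mapped
    to [0, 1] via ``r = sqrt(1 - exp(-2 MI / 3))``.
    """
    n_frames, n_nodes, _ = disp.shape
    flat = disp.transpose(1, 2, 0).reshape(n_nodes * 3, n_frames)
    cov = np.cov(flat)
    c = np.eye(n_nodes)
    logdet_marg = np.empty(n_nodes)
    for i in range(n_nodes):
        s = cov[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
        logdet_marg[i] = np.linalg.slogdet(s)[1]
    for i, j in itertools.combinations(range(n_nodes), 2):
        sel = np.r_[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
        joint = cov[np.ix_(sel, sel)]
        mi = 0.5 * (logdet_marg[i] + logdet_marg[j] - np.linalg.slogdet(joint)[1])
        mi = max(mi, 0.0)
        c[i, j] = c[j, i] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * mi / 3.0)))
    return c


def _pearson_correlation(disp: np.ndarray) -> np.ndarray:
    """|Pearson| of the vector displacements: <dri.drj>/sqrt(<dri^2><drj^2>)."""
    n_nodes = disp.shape[1]
    dots = np.einsum("fik,fjk->ij", disp, disp) / disp.shape[0]
    var = np.diag(dots)
    c = np.abs(dots) / np.sqrt(np.outer(var, var))
    np.fill_diagonal(c, 1.0)
    return c


def generalized_correlation(
    traj: NodeTrajectory, estimator: str = "gaussian_mi"
) -> CorrelationResult:
    """Pairwise generalized correlations of node motions, in [0, 1].

    ``estimator`` is ``"gaussian_mi"`` (default; mutual-information form
    under a Gaussian assumption) or ``"pearson"`` (absolute normalized
    vector covariance).  Zero-variance nodes get zero correlation to every
    other node, with a warning.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for correlations")
    if traj.n_frames < 100:
        logger.warning(
            "generalized_correlation on %d frames; >= 100 recommended",
            traj.n_frames,
        )
    disp = traj.displacements()
    var = (disp**2).sum(axis=2).mean(axis=0)
    dead = var < 1e-20
    if dead.any():
        logger.warning("%d zero-variance node(s); correlations set to 0", dead.sum())
        disp = disp.copy()
        disp[:, dead, :] = np.nan  # excluded below
    if estimator == "gaussian_mi":
        live = ~dead
        c = np.eye(traj.n_nodes)
        if live.sum() >= 2:
            sub = _gaussian_mi_correlation(disp[:, live, :])
            c[np.ix_(live, live)] = sub
        c[dead, :] = 0.0
        c[:, dead] = 0.0
        np.fill_diagonal(c, 1.0)
    elif estimator == "pearson":
        disp2 = np.where(np.isnan(disp), 0.0, disp)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = _pearson_correlation(disp2)
        c[dead, :] = 0.0
        c[:, dead] = 0.0
        np.fill_diagonal(c, 1.0)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return CorrelationResult(matrix=c, estimator=estimator, node_ids=list(traj.ids))


def edge_weight(c):
    """Correlation-to-distance map ``d = -log|C|`` (natural log).

    Nonnegative for ``|C| <= 1``; ``C = 0`` maps to ``+inf`` (edge
    effectively absent).
    """
    c = np.abs(np.asarray(c, dtype=float))
    if (c > 1.0 + 1e-12).any():
        raise ValueError("|C| must be <= 1")
    with np.errstate(divide="ignore"):
        return -np.log(np.minimum(c, 1.0))


def build_correlation_graph(
    traj: NodeTrajectory,
    cutoff: float = 4.5,
    occupancy: float = 0.75,
    estimator: str = "gaussian_mi",
) -> nx.Graph:
    """Contact graph with generalized-correlation edge weights.

    Edge attributes: ``occupancy``, ``C`` and the distance weight ``d``.
    Graph attributes record the parameters and the correlation estimator.
    """
    edges = contact_edges(traj, cutoff=cutoff, occupancy=occupancy)
    corr = generalized_correlation(traj, estimator=estimator)
    index = {nid: i for i, nid in enumerate(traj.ids)}
    g = nx.Graph(cutoff=cutoff, occupancy=occupancy, estimator=corr.estimator)
    for nid, kind, mass in zip(traj.ids, traj.kinds, traj.masses):
        g.add_node(nid, kind=kind, mass=float(mass))
    for _, row in edges.iterrows():
        c = float(corr.matrix[index[row.u], index[row.v]])
        g.add_edge(row.u, row.v, occupancy=float(row.occupancy), C=c,
                   d=float(edge_weight(c)))
    return g


def _finite_view(graph: nx.Graph) -> nx.Graph:
    """Subgraph without infinite-weight (C = 0) edges."""
    keep = [(u, v) for u, v, d in graph.edges(data="d") if math.isfinite(d)]
    h = nx.Graph()
    h.add_nodes_from(graph.nodes(data=True))
    for u, v in keep:
        h.add_edge(u, v, **graph.edges[u, v])
    return h


def central_node(graph: nx.Graph, subset):
    """Closeness center of ``subset``: the member minimizing the sum of
    shortest-path distances (weight ``d``) to all other members; ties broken
    by lowest node id."""
    subset = list(subset)
    missing = [n for n in subset if n not in graph]
    if missing:
        raise KeyError(f"unknown node(s): {missing}")
    h = _finite_view(graph)
    totals = {}
    for u in subset:
        lengths = nx.single_source_dijkstra_path_length(h, u, weight="d")
        if any(v not in lengths for v in subset):
            comp = [sorted(c & set(subset)) for c in nx.connected_components(h)
                    if c & set(subset)]
            raise ValueError(f"subset is disconnected; components: {comp}")
        totals[u] = sum(lengths[v] for v in subset)
    best = min(totals.values())
    return min(u for u, t in totals.items() if t <= best + 1e-12)


def shortest_path(graph: nx.Graph, source, target):
    """Minimum-weight path on weights ``d`` (Dijkstra); among equal-weight
    optima the lexicographically smallest node sequence is returned.

    Returns ``(path, total_weight)``.
    """
    h = _finite_view(graph)
    try:
        paths = list(nx.all_shortest_paths(h, source, target, weight="d"))
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise ValueError(f"no path between {source!r} and {target!r}") from exc
    path = min(paths)
    weight = sum(h.edges[u, v]["d"] for u, v in zip(path[:-1], path[1:]))
    return path, weight


def edge_correlation_delta(graph_a: nx.Graph, graph_b: nx.Graph) -> pd.DataFrame:
    """Shared edges ranked by the magnitude of their correlation change
    ``|C_A - C_B|`` (descending)."""
    shared = set(map(frozenset, graph_a.edges())) & set(
        map(frozenset, graph_b.edges())
    )
    if not shared:
        logger.warning("edge_correlation_delta: no shared edges")
        return pd.DataFrame(columns=["u", "v", "c_a", "c_b", "delta", "abs_delta"])
    rows = []
    for e in shared:
        u, v = sorted(e)
        ca = graph_a.edges[u, v]["C"]
        cb = graph_b.edges[u, v]["C"]
        rows.append((u, v, ca, cb, ca - cb, abs(ca - cb)))
    df = pd.DataFrame(rows, columns=["u", "v", "c_a", "c_b", "delta", "abs_delta"])
    return df.sort_values(["abs_delta", "u", "v"], ascending=[False, True, True]
                          ).reset_index(drop=True)


def write_trajectory(traj: NodeTrajectory, coords_path, nodes_path) -> None:
    """Flat coordinate table (frame, node_id, x, y, z) + node metadata CSV."""
    n_f, n_n = traj.n_frames, traj.n_nodes
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_f), n_n),
            "node_id": np.tile(np.asarray(traj.ids), n_f),
            "x": traj.coords[:, :, 0].ravel(),
            "y": traj.coords[:, :, 1].ravel(),
            "z": traj.coords[:, :, 2].ravel(),
        }
    )
    df.to_csv(coords_path, sep="\t", index=False)
    pd.DataFrame(
        {"node_id": traj.ids, "kind": traj.kinds, "mass": traj.masses}
    ).to_csv(nodes_path, index=False)


def read_trajectory(coords_path, nodes_path) -> NodeTrajectory:
    coords = pd.read_csv(coords_path, sep="\t")
    nodes = pd.read_csv(nodes_path)
    ids = list(nodes["node_id"])
    order = {nid: i for i, nid in enumerate(ids)}
    n_frames = int(coords["frame"].max()) + 1
    arr = np.full((n_frames, len(ids), 3), np.nan)
    fi = coords["frame"].to_numpy()
    ni = coords["node_id"].map(order).to_numpy()
    arr[fi, ni, 0] = coords["x"]
    arr[fi, ni, 1] = coords["y"]
    arr[fi, ni, 2] = coords["z"]
    return NodeTrajectory(
        ids=ids,
        kinds=list(nodes["kind"]),
        masses=nodes["mass"].to_numpy(),
        coords=arr,
    )
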