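"""Thresholded functional brain networks and their topology indices.

Each 20 s window's MI matrix becomes a graph over the montage leads: an
edge joins two leads when their mutual information strictly exceeds the
window's threshold, by default the arithmetic mean of all off-diagonal MI
entries of that window ("uniform MI of all channels").  MI weights are
retained so the binary and weighted views coexist on the same object.

Topology indices follow the standard graph-theoretic definitions: node
degree and its distribution, average shortest-path length in hops (over
connected ordered pairs only, with the connected fraction reported), and
the average local clustering coefficient.  Core nodes are ranked by total
binary degree summed over all windows; the per-window top-k strongest MI
pairs and a degree-quantile activation rule operationalize the propagation
path of synchronous discharge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .mutual_information import MIMatrix

__all__ = [
    "BrainNetwork",
    "NetworkMetrics",
    "CoreNodeReport",
    "PropagationPath",
    "MetricTrajectory",
    "build_network",
    "degree_metrics",
    "network_metrics",
    "average_path_length",
    "average_clustering",
    "core_nodes",
    "top_k_edges",
    "propagation_path",
    "metric_trajectory",
]


@dataclass
class BrainNetwork:
    """One window's thresholded graph over the montage leads.

    ``edges`` maps each unordered 0-based channel pair (i, j), i < j, to its
    MI weight in bits; ``binary(i, j)`` is 1 iff the weight strictly exceeds
    the threshold.  Only supra-threshold pairs are stored as edges.
    """

    node_names: list[str]
    edges: dict[tuple[int, int], float]
    threshold: float
    window_id: Optional[int] = None
    period: Optional[str] = None
    weights: Optional[np.ndarray] = None  # full MI matrix, for the weighted view

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self, weighted: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for (i, j), w in self.edges.items():
            if weighted:
                g.add_edge(i, j, weight=w)
            else:
                g.add_edge(i, j)
        return g

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d


def build_network(mi: MIMatrix, threshold: Optional[float] = None,
                  ) -> BrainNetwork:
    """Binarize an MI matrix at the mean-MI threshold.

    The default threshold is the arithmetic mean of the window's off-diagonal
    MI entries; pass an explicit ``threshold`` (e.g. a whole-recording mean)
    to override.  Edges require *strictly* greater MI, so an all-equal matrix
    yields an empty graph (warned, not an error).
    """
    offdiag = mi.offdiag()
    thr = float(np.mean(offdiag)) if threshold is None else float(threshold)
    edges = {
        (i, j): w for i, j, w in mi.pair_items() if w > thr
    }
    if not edges:
        warnings.warn(
            f"window {mi.window_id}: no MI entry strictly exceeds the "
            f"threshold {thr:.4g}; network is empty", stacklevel=2,
        )
    return BrainNetwork(node_names=list(mi.channel_names), edges=edges,
                        threshold=thr, window_id=mi.window_id,
                        period=mi.period, weights=mi.values.copy())


@dataclass(frozen=True)
class NetworkMetrics:
    """Topology indices of one window's binary network."""

    degrees: np.ndarray
    degree_distribution: np.ndarray  # histogram over degree 0 .. n-1
    average_path_length: float  # NaN when the graph has no edge
    average_clustering: float
    n_edges: int
    connected_pair_fraction: float

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())


def degree_metrics(net: BrainNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node binary degrees and their histogram over 0 .. n-1."""
    d = net.degrees()
    hist = np.bincount(d, minlength=net.n_nodes)[: net.n_nodes]
    return d, hist


def average_path_length(net: BrainNetwork) -> tuple[float, float]:
    """Mean shortest-path hop count over connected ordered node pairs.

    Returns (average, connected_pair_fraction).  Pairs in different
    components are excluded from the mean; an edgeless network has no
    defined path length and returns (NaN, 0.0).
    """
    n = net.n_nodes
    if net.n_edges == 0:
        return float("nan"), 0.0
    g = net.to_networkx()
    total = 0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for target, hops in dists.items():
            if hops > 0:
                total += hops
                count += 1
    n_ordered = n * (n - 1)
    if count == 0:
        return float("nan"), 0.0
    return total / count, count / n_ordered


def average_clustering(net: BrainNetwork) -> float:
    """Average local clustering coefficient (degree < 2 nodes count as 0)."""
    if net.n_nodes == 0:
        return 0.0
    return float(nx.average_clustering(net.to_networkx()))


def network_metrics(net: BrainNetwork) -> NetworkMetrics:
    """All topology indices of one network in a single report."""
    d, hist = degree_metrics(net)
    apl, frac = average_path_length(net)
    return NetworkMetrics(
        degrees=d, degree_distribution=hist, average_path_length=apl,
        average_clustering=average_clustering(net), n_edges=net.n_edges,
        connected_pair_fraction=frac,
    )


@dataclass(frozen=True)
class CoreNodeReport:
    """Total binary degree per lead summed over every window of every period.

    ``ranking`` lists 0-based channel indices by descending total degree,
    ties broken by montage position (stable, reproducible).
    """

    node_names: list[str]
    total_degree: np.ndarray
    ranking: list[int]

    def top(self, k: int) -> list[tuple[str, int]]:
        return [(self.node_names[i], int(self.total_degree[i]))
                for i in self.ranking[:k]]


def core_nodes(nets: Sequence[BrainNetwork]) -> CoreNodeReport:
    """Rank leads by summed degree across all windows; the top lead is the
    most active node of the whole episode."""
    if not nets:
        raise ValueError("need at least one network")
    names = nets[0].node_names
    totals = np.zeros(len(names), dtype=int)
    for net in nets:
        if net.node_names != names:
            raise ValueError("networks have mismatched node sets")
        totals += net.degrees()
    order = sorted(range(len(names)), key=lambda i: (-totals[i], i))
    return CoreNodeReport(node_names=list(names), total_degree=totals,
                          ranking=order)


def top_k_edges(mi: MIMatrix, k: int = 20) -> list[tuple[int, int, float]]:
    """The k unordered channel pairs with largest MI, descending.

    Ties are broken lexicographically by (smaller index, larger index).
    ``k`` beyond the number of available pairs returns all pairs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = sorted(mi.pair_items(), key=lambda t: (-t[2], t[0], t[1]))
    return [(i, j, w) for i, j, w in pairs[:k]]


@dataclass(frozen=True)
class Activation:
    """One node's first activation: window, channel, degree, strongest edge."""

    window_pos: int
    window_id: Optional[int]
    channel: int
    degree: int
    strongest_partner: Optional[int]
    strongest_mi: float


@dataclass
class PropagationPath:
    """Chronological sequence of node activations across windows.

    A node activates in the first window where its binary degree reaches the
    window's activation quantile (default: top quartile of that window's
    degrees) and is nonzero.  This degree-quantile rule is this package's
    operationalization of the narrative discharge-propagation pathway.
    """

    activations: list[Activation]
    quantile: float
    top_edges: list[list[tuple[int, int, float]]] = field(default_factory=list)

    def order(self) -> list[int]:
        return [a.channel for a in self.activations]


def propagation_path(nets: Sequence[BrainNetwork],
                     quantile: float = 0.75,
                     top_k: int = 20) -> PropagationPath:
    """Extract the activation path from chronologically ordered networks.

    Within a window, newly activated nodes are listed in montage order
    (deterministic tie-break).  Each activation is annotated with the node's
    strongest incident MI edge in that window.
    """
    if len(nets) < 1:
        raise ValueError("need at least one network")
    activations: list[Activation] = []
    seen: set[int] = set()
    tops: list[list[tuple[int, int, float]]] = []
    for pos, net in enumerate(nets):
        d = net.degrees()
        if net.weights is not None:
            m = MIMatrix(values=net.weights,
                         channel_names=net.node_names,
                         window_id=net.window_id, period=net.period)
            tops.append(top_k_edges(m, top_k))
        active = d[d > 0]
        if active.size == 0:
            continue
        # quantile over participating nodes, upper interpolation: a lone
        # hub activates alone, a uniform graph activates everyone
        thr = np.quantile(active, quantile, method="higher")
        for ch in range(net.n_nodes):
            if ch in seen or d[ch] == 0 or d[ch] < thr:
                continue
            partner, best = None, -np.inf
            for (i, j), w in net.edges.items():
                if i == ch or j == ch:
                    other = j if i == ch else i
                    if w > best:
                        partner, best = other, w
            activations.append(Activation(
                window_pos=pos, window_id=net.window_id, channel=ch,
                degree=int(d[ch]), strongest_partner=partner,
                strongest_mi=float(best) if partner is not None else float("nan"),
            ))
            seen.add(ch)
    if not activations:
        warnings.warn("no node reached the activation quantile in any window",
                      stacklevel=2)
    return PropagationPath(activations=activations, quantile=quantile,
                           top_edges=tops)


@dataclass
class MetricTrajectory:
    """Per-window topology-index series across the seizure course."""

    window_ids: list[Optional[int]]
    periods: list[Optional[str]]
    mean_degree: np.ndarray
    avg_path_length: np.ndarray  # NaN marks undefined (edgeless) windows
    avg_clustering: np.ndarray
    n_edges: np.ndarray
    connected_pair_fraction: np.ndarray


def metric_trajectory(nets: Sequence[BrainNetwork]) -> MetricTrajectory:
    """Degree / path-length / clustering trajectories over chronological
    windows; undefined path lengths carry NaN."""
    if not nets:
        raise ValueError("need at least one network")
    rows = [network_metrics(net) for net in nets]
    return MetricTrajectory(
        window_ids=[net.window_id for net in nets],
        periods=[net.period for net in nets],
        mean_degree=np.array([r.mean_degree for r in rows]),
        avg_path_length=np.array([r.average_path_length for r in rows]),
        avg_clustering=np.array([r.average_clustering for r in rows]),
        n_edges=np.array([r.n_edges for r in rows]),
        connected_pair_fraction=np.array(
            [r.connected_pair_fraction for r in rows]),
    )
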