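"""Graph construction and topology indices against brute-force oracles."""

from collections import deque
from itertools import combinations

import numpy as np
import pytest

from seiznet.brain_network import (BrainNetwork, average_clustering,
                                   average_path_length, build_network,
                                   core_nodes, degree_metrics,
                                   metric_trajectory, network_metrics,
                                   propagation_path, top_k_edges)
from seiznet.mutual_information import MIMatrix


def make_matrix(values, names=None, window_id=0, period=None):
    v = np.asarray(values, dtype=float)
    return MIMatrix(values=v, channel_names=names or
                    [f"c{i}" for i in range(v.shape[0])],
                    window_id=window_id, period=period)


def random_symmetric(rng, n):
    a = rng.random((n, n))
    v = (a + a.T) / 2
    np.fill_diagonal(v, 1.0)
    return v


def graph_from_edges(n, pairs, weight=0.9):
    v = np.full((n, n), 0.0)
    for i, j in pairs:
        v[i, j] = v[j, i] = weight
    np.fill_diagonal(v, 1.0)
    return build_network(make_matrix(v), threshold=weight / 2)


# --- BFS and triangle oracles (independent of networkx) -----------------

def bfs_apl_oracle(n, pairs):
    adj = {i: set() for i in range(n)}
    for i, j in pairs:
        adj[i].add(j)
        adj[j].add(i)
    total, count = 0, 0
    for s in range(n):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        for t, d in dist.items():
            if t != s:
                total += d
                count += 1
    return (total / count if count else float("nan"),
            count / (n * (n - 1)) if n > 1 else 0.0)


def clustering_oracle(n, pairs):
    adj = {i: set() for i in range(n)}
    for i, j in pairs:
        adj[i].add(j)
        adj[j].add(i)
    cs = []
    for v in range(n):
        k = len(adj[v])
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a, b in combinations(sorted(adj[v]), 2)
                    if b in adj[a])
        cs.append(links / (k * (k - 1) / 2))
    return sum(cs) / n


# --- thresholding -------------------------------------------------------

def test_single_outlier_pair_yields_one_edge():
    v = np.full((5, 5), 0.2)
    np.fill_diagonal(v, 1.0)
    v[1, 3] = v[3, 1] = 0.9
    net = build_network(make_matrix(v))
    assert set(net.edges) == {(1, 3)}


def test_all_equal_offdiagonals_yield_empty_graph():
    v = np.full((6, 6), 0.5)
    np.fill_diagonal(v, 1.0)
    with pytest.warns(UserWarning, match="empty"):
        net = build_network(make_matrix(v))
    assert net.n_edges == 0


def test_threshold_equals_offdiagonal_mean_and_edges_match_bruteforce(rng):
    for _ in range(25):
        v = random_symmetric(rng, 6)
        net = build_network(make_matrix(v))
        iu = np.triu_indices(6, k=1)
        assert net.threshold == pytest.approx(v[iu].mean(), abs=1e-15)
        expected = {(i, j) for i in range(6) for j in range(i + 1, 6)
                    if v[i, j] > net.threshold}
        assert set(net.edges) == expected


def test_raising_threshold_never_adds_edges(rng):
    for _ in range(20):
        v = random_symmetric(rng, 8)
        m = make_matrix(v)
        thresholds = np.sort(rng.random(5))
        prev = None
        for t in thresholds:
            edges = set(build_network(m, threshold=t).edges)
            if prev is not None:
                assert edges.issubset(prev)
            prev = edges


# --- degrees ------------------------------------------------------------

def test_degree_closed_forms():
    complete = graph_from_edges(22, list(combinations(range(22), 2)))
    d, hist = degree_metrics(complete)
    assert (d == 21).all()
    assert hist[21] == 22

    with pytest.warns(UserWarning):
        empty = build_network(make_matrix(np.eye(4)))
    assert (degree_metrics(empty)[0] == 0).all()

    path = graph_from_edges(3, [(0, 1), (1, 2)])
    assert degree_metrics(path)[0].tolist() == [1, 2, 1]


def test_handshake_lemma_on_random_graphs(rng):
    for _ in range(30):
        v = random_symmetric(rng, 9)
        net = build_network(make_matrix(v))
        assert net.degrees().sum() == 2 * net.n_edges


# --- path length --------------------------------------------------------

def test_average_path_length_closed_forms():
    complete = graph_from_edges(6, list(combinations(range(6), 2)))
    assert average_path_length(complete)[0] == pytest.approx(1.0)

    path = graph_from_edges(3, [(0, 1), (1, 2)])
    apl, frac = average_path_length(path)
    assert apl == pytest.approx(4 / 3)
    assert frac == pytest.approx(1.0)

    with pytest.warns(UserWarning):
        empty = build_network(make_matrix(np.eye(4)))
    assert np.isnan(average_path_length(empty)[0])


def test_average_path_length_matches_bfs_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(4, 11))
        v = random_symmetric(rng, n)
        net = build_network(make_matrix(v))
        if net.n_edges == 0:
            continue
        apl, frac = average_path_length(net)
        o_apl, o_frac = bfs_apl_oracle(n, list(net.edges))
        assert apl == pytest.approx(o_apl, rel=1e-12)
        assert frac == pytest.approx(o_frac, rel=1e-12)


def test_disconnected_pairs_excluded_from_mean():
    # two disjoint edges: only within-component pairs count
    net = graph_from_edges(4, [(0, 1), (2, 3)])
    apl, frac = average_path_length(net)
    assert apl == pytest.approx(1.0)
    assert frac == pytest.approx(4 / 12)


# --- clustering ---------------------------------------------------------

def test_clustering_closed_forms():
    triangle = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
    assert average_clustering(triangle) == pytest.approx(1.0)

    star = graph_from_edges(5, [(0, j) for j in range(1, 5)])
    assert average_clustering(star) == pytest.approx(0.0)

    # 4-cycle plus one chord: nodes on the chord have c=1/3... enumerate
    chorded = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
    assert average_clustering(chorded) == pytest.approx(
        clustering_oracle(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)]))


def test_clustering_matches_triangle_enumeration_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(4, 11))
        v = random_symmetric(rng, n)
        net = build_network(make_matrix(v))
        assert average_clustering(net) == pytest.approx(
            clustering_oracle(n, list(net.edges)), rel=1e-12)


def test_metric_ranges_on_random_graphs(rng):
    for _ in range(30):
        v = random_symmetric(rng, 10)
        met = network_metrics(build_network(make_matrix(v)))
        assert 0.0 <= met.average_clustering <= 1.0
        assert ((0 <= met.degrees) & (met.degrees <= 9)).all()
        if met.n_edges:
            assert met.average_path_length >= 1.0


# --- top-k edges --------------------------------------------------------

def test_top_k_unique_maximum():
    v = np.full((5, 5), 0.1)
    np.fill_diagonal(v, 1.0)
    v[2, 4] = v[4, 2] = 0.8
    assert top_k_edges(make_matrix(v), k=1)[0][:2] == (2, 4)


def test_top_k_saturates_to_all_pairs(rng):
    v = random_symmetric(rng, 6)
    got = top_k_edges(make_matrix(v), k=100)
    assert len(got) == 15
    weights = [w for _, _, w in got]
    assert weights == sorted(weights, reverse=True)


def test_top_20_matches_full_sort_oracle(rng):
    for _ in range(20):
        v = random_symmetric(rng, 22)
        m = make_matrix(v)
        got = top_k_edges(m, k=20)
        full = sorted(((i, j, v[i, j]) for i in range(22)
                       for j in range(i + 1, 22)),
                      key=lambda t: (-t[2], t[0], t[1]))
        assert got == full[:20]
        # every kept weight >= every excluded weight
        assert min(w for _, _, w in got) >= max(w for _, _, w in full[20:])


# --- core nodes ---------------------------------------------------------

def test_core_nodes_single_window_equals_degree_order(rng):
    v = random_symmetric(rng, 7)
    net = build_network(make_matrix(v))
    rep = core_nodes([net])
    d = net.degrees()
    assert all(d[rep.ranking[k]] >= d[rep.ranking[k + 1]]
               for k in range(6))
    assert rep.total_degree.tolist() == d.tolist()


def test_core_nodes_complementary_stars_tie():
    a = graph_from_edges(6, [(0, j) for j in range(1, 6)])
    b = graph_from_edges(6, [(1, j) for j in [0, 2, 3, 4, 5]])
    rep = core_nodes([a, b])
    assert rep.total_degree[0] == rep.total_degree[1] == 6
    assert rep.ranking[:2] == [0, 1]  # tie broken by montage position


# --- propagation path ---------------------------------------------------

def test_single_hub_activation():
    hub = graph_from_edges(6, [(2, j) for j in (0, 1, 3)])
    p = propagation_path([hub], quantile=0.75)
    assert p.activations[0].channel == 2
    assert p.activations[0].window_pos == 0
    assert p.activations[0].strongest_partner in (0, 1, 3)


def test_staged_activation_orders_regions():
    # window 0: clique on {0,1,2}; window 1: clique on {3,4,5} too
    w0 = graph_from_edges(6, list(combinations([0, 1, 2], 2)))
    w1 = graph_from_edges(6, list(combinations([0, 1, 2], 2)) +
                          list(combinations([3, 4, 5], 2)))
    p = propagation_path([w0, w1], quantile=0.5)
    order = p.order()
    assert order[:3] == [0, 1, 2]
    assert set(order[3:]) == {3, 4, 5}


def test_uniform_graph_activates_in_montage_order():
    complete = graph_from_edges(5, list(combinations(range(5), 2)))
    p = propagation_path([complete, complete], quantile=0.75)
    assert p.order() == [0, 1, 2, 3, 4]
    assert all(a.window_pos == 0 for a in p.activations)


def test_no_activation_warns():
    with pytest.warns(UserWarning):
        empty = build_network(make_matrix(np.eye(4)))
    with pytest.warns(UserWarning, match="activation"):
        p = propagation_path([empty])
    assert p.activations == []


# --- trajectories -------------------------------------------------------

def test_identical_networks_give_constant_trajectories(rng):
    v = random_symmetric(rng, 8)
    nets = [build_network(make_matrix(v, window_id=i)) for i in range(4)]
    t = metric_trajectory(nets)
    assert np.ptp(t.mean_degree) == 0
    assert np.ptp(t.avg_path_length) == 0
    assert np.ptp(t.avg_clustering) == 0
    assert t.window_ids == [0, 1, 2, 3]


def test_edgeless_window_carries_undefined_marker():
    with pytest.warns(UserWarning):
        empty = build_network(make_matrix(np.eye(5), window_id=0))
    full = graph_from_edges(5, list(combinations(range(5), 2)))
    t = metric_trajectory([empty, full])
    assert np.isnan(t.avg_path_length[0])
    assert t.avg_path_length[1] == pytest.approx(1.0)
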