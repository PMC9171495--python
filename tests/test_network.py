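"""Network-level tests: trial averaging, cost thresholding, snapshots, and
directed global efficiency (against an independent BFS oracle)."""

from collections import deque

import numpy as np
import pytest

from tvconn.containers import BinaryNetwork, TimeVaryingConnectivity
from tvconn.network import (average_trials, ge_series, global_efficiency,
                            snapshot, threshold_cost)


def bfs_global_efficiency(adj: np.ndarray) -> float:
    """Independent oracle: all-pairs BFS hop counts, mean of 1/d."""
    n = adj.shape[0]
    total = 0.0
    for s in range(n):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[v, u] and v not in dist:  # [sink, source] convention
                    dist[v] = dist[u] + 1
                    q.append(v)
        for v, d in dist.items():
            if v != s:
                total += 1.0 / d
    return total / (n * (n - 1))


def tvc_from_theta(theta, times=None, labels=None):
    theta = np.asarray(theta, dtype=float)
    T, n = theta.shape[0], theta.shape[1]
    if times is None:
        times = np.arange(T, dtype=float)
    if labels is None:
        labels = [f"ch{i+1}" for i in range(n)]
    return TimeVaryingConnectivity(theta=theta, band=(8.0, 30.0),
                                   times=np.asarray(times, dtype=float),
                                   channel_labels=labels)


class TestAverageTrials:
    def test_single_trial_identity(self):
        a = tvc_from_theta(np.full((3, 2, 2), 0.5))
        assert np.allclose(average_trials([a]).theta, a.theta)

    def test_mean_of_two(self):
        a = tvc_from_theta(np.full((2, 2, 2), 0.2))
        b = tvc_from_theta(np.full((2, 2, 2), 0.4))
        assert np.allclose(average_trials([a, b]).theta, 0.3)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        mats = [tvc_from_theta(rng.uniform(0, 1, (2, 3, 3))) for _ in range(4)]
        fwd = average_trials(mats).theta
        rev = average_trials(mats[::-1]).theta
        assert np.allclose(fwd, rev)

    def test_shape_mismatch_rejected(self):
        a = tvc_from_theta(np.full((2, 2, 2), 0.5))
        b = tvc_from_theta(np.full((3, 2, 2), 0.5))
        with pytest.raises(ValueError):
            average_trials([a, b])


class TestThresholdCost:
    def test_five_percent_of_21_nodes_is_21_edges(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 1, (21, 21))
        net = threshold_cost(W, 0.05)
        assert net.n_edges == 21

    def test_full_cost_gives_complete_digraph(self):
        W = np.random.default_rng(2).uniform(0, 1, (5, 5))
        net = threshold_cost(W, 1.0)
        assert net.n_edges == 20
        assert np.all(np.diag(net.adjacency) == 0)

    def test_equal_weights_resolved_by_tie_rule(self):
        W = np.ones((6, 6))
        net = threshold_cost(W, 0.2)  # round(0.2*30) = 6 edges
        assert net.n_edges == 6
        again = threshold_cost(W, 0.2)
        assert np.array_equal(net.adjacency, again.adjacency)

    def test_strongest_edges_selected(self):
        W = np.zeros((4, 4))
        W[1, 0], W[2, 3], W[0, 2] = 0.9, 0.8, 0.7
        net = threshold_cost(W, 3 / 12)
        assert net.adjacency[1, 0] == net.adjacency[2, 3] == net.adjacency[0, 2] == 1
        assert net.n_edges == 3

    def test_zero_edge_cost_warns(self):
        W = np.random.default_rng(3).uniform(0, 1, (3, 3))
        with pytest.warns(UserWarning):
            net = threshold_cost(W, 0.05)  # round(0.05*6) = 0
        assert net.n_edges == 0


class TestSnapshot:
    def test_task_window_with_default_interval(self):
        times = np.arange(0, 601) / 100.0  # [0, 6] s at 100 Hz
        tvc = tvc_from_theta(np.random.default_rng(4).uniform(0, 1, (601, 3, 3)),
                             times=times)
        nets = snapshot(tvc, 1.5, cost=0.5)
        assert [n.time for n in nets] == [0.0, 1.5, 3.0, 4.5, 6.0]

    def test_interval_equal_to_span(self):
        times = np.arange(0, 201) / 100.0
        tvc = tvc_from_theta(np.full((201, 2, 2), 0.5), times=times)
        nets = snapshot(tvc, 2.0, cost=0.5)
        assert [n.time for n in nets] == [0.0, 2.0]

    def test_nearest_sample_mapping(self):
        times = np.arange(0, 301) / 100.0
        theta = np.zeros((301, 2, 2))
        theta[150, 0, 1] = 1.0  # only sample 150 has an edge worth keeping
        tvc = tvc_from_theta(theta, times=times)
        nets = snapshot(tvc, 1.5, cost=0.5)
        assert nets[1].time == pytest.approx(1.5)
        assert nets[1].adjacency[0, 1] == 1


class TestGlobalEfficiency:
    def _net(self, adj):
        adj = np.asarray(adj)
        return BinaryNetwork(adjacency=adj, time=0.0, cost=1.0,
                             channel_labels=[f"n{i}" for i in range(adj.shape[0])])

    def test_complete_graph_is_one(self):
        adj = 1 - np.eye(4, dtype=int)
        assert global_efficiency(self._net(adj)) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(self._net(np.zeros((5, 5), dtype=int))) == 0.0

    def test_directed_path_hand_case(self):
        # 1->2->3: d12=1, d23=1, d13=2, reverse pairs unreachable
        adj = np.zeros((3, 3), dtype=int)
        adj[1, 0] = adj[2, 1] = 1
        assert global_efficiency(self._net(adj)) == pytest.approx(2.5 / 6)

    def test_matches_bfs_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 6))
            adj = (rng.uniform(size=(n, n)) < rng.uniform(0.1, 0.9)).astype(int)
            np.fill_diagonal(adj, 0)
            assert global_efficiency(self._net(adj)) == pytest.approx(
                bfs_global_efficiency(adj), abs=1e-12)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(3, 6))
            adj = (rng.uniform(size=(n, n)) < 0.3).astype(int)
            np.fill_diagonal(adj, 0)
            before = global_efficiency(self._net(adj))
            zeros = np.argwhere((adj == 0) & ~np.eye(n, dtype=bool))
            if zeros.size == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            adj2 = adj.copy()
            adj2[i, j] = 1
            assert global_efficiency(self._net(adj2)) >= before - 1e-12


class TestGeSeries:
    def test_constant_connectivity_gives_constant_series(self):
        theta = np.full((201, 3, 3), 1 / 3.0)
        theta += 0.0
        times = np.arange(201) / 100.0
        s = ge_series(tvc_from_theta(theta, times=times), cost=0.5, interval=0.5)
        assert np.all(s.ge == s.ge[0])

    def test_series_bounded(self):
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 1, (101, 4, 4))
        times = np.arange(101) / 100.0
        s = ge_series(tvc_from_theta(theta, times=times), cost=0.3, interval=0.25)
        assert np.all((s.ge >= 0) & (s.ge <= 1))
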