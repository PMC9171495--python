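"""Graph-level analysis of time-varying connectivity: trial averaging,
cost-based binarisation, network snapshots, and directed global efficiency.

Global efficiency of a directed binary network with n nodes is

    GE = 1 / (n (n−1)) · Σ_{i≠j} 1 / d_ij,

where d_ij is the directed shortest-path hop count from i to j and
unreachable pairs contribute 0 (1/∞).  GE is 1 for the complete directed
graph and 0 for the empty one.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .containers import BinaryNetwork, EfficiencySeries, TimeVaryingConnectivity

__all__ = [
    "average_trials",
    "threshold_cost",
    "snapshot",
    "global_efficiency",
    "ge_series",
]

DEFAULT_COST = 0.05
DEFAULT_SNAPSHOT_INTERVAL = 1.5


def average_trials(trial_connectivities: list[TimeVaryingConnectivity],
                   class_label: str | None = None,
                   trial_labels: list[str] | None = None
                   ) -> TimeVaryingConnectivity:
    """Element-wise mean of per-trial Θ² series (optionally one class only).

    All inputs must share channel labels and time axes; averaging is
    order-independent.
    """
    if class_label is not None:
        if trial_labels is None:
            raise ValueError("class selection requires per-trial labels")
        trial_connectivities = [c for c, l in zip(trial_connectivities, trial_labels)
                                if l == class_label]
    if not trial_connectivities:
        raise ValueError("no trials to average")
    ref = trial_connectivities[0]
    for c in trial_connectivities[1:]:
        if c.theta.shape != ref.theta.shape:
            raise ValueError("mismatched connectivity shapes")
        if tuple(c.channel_labels) != tuple(ref.channel_labels):
            raise ValueError("mismatched channel labels")
        if not np.allclose(c.times, ref.times):
            raise ValueError("mismatched time axes")
    mean = np.mean([c.theta for c in trial_connectivities], axis=0)
    return TimeVaryingConnectivity(theta=mean, band=ref.band, times=ref.times,
                                   channel_labels=ref.channel_labels)


def threshold_cost(W: np.ndarray, cost: float = DEFAULT_COST,
                   channel_labels=None, time: float = 0.0) -> BinaryNetwork:
    """Binarise a weighted directed matrix at a fixed connectivity cost.

    Keeps the ``round(cost · n(n−1))`` strongest off-diagonal weights.
    Ties are broken deterministically by (weight desc, source index,
    target index); the diagonal is always zero.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n) or n < 2:
        raise ValueError("W must be square with n >= 2")
    if not 0 < cost <= 1:
        raise ValueError("cost must lie in (0, 1]")
    m = int(round(cost * n * (n - 1)))
    if m == 0:
        warnings.warn(f"cost {cost} retains 0 of {n * (n - 1)} edges; empty network")
    idx = [(i, j) for i in range(n) for j in range(n) if i != j]
    # entry [i, j] is flow j→i, so the tie-break (source, target) = (j, i)
    order = sorted(range(len(idx)),
                   key=lambda k: (-W[idx[k]], idx[k][1], idx[k][0]))
    adj = np.zeros((n, n), dtype=np.int8)
    for k in order[:m]:
        adj[idx[k]] = 1
    if channel_labels is None:
        channel_labels = tuple(f"ch{i + 1}" for i in range(n))
    return BinaryNetwork(adjacency=adj, channel_labels=channel_labels,
                         time=time, cost=cost)


def snapshot(net_series: TimeVaryingConnectivity,
             interval: float = DEFAULT_SNAPSHOT_INTERVAL,
             cost: float = DEFAULT_COST,
             start: float = 0.0, stop: float | None = None
             ) -> list[BinaryNetwork]:
    """Binary networks at regularly spaced times ``start, start+interval, …``.

    Requested times map to the nearest sample of the series' time grid;
    the default start is stimulus onset (0 s) and the default stop the end
    of the series.
    """
    times = net_series.times
    if stop is None:
        stop = float(times[-1])
    span = stop - start
    if interval <= 0 or interval > span + 1e-9:
        raise ValueError(f"interval {interval} s invalid for span {span} s")
    n_snap = int(np.floor(span / interval + 1e-9)) + 1
    requested = start + interval * np.arange(n_snap)
    nets = []
    for t_req in requested:
        k = int(np.argmin(np.abs(times - t_req)))
        nets.append(threshold_cost(net_series.theta[k], cost,
                                   channel_labels=net_series.channel_labels,
                                   time=float(times[k])))
    if not nets:
        raise ValueError("no snapshot times inside the series")
    return nets


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Directed global efficiency of a binary network (see module docs)."""
    adj = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = shortest_path(adj.astype(float), method="D", directed=True, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def ge_series(subject_connectivity: TimeVaryingConnectivity,
              cost: float = DEFAULT_COST,
              interval: float = DEFAULT_SNAPSHOT_INTERVAL,
              start: float = 0.0, stop: float | None = None,
              subject: str = "", condition: str = "") -> EfficiencySeries:
    """Global efficiency of the cost-thresholded network at each grid time."""
    nets = snapshot(subject_connectivity, interval, cost, start, stop)
    times = np.array([net.time for net in nets])
    ge = np.array([global_efficiency(net) for net in nets])
    return EfficiencySeries(times=times, ge=ge, subject=subject, condition=condition)
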