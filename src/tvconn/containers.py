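"""Core in-memory containers shared across the pipeline.

All containers are thin dataclasses around numpy arrays with validated
invariants.  Conventions used throughout the package:

* EEG amplitudes are in microvolts (μV), sampling rates in Hz.
* Trial time axes are in seconds relative to stimulus onset (0 s = onset);
  epochs use a closed-left / open-right window, so a [−4 s, 6 s) window at
  fs Hz holds exactly ``10 * fs`` samples.
* Directed connectivity matrices are indexed ``[i, j]`` = influence of node
  ``j`` (source) on node ``i`` (sink), matching the row-normalised directed
  transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "TrialSet",
    "TVMVARModel",
    "SpectralTransfer",
    "TimeVaryingConnectivity",
    "BinaryNetwork",
    "EfficiencySeries",
    "CohortRecord",
    "MONTAGE_10_20_21",
]

#: The 21-electrode 10–20 montage used for network construction.
MONTAGE_10_20_21 = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2", "Oz",
)


def _check_labels(labels: Sequence[str], n: int) -> tuple[str, ...]:
    labels = tuple(str(c) for c in labels)
    if len(labels) != n:
        raise ValueError(f"{len(labels)} channel labels for {n} channels")
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")
    return labels


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in μV.
    fs
        Sampling rate in Hz.
    channel_labels
        10–20 channel names, unique, one per row of ``data``.
    events
        ``(sample_index, class_label)`` pairs marking stimulus onsets.
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.channel_labels = _check_labels(self.channel_labels, self.data.shape[0])
        for samp, _label in self.events:
            if not 0 <= samp < self.data.shape[1]:
                raise ValueError(f"event sample {samp} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        if "data" in kw and "events" not in kw:
            kw["events"] = list(self.events)
        return replace(self, **kw)


@dataclass
class TrialSet:
    """Epoched trials: ``(n_trials, n_channels, n_samples)`` in μV.

    ``times`` is the shared per-sample time axis in seconds relative to
    stimulus onset.  ``rejected_mask`` tracks, per *original* trial, whether
    it was dropped by artifact rejection (True = rejected); ``data`` only
    holds retained trials.
    """

    data: np.ndarray
    times: np.ndarray
    labels: list[str]
    fs: float
    channel_labels: Sequence[str]
    rejected_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("times length must match the sample axis")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one class label per trial required")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.channel_labels = _check_labels(self.channel_labels, self.data.shape[1])
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.data.shape[0], dtype=bool)
        else:
            self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kw) -> "TrialSet":
        return replace(self, **kw)


@dataclass
class TVMVARModel:
    """Time-varying MVAR model tracked by an adaptive Kalman filter.

    ``coefficients`` has shape ``(n_times, order, n, n)``: ``A(k, t)[i, j]``
    is the weight of channel ``j`` at lag ``k+1`` in the prediction of
    channel ``i`` at time ``t``.  ``innovation_cov`` is the final recursive
    estimate of the innovation (one-step prediction error) covariance.
    """

    order: int
    coefficients: np.ndarray
    innovation_cov: np.ndarray
    channel_labels: Sequence[str]
    fs: float
    update_coefficient: float
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        T, p, n, n2 = self.coefficients.shape
        if p != self.order or n != n2:
            raise ValueError("coefficient tensor must be (times, order, n, n)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")
        self.channel_labels = _check_labels(self.channel_labels, n)

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[2]

    @property
    def n_times(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class SpectralTransfer:
    """Complex spectral transfer matrix H(f, t), shape ``(T, F, n, n)``."""

    H: np.ndarray
    freqs: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=complex)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.H.ndim != 4 or self.H.shape[2] != self.H.shape[3]:
            raise ValueError("H must be (n_times, n_freqs, n, n)")
        if self.H.shape[1] != self.freqs.size:
            raise ValueError("frequency axis mismatch")
        if not np.all(np.isfinite(self.H)):
            raise ValueError("non-finite transfer matrix entries")
        self.channel_labels = _check_labels(self.channel_labels, self.H.shape[2])


@dataclass
class TimeVaryingConnectivity:
    """Band-averaged directed coupling Θ²(t), shape ``(n_times, n, n)``.

    Every row sums to 1 at every time point (diagonal included), inherited
    from the row normalisation of the squared transfer magnitudes.
    """

    theta: np.ndarray
    band: tuple[float, float]
    times: np.ndarray
    channel_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.theta.ndim != 3 or self.theta.shape[1] != self.theta.shape[2]:
            raise ValueError("theta must be (n_times, n, n)")
        if self.times.shape != (self.theta.shape[0],):
            raise ValueError("time axis mismatch")
        if np.any(self.theta < -1e-9) or np.any(self.theta > 1 + 1e-9):
            raise ValueError("theta entries must lie in [0, 1]")
        self.channel_labels = _check_labels(self.channel_labels, self.theta.shape[1])

    @property
    def n_channels(self) -> int:
        return self.theta.shape[1]


@dataclass
class BinaryNetwork:
    """Directed binary network at a fixed connectivity cost."""

    adjacency: np.ndarray
    channel_labels: Sequence[str]
    time: float
    cost: float

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("diagonal must be zero")
        self.adjacency = self.adjacency.astype(np.int8)
        self.channel_labels = _check_labels(self.channel_labels, n)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


@dataclass
class EfficiencySeries:
    """Global efficiency over time for one subject/condition."""

    times: np.ndarray
    ge: np.ndarray
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ge = np.asarray(self.ge, dtype=float)
        if self.times.shape != self.ge.shape:
            raise ValueError("times and ge must align")
        if np.any(self.ge < -1e-12) or np.any(self.ge > 1 + 1e-12):
            raise ValueError("global efficiency must lie in [0, 1]")

    def mean_in_window(self, window: tuple[float, float]) -> float:
        lo, hi = window
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError(f"no efficiency samples in window {window}")
        return float(self.ge[mask].mean())


@dataclass
class CohortRecord:
    """One subject: group membership, clinical score, efficiency series."""

    subject: str
    group: str  # LS | RS | HC
    fma: float | None = None
    severity: str | None = None
    ge_series: list[EfficiencySeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("LS", "RS", "HC"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.fma is not None and not 0 <= self.fma <= 60:
            raise ValueError("FMA score must lie in [0, 60]")

    @property
    def is_patient(self) -> bool:
        return self.group in ("LS", "RS")

    def mean_ge(self, window: tuple[float, float]) -> float:
        """Subject-level GE: mean over the window and all conditions."""
        if not self.ge_series:
            raise ValueError(f"subject {self.subject} has no efficiency series")
        return float(np.mean([s.mean_in_window(window) for s in self.ge_series]))
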