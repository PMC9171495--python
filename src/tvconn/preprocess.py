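"""Preprocessing: band-pass filtering, re-referencing, epoching, artifact
rejection, downsampling, and montage selection.

The canonical order, matching the analysis pipeline, is::

    bandpass -> rereference -> epoch -> reject_artifacts -> downsample -> select_channels

Artifact rejection is applied at the full sampling rate (before
downsampling) and on the channels present at that point; an absolute
amplitude exceeding the threshold on any channel rejects the whole trial.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .containers import MONTAGE_10_20_21, Recording, TrialSet

__all__ = [
    "bandpass",
    "rereference",
    "epoch",
    "reject_artifacts",
    "downsample",
    "select_channels",
    "preprocess_recording",
    "preprocess_trials",
]

logger = logging.getLogger(__name__)


def bandpass(rec: Recording, low: float = 8.0, high: float = 30.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward–backward, 4th order per pass).

    Passband gain ~1, stopband strongly attenuated; zero phase shift so
    event timing is preserved.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist {nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(data=out)


def rereference(rec: Recording, scheme: str = "average",
                weights: np.ndarray | None = None) -> Recording:
    """Re-reference: subtract a reference signal from every channel.

    ``scheme="average"`` subtracts the instantaneous mean across channels
    (common average reference), so the per-sample channel mean of the
    output is exactly zero.  ``scheme="custom"`` subtracts
    ``weights @ data`` (weights summing over channels), e.g. a one-hot
    vector re-references to a single electrode; this is the hook through
    which a lead-field-based reference operator can be plugged in.
    """
    if rec.n_channels < 2:
        raise ValueError("re-referencing requires at least 2 channels")
    if scheme == "average":
        ref = rec.data.mean(axis=0, keepdims=True)
    elif scheme == "custom":
        if weights is None:
            raise ValueError("custom scheme requires weights")
        w = np.asarray(weights, dtype=float)
        if w.shape != (rec.n_channels,):
            raise ValueError("weights must have one entry per channel")
        ref = w[None, :] @ rec.data
    else:
        raise ValueError(f"unknown re-reference scheme {scheme!r}")
    return rec.copy_with(data=rec.data - ref)


def epoch(rec: Recording, window: tuple[float, float] = (-4.0, 6.0)) -> TrialSet:
    """Cut trials around each event with a closed-left/open-right window.

    The window [t0, t1) relative to stimulus onset yields exactly
    ``(t1 - t0) * fs`` samples per trial.  Events too close to a recording
    edge are skipped (and logged), not errors.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    pre = int(round(-t0 * rec.fs))
    post = int(round(t1 * rec.fs))
    n_samp = pre + post
    trials, labels = [], []
    for samp, label in rec.events:
        if samp - pre < 0 or samp + post > rec.n_samples:
            logger.warning("event at sample %d too close to recording edge; skipped", samp)
            continue
        trials.append(rec.data[:, samp - pre:samp + post])
        labels.append(label)
    if not trials:
        raise ValueError("no events with enough surrounding data to epoch")
    times = (np.arange(n_samp) - pre) / rec.fs
    return TrialSet(data=np.stack(trials), times=times, labels=labels,
                    fs=rec.fs, channel_labels=rec.channel_labels)


def reject_artifacts(ts: TrialSet, threshold: float = 70.0) -> TrialSet:
    """Drop trials whose absolute amplitude exceeds ``threshold`` μV anywhere.

    The ±threshold rule is an amplitude gate: a single sample with
    |x| > threshold on any channel rejects the trial.  ``rejected_mask``
    records the decision per original trial.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = np.abs(ts.data).max(axis=(1, 2)) > threshold
    if bad.all():
        raise ValueError(
            f"all {ts.n_trials} trials exceed ±{threshold} μV: no data survives")
    keep = ~bad
    return ts.copy_with(
        data=ts.data[keep],
        labels=[l for l, k in zip(ts.labels, keep) if k],
        rejected_mask=ts.rejected_mask | _expand_mask(ts.rejected_mask, bad),
    )


def _expand_mask(existing: np.ndarray, new_bad: np.ndarray) -> np.ndarray:
    """Map a mask over currently retained trials back onto original indices."""
    out = np.zeros_like(existing, dtype=bool)
    retained_idx = np.flatnonzero(~existing)
    out[retained_idx[new_bad]] = True
    return out


def downsample(ts: TrialSet, target_fs: float = 100.0) -> TrialSet:
    """Anti-aliased resampling to ``target_fs``; time axis is preserved.

    Integer decimation uses a polyphase FIR; non-integer ratios go through
    the rational ``resample_poly`` approximation.
    """
    if target_fs > ts.fs:
        raise ValueError(f"target_fs {target_fs} exceeds current fs {ts.fs}")
    if np.isclose(target_fs, ts.fs):
        return ts
    from fractions import Fraction
    frac = Fraction(target_fs / ts.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(ts.data, up, down, axis=-1)
    n_new = out.shape[-1]
    times = ts.times[0] + np.arange(n_new) / target_fs
    return ts.copy_with(data=out, times=times, fs=target_fs)


def select_channels(ts: TrialSet, montage=MONTAGE_10_20_21) -> TrialSet:
    """Reorder/subset channels to the requested montage, in its order."""
    montage = tuple(montage)
    missing = [m for m in montage if m not in ts.channel_labels]
    if missing:
        raise KeyError(f"requested channels absent from data: {missing}")
    idx = [list(ts.channel_labels).index(m) for m in montage]
    return ts.copy_with(data=ts.data[:, idx, :], channel_labels=montage)


def preprocess_recording(rec: Recording, *, band: tuple[float, float] = (8.0, 30.0),
                         window: tuple[float, float] = (-4.0, 6.0),
                         threshold: float = 70.0, target_fs: float = 100.0,
                         montage=None, reference: str = "average") -> TrialSet:
    """Run the full canonical preprocessing chain on one recording."""
    rec = bandpass(rec, *band)
    if reference != "none":
        rec = rereference(rec, reference)
    ts = epoch(rec, window)
    ts = reject_artifacts(ts, threshold)
    ts = downsample(ts, target_fs)
    if montage is not None:
        ts = select_channels(ts, montage)
    return ts


def preprocess_trials(ts: TrialSet, *, band: tuple[float, float] = (8.0, 30.0),
                      threshold: float = 70.0, target_fs: float = 100.0,
                      montage=None, reference: str = "average") -> TrialSet:
    """Preprocess an already-epoched trial set (synthetic-data path).

    Same stages and order as :func:`preprocess_recording`, minus epoching.
    """
    low, high = band
    nyq = ts.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist {nyq})")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=ts.fs, output="sos")
    data = signal.sosfiltfilt(sos, ts.data, axis=-1)
    if ts.n_channels >= 2 and reference == "average":
        data = data - data.mean(axis=1, keepdims=True)
    out = ts.copy_with(data=data)
    out = reject_artifacts(out, threshold)
    out = downsample(out, target_fs)
    if montage is not None:
        out = select_channels(out, montage)
    return out
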