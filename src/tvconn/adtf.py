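"""Adaptive directed transfer function: spectral transfer matrices from
time-varying MVAR coefficients, row normalisation, and band averaging.

For lag coefficients A_k(t) the frequency-domain coefficient matrix is

    Ā(f, t) = I − Σ_{k=1}^{p} A_k(t) e^{−j 2π f k Δt},    Δt = 1/fs,

(the zero-lag term is −I folded into the identity, the standard DTF sign
convention, so an empty model gives H = I).  The transfer matrix is
H(f, t) = Ā(f, t)⁻¹, and the normalised squared ADTF

    r²_ij(f, t) = |H_ij(f, t)|² / Σ_m |H_im(f, t)|²

quantifies directed flow from node j to node i; each row sums to one.
Band averaging over the 8–30 Hz motor-imagery band yields Θ²_ij(t), the
arithmetic mean of r²_ij over the included frequency bins (so Θ² stays in
[0, 1] and rows remain normalised).
"""

from __future__ import annotations

import numpy as np

from .containers import SpectralTransfer, TimeVaryingConnectivity, TVMVARModel

__all__ = [
    "default_band_grid",
    "transfer_matrix",
    "adtf_normalize",
    "band_average",
    "connectivity_from_model",
]

DEFAULT_BAND = (8.0, 30.0)


def default_band_grid(band: tuple[float, float] = DEFAULT_BAND,
                      step: float = 1.0) -> np.ndarray:
    """Frequency grid covering ``band`` inclusive at ``step`` Hz spacing."""
    f1, f2 = band
    n = int(round((f2 - f1) / step))
    return f1 + step * np.arange(n + 1)


def transfer_matrix(model: TVMVARModel, freqs: np.ndarray) -> SpectralTransfer:
    """Spectral transfer matrix H(f, t) = Ā(f, t)⁻¹ on a frequency grid."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    nyq = model.fs / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError(f"frequencies must lie strictly inside (0, {nyq}) Hz")
    coeffs = model.coefficients  # (T, p, n, n)
    T, p, n, _ = coeffs.shape
    k = np.arange(1, p + 1)
    # phases[f, k] = exp(-i 2π f k / fs)
    phases = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / model.fs)
    Abar = np.eye(n) - np.einsum("fk,tkij->tfij", phases, coeffs)
    try:
        H = np.linalg.inv(Abar)
    except np.linalg.LinAlgError:
        dets = np.abs(np.linalg.det(Abar))
        t_idx, f_idx = np.unravel_index(int(np.argmin(dets)), dets.shape)
        raise np.linalg.LinAlgError(
            f"Ā singular near f={freqs[f_idx]:.3g} Hz, t index {t_idx}") from None
    if not np.all(np.isfinite(H)):
        bad = ~np.isfinite(H).all(axis=(2, 3))
        t_idx, f_idx = np.argwhere(bad)[0]
        raise np.linalg.LinAlgError(
            f"non-finite transfer matrix at f={freqs[f_idx]:.3g} Hz, t index {t_idx}")
    return SpectralTransfer(H=H, freqs=freqs, fs=model.fs,
                            channel_labels=model.channel_labels,
                            times=model.times)


def adtf_normalize(H: SpectralTransfer | np.ndarray) -> np.ndarray:
    """Row-normalised squared transfer magnitudes r²_ij(f, t).

    Returns a ``(T, F, n, n)`` tensor whose every row (last axis) sums to
    one; entries lie in [0, 1].  Raises if any row of H is entirely zero.
    """
    Ht = H.H if isinstance(H, SpectralTransfer) else np.asarray(H)
    mag2 = np.abs(Ht) ** 2
    denom = mag2.sum(axis=-1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("all-zero row in H: ADTF normalisation undefined")
    return mag2 / denom


def band_average(r2: np.ndarray, freqs: np.ndarray,
                 band: tuple[float, float] = DEFAULT_BAND,
                 times: np.ndarray | None = None,
                 channel_labels=None) -> TimeVaryingConnectivity:
    """Average r²(f, t) over the frequency bins inside ``band`` → Θ²(t).

    Uses the arithmetic mean over included bins (divide by bin count), so
    Θ² inherits the row normalisation and stays in [0, 1].
    """
    r2 = np.asarray(r2, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    f1, f2 = band
    mask = (freqs >= f1) & (freqs <= f2)
    if not mask.any():
        raise ValueError(f"band {band} contains no grid frequencies")
    theta = r2[:, mask].mean(axis=1)
    T, n = theta.shape[0], theta.shape[1]
    if times is None:
        times = np.arange(T, dtype=float)
    if channel_labels is None:
        channel_labels = tuple(f"ch{i + 1}" for i in range(n))
    return TimeVaryingConnectivity(theta=theta, band=(f1, f2), times=times,
                                   channel_labels=channel_labels)


def onset_crossing_time(theta: np.ndarray, times: np.ndarray, *,
                        baseline_end: float = 0.0, settle: float = 1.0,
                        smooth: float = 0.2, hold: float = 0.25) -> float:
    """Latency at which a coupling time course first reaches half its plateau.

    The plateau is the mean of the second half of the post-``baseline_end``
    segment.  To be robust against estimation noise, the trace is smoothed
    with a ``smooth``-second moving average and the crossing must be
    sustained for ``hold`` seconds; the first ``settle`` seconds are
    excluded because the adaptive filter starts from a zero state and its
    early estimates are transients, not signal.  Returns ``inf`` when no
    sustained crossing exists.
    """
    theta = np.asarray(theta, dtype=float)
    times = np.asarray(times, dtype=float)
    if theta.shape != times.shape:
        raise ValueError("theta and times must align")
    dt = float(np.median(np.diff(times)))
    sel = times >= times[0] + settle
    th, t = theta[sel], times[sel]
    post = th[t >= baseline_end]
    if post.size < 4:
        raise ValueError("too few post-onset samples to define a plateau")
    half = 0.5 * post[post.size // 2:].mean()
    w = max(1, int(round(smooth / dt)))
    kernel = np.ones(w) / w
    sm = np.convolve(th, kernel, mode="same")
    need = max(1, int(round(hold / dt)))
    run = 0
    for i, above in enumerate(sm >= half):
        run = run + 1 if above else 0
        if run == need:
            return float(t[i - need + 1])
    return float("inf")


def connectivity_from_model(model: TVMVARModel,
                            band: tuple[float, float] = DEFAULT_BAND,
                            grid_step: float = 1.0,
                            times: np.ndarray | None = None,
                            time_stride: int = 1) -> TimeVaryingConnectivity:
    """Full ADTF chain: transfer matrix → normalisation → band average.

    ``time_stride > 1`` evaluates the spectral transform on every k-th
    sample only — the coefficients are already computed at every sample,
    so this is pure decimation of the connectivity time grid.
    """
    if time_stride < 1:
        raise ValueError("time_stride must be >= 1")
    if times is None:
        times = np.arange(model.n_times) / model.fs
    times = np.asarray(times, dtype=float)
    if time_stride > 1:
        sub = TVMVARModel(order=model.order,
                          coefficients=model.coefficients[::time_stride],
                          innovation_cov=model.innovation_cov,
                          channel_labels=model.channel_labels, fs=model.fs,
                          update_coefficient=model.update_coefficient)
        model, times = sub, times[::time_stride]
    freqs = default_band_grid(band, grid_step)
    H = transfer_matrix(model, freqs)
    r2 = adtf_normalize(H)
    return band_average(r2, freqs, band, times=times,
                        channel_labels=model.channel_labels)
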