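"""Time-varying MVAR estimation with an adaptive Kalman filter, and AIC
model-order selection.

Model: ``x(t) = Σ_{k=1}^{p} A_k(t) x(t−k) + e(t)`` with innovations e(t).
The coefficient matrices are tracked by the classic adaptive-filter
formulation: the state is the coefficient matrix itself under a
random-walk transition, with a single scalar *update coefficient* (UC)
setting the state-noise level and hence the adaptation speed / variance
trade-off.  All channels share one regressor vector
``c(t) = [x(t−1); …; x(t−p)]`` and one state covariance P, so the filter
reduces to n parallel scalar-observation updates with a shared gain:

    e(t)   = x(t) − Θ(t−1) c(t)
    g(t)   = P c / (cᵀ P c + v)
    Θ(t)   = Θ(t−1) + e(t) g(t)ᵀ
    P(t)   = P − g (cᵀP) + UC·I
    V(t)   = (1−UC) V(t−1) + UC e eᵀ        (innovation covariance)

with v the scalar measurement-noise proxy (mean innovation variance).
Filtering is forward-only: the coefficient estimate stored at time t
depends only on samples up to and including t.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import TrialSet, TVMVARModel

__all__ = [
    "aic",
    "aic_from_covariance",
    "select_order",
    "fit_kalman",
    "fit_trials",
    "OrderSelection",
]

DEFAULT_UPDATE_COEFFICIENT = 1e-3


# ---------------------------------------------------------------------------
# AIC order selection

def aic_from_covariance(innovation_cov: np.ndarray, n_channels: int, p: int,
                        n_samples: int) -> float:
    """AIC(p) = ln det(ε) + 2 β² p / α.

    β is the node (channel) count, α the number of samples in the full
    trial window, ε the innovation covariance of the fitted order-p model.

    Re-referenced (e.g. common-average) data has an exactly singular
    covariance: the null direction's eigenvalue is floored at
    ``1e-10 × λ_max``, which shifts the log-determinant by a near-constant
    across candidate orders and leaves the AIC argmin intact.  A
    covariance with no positive eigenvalue yields +inf with a warning.
    """
    w = np.linalg.eigvalsh(np.asarray(innovation_cov, dtype=float))
    w_max = w.max(initial=0.0)
    if w_max <= 0 or not np.isfinite(w_max):
        warnings.warn("degenerate innovation covariance; AIC undefined, returning inf")
        return float("inf")
    logdet = float(np.sum(np.log(np.maximum(w, 1e-10 * w_max))))
    return float(logdet + 2.0 * n_channels ** 2 * p / n_samples)


def _ols_var_fit(trial: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares VAR(p) fit of one trial ``(n, T)``.

    Returns ``(A, cov)`` with ``A`` of shape ``(p, n, n)`` and ``cov`` the
    maximum-likelihood innovation covariance (residual covariance with
    denominator = number of regression rows).
    """
    x = np.asarray(trial, dtype=float)
    n, T = x.shape
    if T <= p * n:
        raise ValueError(f"trial too short ({T} samples) for order {p} with {n} channels")
    # design: row t predicts x(:, t) from x(:, t-1..t-p)
    Y = x[:, p:].T  # (T-p, n)
    Z = np.empty((T - p, n * p))
    for k in range(p):
        Z[:, k * n:(k + 1) * n] = x[:, p - 1 - k:T - 1 - k].T
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ B
    cov = resid.T @ resid / resid.shape[0]
    A = B.T.reshape(n, p, n).transpose(1, 0, 2)
    return A, cov


def aic(trial: np.ndarray, p: int) -> float:
    """AIC of an order-p VAR fit to one trial ``(channels, samples)``.

    ε̂ comes from an ordinary least-squares fit (deterministic, fast); α is
    the full trial sample count.
    """
    x = np.asarray(trial, dtype=float)
    n, T = x.shape
    _, cov = _ols_var_fit(x, p)
    return aic_from_covariance(cov, n, p, T)


class OrderSelection:
    """Result of an AIC scan: candidate orders, scores, selected order."""

    def __init__(self, orders: np.ndarray, aic_values: np.ndarray):
        self.orders = np.asarray(orders, dtype=int)
        self.aic_values = np.asarray(aic_values, dtype=float)
        finite = np.isfinite(self.aic_values)
        if not finite.any():
            raise ValueError("AIC undefined for every candidate order")
        # argmin with ties broken toward the smaller order (stable argmin)
        self.selected = int(self.orders[int(np.argmin(self.aic_values))])

    def __repr__(self) -> str:
        return f"OrderSelection(selected={self.selected}, range={self.orders.min()}–{self.orders.max()})"


def select_order(trials: TrialSet | np.ndarray, p_range: tuple[int, int] = (2, 20)
                 ) -> OrderSelection:
    """Select the MVAR order minimising the trial-averaged AIC over 2–20.

    Accepts a TrialSet or a raw ``(trials, channels, samples)`` array.
    """
    data = trials.data if isinstance(trials, TrialSet) else np.asarray(trials, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] == 0:
        raise ValueError("empty trial set")
    lo, hi = p_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid order range")
    n, T = data.shape[1], data.shape[2]
    if T <= hi * n:
        raise ValueError(
            f"trials of {T} samples cannot identify order {hi} with {n} channels")
    orders = np.arange(lo, hi + 1)
    scores = np.empty(orders.size)
    for i, p in enumerate(orders):
        scores[i] = float(np.mean([aic(tr, int(p)) for tr in data]))
    return OrderSelection(orders, scores)


# ---------------------------------------------------------------------------
# Kalman filtering

def _kalman_batch(data: np.ndarray, p: int, uc: float,
                  psd_check_interval: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Run the adaptive Kalman filter over a batch of trials.

    Parameters
    ----------
    data
        ``(B, n, T)`` batch of trials (same length).
    p
        Model order.
    uc
        Update coefficient in (0, 1).
    psd_check_interval
        If > 0, verify every K updates that the innovation-covariance
        estimate stays symmetric positive semi-definite.

    Returns
    -------
    A : ``(B, T, p, n, n)`` coefficient estimates (zeros for t < p).
    V : ``(B, n, n)`` final innovation covariance estimates.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 2:
        x = x[None]
    B, n, T = x.shape
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input data")
    if p < 1:
        raise ValueError("order must be >= 1")
    if not 0 < uc < 1:
        raise ValueError("update coefficient must lie in (0, 1)")
    d = n * p
    A = np.zeros((B, T, p, n, n))
    theta = np.zeros((B, n, d))
    P = np.tile(np.eye(d), (B, 1, 1))
    # innovation covariance initialised from an early-sample covariance
    n0 = min(T, max(10 * p, 50))
    seg = x[:, :, :n0]
    V = np.einsum("bnt,bmt->bnm", seg, seg) / n0
    V += 1e-12 * np.eye(n)
    eyed = uc * np.eye(d)
    for t in range(p, T):
        # lag-major regressor: [x(t-1); x(t-2); ...; x(t-p)]
        c = x[:, :, t - p:t][:, :, ::-1].transpose(0, 2, 1).reshape(B, d)
        pred = np.einsum("bnd,bd->bn", theta, c)
        e = x[:, :, t] - pred
        Pc = np.einsum("bde,be->bd", P, c)
        v = np.einsum("bnn->b", V) / n  # scalar measurement-noise proxy
        s = np.einsum("bd,bd->b", c, Pc) + v + 1e-24
        g = Pc / s[:, None]
        theta = theta + e[:, :, None] * g[:, None, :]
        P = P - g[:, :, None] * Pc[:, None, :] + eyed
        P = 0.5 * (P + P.transpose(0, 2, 1))
        V = (1 - uc) * V + uc * e[:, :, None] * e[:, None, :]
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"Kalman state diverged at sample {t}")
        if psd_check_interval and (t - p) % psd_check_interval == 0:
            w = np.linalg.eigvalsh(V)
            if np.any(w < -1e-8):
                raise FloatingPointError(
                    f"innovation covariance lost positive semi-definiteness at sample {t}")
        A[:, t] = theta.reshape(B, n, p, n).transpose(0, 2, 1, 3)
    return A, V


def fit_kalman(trial: np.ndarray, p: int,
               update_coefficient: float = DEFAULT_UPDATE_COEFFICIENT,
               fs: float = 100.0, channel_labels=None,
               psd_check_interval: int = 0) -> TVMVARModel:
    """Fit the time-varying MVAR model to one trial ``(channels, samples)``.

    Coefficients for t < p remain at their zero initialisation.  For
    stationary input, post-burn-in time-averaged coefficients approximate
    the static least-squares VAR solution; adaptation speed grows with the
    update coefficient.
    """
    x = np.asarray(trial, dtype=float)
    if x.ndim != 2:
        raise ValueError("trial must be (channels, samples)")
    A, V = _kalman_batch(x[None], p, update_coefficient, psd_check_interval)
    n = x.shape[0]
    if channel_labels is None:
        channel_labels = tuple(f"ch{i + 1}" for i in range(n))
    return TVMVARModel(order=p, coefficients=A[0], innovation_cov=V[0],
                       channel_labels=channel_labels, fs=fs,
                       update_coefficient=update_coefficient)


def fit_trials(ts: TrialSet, p: int | None = None,
               update_coefficient: float = DEFAULT_UPDATE_COEFFICIENT,
               p_range: tuple[int, int] = (2, 20)) -> list[TVMVARModel]:
    """Fit every trial of a TrialSet with one shared order.

    If ``p`` is None the order is selected once on the trial-averaged AIC
    (one order per subject) and reused for every trial.  Trials are
    filtered in a single vectorised batch.
    """
    if ts.n_trials == 0:
        raise ValueError("empty trial set")
    if p is None:
        p = select_order(ts, p_range).selected
    # chunk the batch so the coefficient tensor stays within ~1.6 GB
    T, n = ts.n_samples, ts.n_channels
    per_trial = T * p * n * n * 8
    chunk = max(1, int(2e8 // max(per_trial, 1)))
    models: list[TVMVARModel] = []
    for start in range(0, ts.n_trials, chunk):
        A, V = _kalman_batch(ts.data[start:start + chunk], p, update_coefficient)
        for b in range(A.shape[0]):
            models.append(TVMVARModel(
                order=p, coefficients=A[b], innovation_cov=V[b],
                channel_labels=ts.channel_labels, fs=ts.fs,
                update_coefficient=update_coefficient))
    return models
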