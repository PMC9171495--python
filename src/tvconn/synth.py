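"""Synthetic ground-truth generators: time-varying MVAR signals, kinesthetic
motor-imagery (KMI) trial paradigms, and cohorts with a planted link between
clinical scores and network coupling.

The generators emulate the study conditions of a KMI experiment: 21-channel
10–20 recordings at 1000 Hz, trials of 4 s rest followed by 6 s task, 30
trials per class, and three groups (left-hemiplegic stroke LS,
right-hemiplegic stroke RS, healthy controls HC) whose task-state directed
coupling differs.  Channel dynamics are damped stochastic oscillators
(AR(2) resonances inside the 8–30 Hz analysis band) so that the directed
coupling the pipeline must recover carries power in the band it analyses.
A fast 3-channel profile exists for tests and quick runs.

The generative model is the same time-varying MVAR process the estimator
assumes: ``x(t) = Σ_k A_k(t) x(t−k) + e(t)`` with Gaussian innovations.
This is deliberately not a biophysical head model — no volume conduction
or lead fields — so planted directed couplings are unambiguous ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import MONTAGE_10_20_21, CohortRecord, Recording, TrialSet

__all__ = [
    "ScheduleSegment",
    "CoefficientSchedule",
    "ParadigmSpec",
    "CohortSpec",
    "SyntheticSubject",
    "companion_spectral_radius",
    "oscillator_coefficients",
    "ring_edges",
    "kmi_schedules",
    "simulate_tvmvar",
    "generate_kmi_trialset",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# coefficient schedules

def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a lag tensor ``(p, n, n)``.

    The MVAR process is asymptotically stable iff this is < 1.
    """
    A = np.asarray(A, dtype=float)
    p, n, _ = A.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = A.transpose(1, 0, 2).reshape(n, n * p)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass(frozen=True)
class ScheduleSegment:
    """One piece of a coefficient schedule: constant lags on [start, end)."""

    start: float
    end: float
    coefficients: np.ndarray  # (order, n, n)


@dataclass
class CoefficientSchedule:
    """Piecewise lag-coefficient schedule A(k, t) over a trial window.

    Segments must tile the window without gaps or overlap, and every
    segment must be stable (companion spectral radius < 1).  ``transition``
    is either ``"step"`` (coefficients switch at segment boundaries) or
    ``("ramp", duration_s)`` (linear interpolation from the previous
    segment's tensor over ``duration_s`` after each boundary).
    """

    segments: list[ScheduleSegment]
    transition: str | tuple[str, float] = "step"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        segs = sorted(self.segments, key=lambda s: s.start)
        shape = np.asarray(segs[0].coefficients).shape
        if len(shape) != 3 or shape[1] != shape[2] or shape[0] < 1:
            raise ValueError("segment coefficients must be (order>=1, n, n)")
        for a, b in zip(segs, segs[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError(
                    f"segments must tile the window: gap/overlap between "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
        for i, seg in enumerate(segs):
            if np.asarray(seg.coefficients).shape != shape:
                raise ValueError("all segments must share (order, n, n)")
            rho = companion_spectral_radius(seg.coefficients)
            if rho >= 1.0:
                raise ValueError(
                    f"unstable segment {i} [{seg.start}, {seg.end}): "
                    f"companion spectral radius {rho:.4f} >= 1"
                )
        self.segments = segs
        if isinstance(self.transition, tuple):
            kind, dur = self.transition
            if kind != "ramp" or dur <= 0:
                raise ValueError("tuple transition must be ('ramp', duration>0)")
        elif self.transition != "step":
            raise ValueError("transition must be 'step' or ('ramp', duration)")

    @property
    def order(self) -> int:
        return self.segments[0].coefficients.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments[0].coefficients.shape[1]

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    def coefficients_at(self, t: float) -> np.ndarray:
        """Lag tensor active at time ``t`` (closed-left segments)."""
        idx = 0
        for i, seg in enumerate(self.segments):
            if seg.start <= t < seg.end or (i == len(self.segments) - 1 and t >= seg.end):
                idx = i
                break
        seg = self.segments[idx]
        if idx > 0 and isinstance(self.transition, tuple):
            dur = self.transition[1]
            if t < seg.start + dur:
                w = (t - seg.start) / dur
                prev = self.segments[idx - 1].coefficients
                return (1 - w) * prev + w * seg.coefficients
        return seg.coefficients

    def shifted(self, offset: float) -> "CoefficientSchedule":
        return CoefficientSchedule(
            [ScheduleSegment(s.start + offset, s.end + offset, s.coefficients)
             for s in self.segments],
            transition=self.transition,
        )


def concat_schedules(a: CoefficientSchedule, b: CoefficientSchedule,
                     transition: str | tuple[str, float] = "step") -> CoefficientSchedule:
    if not np.isclose(a.end, b.start):
        raise ValueError("schedules do not abut")
    return CoefficientSchedule(list(a.segments) + list(b.segments), transition=transition)


# ---------------------------------------------------------------------------
# building blocks for the default study conditions

def oscillator_coefficients(n_channels: int, fs: float, *, f0: float = 15.0,
                            damping: float = 50.0, order: int = 2) -> np.ndarray:
    """Diagonal AR(2) lag tensor: independent damped oscillators per channel.

    Each channel has a spectral resonance at ``f0`` Hz with pole radius
    ``exp(-damping / fs)``, i.e. an amplitude decay rate of ``damping`` per
    second independent of the sampling rate.  ``f0`` defaults to 15 Hz, the
    middle of the 8–30 Hz motor-imagery analysis band.  Extra lags beyond 2
    (if ``order > 2``) are zero.
    """
    if order < 2:
        raise ValueError("oscillator needs order >= 2")
    rho = float(np.exp(-damping / fs))
    a1 = 2.0 * rho * np.cos(2.0 * np.pi * f0 / fs)
    a2 = -rho * rho
    A = np.zeros((order, n_channels, n_channels))
    A[0] = a1 * np.eye(n_channels)
    A[1] = a2 * np.eye(n_channels)
    return A


def ring_edges(n_channels: int) -> list[tuple[int, int]]:
    """Directed ring: channel i drives channel (i+1) mod n; edges as (sink, source)."""
    return [((i + 1) % n_channels, i) for i in range(n_channels)]


def graded_ring_weights(n_channels: int, floor: float = 0.7) -> np.ndarray:
    """Relative edge strengths descending linearly from 1 to ``floor``.

    A uniform-strength ring saturates the directed-transfer readout: every
    edge is either detected or not, all together.  Grading the strengths
    means the number of planted edges that rise above the estimation noise
    floor — and with it the binarised topology and its global efficiency —
    varies smoothly with the overall coupling gain.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    return 1.0 - (1.0 - floor) * np.arange(n_channels) / (n_channels - 1)


def kmi_schedules(n_channels: int, fs: float, coupling_gain: float, *,
                  rest_duration: float = 4.0, task_duration: float = 6.0,
                  coupled_edges: list[tuple[int, int]] | None = None,
                  edge_weights: np.ndarray | None = None,
                  f0: float = 15.0, damping: float = 50.0,
                  order: int = 2) -> tuple[CoefficientSchedule, CoefficientSchedule]:
    """Default rest/task schedule pair for a KMI-style trial.

    Rest: independent oscillators on [−rest_duration, 0).  Task: the same
    oscillators plus lag-1 directed coupling of magnitude
    ``coupling_gain × edge_weights`` on ``coupled_edges`` (default: a
    directed ring over all channels with graded weights, see
    :func:`graded_ring_weights`) on [0, task_duration].  ``fs`` here is
    the *model* rate at which the lag dynamics are defined —
    conventionally 100 Hz, so lag 1 is a 10 ms interaction delay.
    """
    base = oscillator_coefficients(n_channels, fs, f0=f0, damping=damping, order=order)
    task = base.copy()
    if coupled_edges is None:
        coupled_edges = ring_edges(n_channels)
        if edge_weights is None:
            edge_weights = graded_ring_weights(n_channels)
    if edge_weights is None:
        edge_weights = np.ones(len(coupled_edges))
    if len(edge_weights) != len(coupled_edges):
        raise ValueError("one weight per coupled edge required")
    for w, (sink, src) in zip(edge_weights, coupled_edges):
        if sink == src:
            raise ValueError("coupled edges must be off-diagonal")
        task[0, sink, src] += coupling_gain * w
    rest = CoefficientSchedule([ScheduleSegment(-rest_duration, 0.0, base)])
    task_sched = CoefficientSchedule([ScheduleSegment(0.0, task_duration, task)])
    return rest, task_sched


# ---------------------------------------------------------------------------
# specs

@dataclass
class ParadigmSpec:
    """KMI trial paradigm: rest then task, two classes.

    ``fs`` is the recording rate of the emitted trials; ``model_fs`` is
    the rate at which the generative MVAR dynamics are defined (100 Hz by
    default, so a lag-1 coupling is a 10 ms cortico-cortical delay).  When
    ``fs > model_fs`` the simulated series is band-limit upsampled by the
    integer factor ``fs / model_fs`` — coupling stays well inside the
    analysis band and the discrete-lag process stays stable, which a
    near-unit-pole MVAR defined directly at 1000 Hz would not.
    """

    rest_duration: float = 4.0
    task_duration: float = 6.0
    fs: float = 1000.0
    n_trials_per_class: int = 30
    classes: tuple[str, ...] = ("left", "right")
    model_fs: float = 100.0

    def __post_init__(self) -> None:
        if self.rest_duration <= 0 or self.task_duration <= 0:
            raise ValueError("durations must be positive")
        if self.fs <= 2 * 30.0:
            raise ValueError("fs must exceed twice the 30 Hz band edge")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        ratio = self.fs / self.model_fs
        if self.fs < self.model_fs or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fs must be an integer multiple of model_fs")

    @property
    def upsample_factor(self) -> int:
        return int(round(self.fs / self.model_fs))

    @property
    def trial_duration(self) -> float:
        return self.rest_duration + self.task_duration

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration * self.fs))


@dataclass
class CohortSpec:
    """Synthetic cohort: group sizes, FMA scores, and the planted link
    between FMA and task-state coupling magnitude.

    A patient with (normalised) score ``u = fma / fma_range[1]`` receives
    task coupling gain ``base_gain + coupling_gain_slope * u``; healthy
    controls receive ``hc_gain``.  ``coupling_gain_slope = 0`` plants no
    FMA–network relationship (null cohort).

    The default gains span [0.12, 0.32]: the monotone region of the
    GE-vs-gain response of the graded-ring design (above ~0.35, strong
    indirect transfer-function flows start displacing the weaker direct
    edges from the fixed-cost edge budget and efficiency falls again).
    """

    n_per_group: tuple[int, int, int] = (7, 5, 9)  # LS, RS, HC
    fma_range: tuple[float, float] = (0.0, 60.0)
    coupling_gain_slope: float = 0.2
    base_gain: float = 0.12
    hc_gain: float = 0.32
    noise_cov: np.ndarray | None = None
    seed: int = 0
    n_channels: int = 21
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    noise_scale_uv: float = 5.0  # innovation SD in μV when noise_cov is None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")
        lo, hi = self.fma_range
        if not (0 <= lo <= hi <= 60):
            raise ValueError("fma_range must lie within [0, 60]")
        if hi == lo and self.coupling_gain_slope != 0:
            raise ValueError(
                "degenerate fma_range (zero width) with nonzero slope plants "
                "an unidentifiable link"
            )
        if self.noise_cov is not None:
            self.noise_cov = np.asarray(self.noise_cov, dtype=float)
            _check_noise_cov(self.noise_cov, self.n_channels)

    def resolved_noise_cov(self) -> np.ndarray:
        if self.noise_cov is not None:
            return self.noise_cov
        return (self.noise_scale_uv ** 2) * np.eye(self.n_channels)


@dataclass
class SyntheticSubject:
    """Record + trials + generative ground truth; unpacks as (record, trials)."""

    record: CohortRecord
    trials: TrialSet
    coupling_gain: float
    coupled_edges: list[tuple[int, int]]

    def __iter__(self):
        return iter((self.record, self.trials))


def _check_noise_cov(cov: np.ndarray, n: int) -> None:
    if cov.shape != (n, n):
        raise ValueError(f"noise_cov must be ({n}, {n})")
    if not np.allclose(cov, cov.T):
        raise ValueError("noise_cov must be symmetric")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("noise_cov must be positive definite") from err


# ---------------------------------------------------------------------------
# simulators

def _simulate_window(schedule: CoefficientSchedule, noise_cov: np.ndarray,
                     t_start: float, t_end: float, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Simulate the MVAR process on [t_start, t_end) with burn-in discarded.

    Burn-in of ``10 * order`` samples (run under the first segment's
    coefficients) precedes the window so it starts near stationarity.
    """
    p = schedule.order
    n = schedule.n_channels
    _check_noise_cov(noise_cov, n)
    burn = 10 * p
    n_out = int(round((t_end - t_start) * fs))
    total = burn + n_out
    L = np.linalg.cholesky(noise_cov)
    innovations = rng.standard_normal((total, n)) @ L.T
    x = np.zeros((total + p, n))
    dt = 1.0 / fs
    # closed-left segment lookup, cached per segment for the step transition
    A = schedule.coefficients_at(t_start)
    ramping = isinstance(schedule.transition, tuple)
    seg_iter_t = None
    for t in range(total):
        time_s = t_start + (t - burn) * dt
        if t >= burn:
            if ramping:
                A = schedule.coefficients_at(time_s)
            else:
                if seg_iter_t is None or time_s >= seg_iter_t:
                    A = schedule.coefficients_at(max(time_s, t_start))
                    nxt = [s.start for s in schedule.segments if s.start > time_s]
                    seg_iter_t = min(nxt) if nxt else np.inf
        hist = x[t:t + p][::-1]  # hist[k] = x(t - 1 - k) in output indexing
        x[t + p] = np.einsum("kij,kj->i", A, hist) + innovations[t]
        if not np.all(np.isfinite(x[t + p])):
            raise FloatingPointError(f"simulation diverged at sample {t}")
    return x[p + burn:].T  # (n, n_out)


def simulate_tvmvar(schedule: CoefficientSchedule, noise_cov: np.ndarray,
                    duration: float, fs: float, seed: int) -> Recording:
    """Simulate a time-varying MVAR process as a continuous Recording.

    The schedule's segments define A(k, t); ``duration`` seconds are
    generated starting at the schedule's start time.  Innovations are
    i.i.d. Gaussian with covariance ``noise_cov``.  Identical seeds yield
    identical output.
    """
    if duration * fs < 10 * schedule.order:
        raise ValueError("duration too short for the model order")
    rng = np.random.default_rng(seed)
    t0 = schedule.start
    data = _simulate_window(schedule, noise_cov, t0, t0 + duration, fs, rng)
    labels = _default_labels(schedule.n_channels)
    return Recording(data=data, fs=fs, channel_labels=labels)


def _default_labels(n: int) -> tuple[str, ...]:
    if n == len(MONTAGE_10_20_21):
        return MONTAGE_10_20_21
    return tuple(f"ch{i + 1}" for i in range(n))


def generate_kmi_trialset(paradigm: ParadigmSpec,
                          rest_schedule: CoefficientSchedule,
                          task_schedule: CoefficientSchedule,
                          seed: int,
                          noise_cov: np.ndarray | None = None,
                          ) -> tuple[TrialSet, dict]:
    """Generate an epoched KMI trial set with known directed coupling.

    Each trial runs the rest schedule on [−rest_duration, 0) and the task
    schedule on [0, task_duration], simulated as one continuous process so
    the rest→task coefficient switch happens mid-trial, exactly as a
    stimulus-onset change.  Schedules are defined at ``paradigm.model_fs``;
    trials are emitted at ``paradigm.fs`` (band-limit upsampled when the
    two differ).  Returns the trial set and a ground-truth dict with the
    directed pairs coupled only in the task state.
    """
    if not (np.isclose(rest_schedule.start, -paradigm.rest_duration)
            and np.isclose(rest_schedule.end, 0.0)):
        raise ValueError("rest schedule must cover [-rest_duration, 0)")
    if not (np.isclose(task_schedule.start, 0.0)
            and np.isclose(task_schedule.end, paradigm.task_duration)):
        raise ValueError("task schedule must cover [0, task_duration]")
    if rest_schedule.n_channels != task_schedule.n_channels:
        raise ValueError("rest/task schedules disagree on channel count")
    full = concat_schedules(rest_schedule, task_schedule,
                            transition=task_schedule.transition)
    n = full.n_channels
    if noise_cov is None:
        noise_cov = np.eye(n)
    rng_root = np.random.SeedSequence(seed)
    n_trials = paradigm.n_trials_per_class * len(paradigm.classes)
    child_seeds = rng_root.spawn(n_trials)
    n_model = int(round(paradigm.trial_duration * paradigm.model_fs))
    data_model = np.empty((n_trials, n, n_model))
    labels: list[str] = []
    k = 0
    for cls in paradigm.classes:
        for _ in range(paradigm.n_trials_per_class):
            rng = np.random.default_rng(child_seeds[k])
            data_model[k] = _simulate_window(
                full, noise_cov, -paradigm.rest_duration,
                paradigm.task_duration, paradigm.model_fs, rng)
            labels.append(cls)
            k += 1
    q = paradigm.upsample_factor
    if q > 1:
        from scipy.signal import resample_poly
        data = resample_poly(data_model, q, 1, axis=-1)
    else:
        data = data_model
    n_samp = paradigm.samples_per_trial
    assert data.shape[-1] == n_samp
    times = (np.arange(n_samp) / paradigm.fs) - paradigm.rest_duration
    ts = TrialSet(data=data, times=times, labels=labels, fs=paradigm.fs,
                  channel_labels=_default_labels(n))
    truth = {"coupled_pairs": _task_only_pairs(rest_schedule, task_schedule)}
    return ts, truth


def _task_only_pairs(rest: CoefficientSchedule, task: CoefficientSchedule
                     ) -> list[tuple[int, int]]:
    rest_any = np.any([np.abs(s.coefficients) > 1e-12 for s in rest.segments], axis=(0, 1))
    task_any = np.any([np.abs(s.coefficients) > 1e-12 for s in task.segments], axis=(0, 1))
    n = rest.n_channels
    return [(i, j) for i in range(n) for j in range(n)
            if i != j and task_any[i, j] and not rest_any[i, j]]


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate a full synthetic cohort with a planted FMA→coupling link.

    Groups LS/RS/HC receive FMA-linked, FMA-linked, and fixed (``hc_gain``)
    task coupling gains respectively; healthy controls carry no FMA score.
    Task coupling is a directed ring over all channels so that, at a
    connectivity cost retaining ~n edges, a fully expressed coupling
    pattern yields a high-efficiency topology while weak coupling degrades
    toward noise-selected edges — the mechanism that links FMA to the
    downstream global-efficiency readout.
    """
    root = np.random.SeedSequence(spec.seed)
    n_subj = sum(spec.n_per_group)
    subj_seeds = root.spawn(n_subj + 1)
    score_rng = np.random.default_rng(subj_seeds[-1])
    noise_cov = spec.resolved_noise_cov()
    lo, hi = spec.fma_range
    fma_max = max(hi, 1e-12)
    edges = ring_edges(spec.n_channels)
    weights = graded_ring_weights(spec.n_channels)
    from .stats import classify_severity  # local import avoids a cycle

    subjects: list[SyntheticSubject] = []
    idx = 0
    for group, count in zip(("LS", "RS", "HC"), spec.n_per_group):
        for _ in range(count):
            if group == "HC":
                fma = None
                gain = spec.hc_gain
                severity = None
            else:
                fma = float(score_rng.uniform(lo, hi))
                gain = spec.base_gain + spec.coupling_gain_slope * (fma / fma_max)
                severity = classify_severity(fma)
            rest, task = kmi_schedules(
                spec.n_channels, spec.paradigm.model_fs, gain,
                rest_duration=spec.paradigm.rest_duration,
                task_duration=spec.paradigm.task_duration,
                coupled_edges=edges, edge_weights=weights,
            )
            trial_seed = int(subj_seeds[idx].generate_state(1)[0] % (2 ** 31))
            trials, _truth = generate_kmi_trialset(
                spec.paradigm, rest, task, trial_seed, noise_cov=noise_cov)
            record = CohortRecord(subject=f"{group}{idx + 1:02d}", group=group,
                                  fma=fma, severity=severity)
            subjects.append(SyntheticSubject(record, trials, gain, edges))
            idx += 1
    return subjects


def quick_cohort_spec(seed: int = 0, *, n_per_group: tuple[int, int, int] = (7, 5, 9),
                      coupling_gain_slope: float = 0.2,
                      n_trials_per_class: int = 6) -> CohortSpec:
    """Fast 3-channel cohort profile: 100 Hz generation, few trials.

    Used by tests and the ``--quick`` pipeline profile; same generative
    family as the full 21-channel/1000 Hz conditions, scaled down.
    """
    paradigm = ParadigmSpec(fs=100.0, n_trials_per_class=n_trials_per_class)
    return CohortSpec(n_per_group=n_per_group,
                      coupling_gain_slope=coupling_gain_slope,
                      seed=seed, n_channels=3, paradigm=paradigm)
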