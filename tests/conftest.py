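import numpy as np
import pytest

from tvconn.containers import Recording, TrialSet
from tvconn.synth import CoefficientSchedule, ScheduleSegment, simulate_tvmvar


@pytest.fixture(scope="session")
def bivariate_var1():
    """60 s of a stationary bivariate VAR(1): a11=a22=0.5, a21=0.5, a12=0."""
    A = np.array([[[0.5, 0.0], [0.5, 0.5]]])
    sched = CoefficientSchedule([ScheduleSegment(0.0, 60.0, A)])
    rec = simulate_tvmvar(sched, np.eye(2), 60.0, 100.0, seed=11)
    return A, rec


@pytest.fixture
def sine_recording():
    """Three channels: 5 Hz, 15 Hz and 12 Hz sinusoids at 1000 Hz."""
    fs = 1000.0
    t = np.arange(int(12 * fs)) / fs
    data = np.stack([np.sin(2 * np.pi * 5 * t),
                     np.sin(2 * np.pi * 15 * t),
                     np.sin(2 * np.pi * 12 * t)]) * 10.0
    return Recording(data=data, fs=fs, channel_labels=["s5", "s15", "s12"])


def make_trialset(data: np.ndarray, fs: float = 100.0, t0: float = -4.0,
                  labels=None) -> TrialSet:
    n_tr, _, n_samp = data.shape
    times = np.arange(n_samp) / fs + t0
    if labels is None:
        labels = ["left"] * n_tr
    chans = [f"ch{i + 1}" for i in range(data.shape[1])]
    return TrialSet(data=data, times=times, labels=labels, fs=fs,
                    channel_labels=chans)
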