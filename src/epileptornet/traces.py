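"""Trace phenomenology: spike/seizure detection and bifurcation location.

The model expresses three interictal phenotypes (silent resting state,
resting state with interictal spikes, resting state with recurrent seizures).
Spikes are brief large-amplitude transients of the epileptiform ensemble;
seizures additionally shift the output baseline for seconds at a time while
the slow variable traverses its ictal excursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .dynamics import simulate, single_node_connectome, equilibrium_state
from .params import CouplingParameters, IntegrationConfig, NodeParameters


@dataclass
class TraceClassification:
    label: str  # 'silent' | 'spiking' | 'seizing'
    spike_rate: float  # events per minute
    n_events: int
    event_times_s: np.ndarray
    seizure_episodes: list[tuple[float, float]] = field(default_factory=list)


def detect_spikes(
    output: np.ndarray,
    dt_ms: float,
    k: float = 5.0,
    hp_hz: float = 15.0,
    refractory_ms: float = 200.0,
) -> np.ndarray:
    """Spike event times (s) from threshold crossings of the fast residual.

    The output is high-pass filtered above the Hopf band so that only the
    fast edges of epileptiform transients remain; events are excursions of
    the residual beyond ``k`` robust standard deviations (1.4826*MAD),
    separated by at least the refractory period.
    """
    fs = 1000.0 / dt_ms
    if hp_hz >= fs / 2:
        raise ValueError("sampling rate too low for the spike high-pass filter")
    sos = butter(3, hp_hz, "highpass", fs=fs, output="sos")
    hp = sosfiltfilt(sos, output)
    sd = 1.4826 * np.median(np.abs(hp - np.median(hp)))
    if sd == 0:
        return np.array([])
    idx = np.flatnonzero(np.abs(hp) > k * sd)
    refr = int(round(refractory_ms / dt_ms))
    events = []
    last = -refr - 1
    for i in idx:
        if i - last > refr:
            events.append(i)
            last = i
    return np.asarray(events, dtype=float) * dt_ms / 1000.0


def detect_seizures(
    output: np.ndarray,
    dt_ms: float,
    shift_threshold: float = 0.25,
    min_duration_s: float = 3.0,
    lp_hz: float = 0.2,
) -> list[tuple[float, float]]:
    """Ictal episodes as sustained low-frequency baseline shifts.

    During a seizure the epileptiform ensemble moves to its ictal branch and
    the mixed output baseline shifts by ~0.9*p model units; episodes are
    intervals where the low-passed output deviates from its median by more
    than ``shift_threshold`` for at least ``min_duration_s``.
    """
    fs = 1000.0 / dt_ms
    sos = butter(3, lp_hz, "lowpass", fs=fs, output="sos")
    lp = sosfiltfilt(sos, output)
    dev = np.abs(lp - np.median(lp)) > shift_threshold
    edges = np.diff(dev.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if dev[0]:
        starts.insert(0, 0)
    if dev[-1]:
        ends.append(len(dev))
    min_len = int(round(min_duration_s * fs))
    return [
        (s * dt_ms / 1000.0, e * dt_ms / 1000.0)
        for s, e in zip(starts, ends)
        if e - s >= min_len
    ]


def classify_trace(
    output: np.ndarray,
    dt_ms: float,
    k: float = 5.0,
    hp_hz: float = 15.0,
    refractory_ms: float = 200.0,
    seizure_shift: float = 0.25,
    seizure_min_s: float = 3.0,
) -> TraceClassification:
    """Label a regional output trace as silent, spiking or seizing.

    Requires more than 60 s of model time.  The spike rate (events/min) is
    reported for all labels; for seizing traces it counts ictal discharges
    as well.
    """
    output = np.asarray(output, dtype=float)
    duration_s = len(output) * dt_ms / 1000.0
    if duration_s <= 60.0:
        raise ValueError(
            f"trace too short to classify ({duration_s:.1f} s <= 60 s)"
        )
    events = detect_spikes(output, dt_ms, k=k, hp_hz=hp_hz,
                           refractory_ms=refractory_ms)
    episodes = detect_seizures(output, dt_ms, shift_threshold=seizure_shift,
                               min_duration_s=seizure_min_s)
    rate = len(events) / (duration_s / 60.0)
    if episodes:
        label = "seizing"
    elif len(events) >= 1:
        label = "spiking"
    else:
        label = "silent"
    return TraceClassification(label, rate, len(events), events, episodes)


def _noise_free_run(params: NodeParameters, duration_s: float,
                    initial_state: np.ndarray, dt: float = 0.1):
    cfg = IntegrationConfig(dt=dt, duration=duration_s, discard=0.001,
                            seed=0, noise_x2y2=0.0, noise_x3=0.0)
    return simulate(single_node_connectome(), params, CouplingParameters(),
                    cfg, initial_state=initial_state[None, :])


def _oscillates(a: float, duration_s: float, tail_s: float,
                amp_threshold: float, base: NodeParameters) -> bool:
    """Sustained x3 oscillation of a noise-free isolated node at Hopf gain a."""
    eq = equilibrium_state(base)
    ic = eq.copy()
    ic[6] += 0.3  # kick the Hopf pair off its fixed point
    params = NodeParameters(x0=base.x0, a=a, p=base.p, b2=base.b2)
    traj = _noise_free_run(params, duration_s, ic)
    x3 = traj.variable("x3")[0]
    tail = x3[-int(tail_s * traj.fs):]
    return (tail.max() - tail.min()) > amp_threshold


def _seizes(x0: float, duration_s: float, base: NodeParameters) -> bool:
    """Autonomous ictal transition of a noise-free node at epileptogenicity x0."""
    eq = equilibrium_state(base)
    params = NodeParameters(x0=x0, a=base.a, p=base.p, b2=base.b2)
    traj = _noise_free_run(params, duration_s, eq)
    return bool(traj.variable("x1")[0].max() > -1.0)


def find_bifurcation(
    variable: str,
    bracket: tuple[float, float],
    tol: float = 0.01,
    duration_s: float | None = None,
    base: NodeParameters | None = None,
) -> float:
    """Bisect the critical value of ``a`` (Hopf) or ``x0`` (seizure onset).

    Classification runs noise-free from fixed initial conditions near the
    subcritical equilibrium: for ``a`` the criterion is a sustained x3
    oscillation after a 60 s transient (tail peak-to-peak > 0.02); for
    ``x0`` an autonomous ictal transition of x1 within the horizon.  Raises
    if both bracket endpoints classify identically.
    """
    if variable not in ("a", "x0"):
        raise ValueError("variable must be 'a' or 'x0'")
    base = base or NodeParameters(x0=-2.5, a=1.5, p=0.5)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")

    if variable == "a":
        duration_s = duration_s or 300.0
        classify = lambda v: _oscillates(v, duration_s, tail_s=50.0,
                                         amp_threshold=0.02, base=base)
    else:
        duration_s = duration_s or 600.0
        classify = lambda v: _seizes(v, duration_s, base=base)

    c_lo, c_hi = classify(lo), classify(hi)
    if c_lo == c_hi:
        raise ValueError(
            f"bracket [{lo}, {hi}] does not straddle the {variable} transition"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if classify(mid) == c_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def spectral_peak_hz(
    a: float = 1.8,
    duration_s: float = 300.0,
    analysis_s: float = 240.0,
    base: NodeParameters | None = None,
) -> float:
    """Dominant frequency (Hz) of x3 for a noise-free supercritical node."""
    from scipy.signal import periodogram

    base = base or NodeParameters(x0=-2.5, a=a, p=0.5)
    eq = equilibrium_state(NodeParameters(x0=base.x0, a=1.5, p=base.p))
    ic = eq.copy()
    ic[6] += 0.3
    traj = _noise_free_run(NodeParameters(x0=base.x0, a=a, p=base.p), duration_s, ic)
    x3 = traj.variable("x3")[0]
    seg = x3[-int(analysis_s * traj.fs):]
    f, pxx = periodogram(seg - seg.mean(), fs=traj.fs)
    return float(f[np.argmax(pxx)])
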