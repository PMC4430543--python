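"""Spike detection and derived electrophysiological measurements.

A "spike" is operationally a local maximum of v above 40 mV (relative to
rest) separated from neighbours by at least 2 ms; the peak time is refined
by parabolic interpolation of the three samples around the maximum.  The
40 mV / 2 ms criterion is a package choice (exposed as arguments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.signal import find_peaks

from .glcore import SolverConfig, Trajectory, default_dt
from .patch import PatchParams, Stimulus, simulate_patch

__all__ = [
    "SpikeTrain",
    "SpikingRange",
    "detect_spikes",
    "find_threshold",
    "refractory_interval",
    "asymptotic_spike_stats",
    "spiking_range",
]

SPIKE_THRESHOLD = 40.0   # mV above rest
MIN_SEPARATION = 2.0     # ms


@dataclass
class SpikeTrain:
    peak_times: np.ndarray   # ms
    peak_values: np.ndarray  # mV

    @property
    def n_spikes(self) -> int:
        return len(self.peak_times)

    @property
    def isi(self) -> np.ndarray:
        """Interspike intervals (ms)."""
        return np.diff(self.peak_times)

    @property
    def inst_freq(self) -> np.ndarray:
        """Instantaneous frequency per ISI, 1000/ISI (Hz)."""
        return 1000.0 / self.isi


@dataclass
class SpikingRange:
    """Constant-current limits [I1, I2] of repetitive firing (uA/cm^2)."""

    I1: Optional[float]
    I2: Optional[float]
    resolution: float

    @property
    def found(self) -> bool:
        return self.I1 is not None and self.I2 is not None


def detect_spikes(
    traj: Union[Trajectory, np.ndarray],
    times: Optional[np.ndarray] = None,
    threshold: float = SPIKE_THRESHOLD,
    min_separation: float = MIN_SEPARATION,
) -> SpikeTrain:
    """Locate spike peaks in a voltage trace.

    Accepts a patch :class:`Trajectory` or a plain voltage array with
    ``times``.  An empty train is a valid result.
    """
    if isinstance(traj, Trajectory):
        v = np.asarray(traj.v)
        t = np.asarray(traj.times)
    else:
        v = np.asarray(traj)
        t = np.asarray(times)
    if v.ndim != 1:
        raise ValueError("detect_spikes expects a single voltage trace")
    if len(v) < 3:
        return SpikeTrain(np.empty(0), np.empty(0))
    dt = t[1] - t[0]
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(v, height=threshold, distance=distance)
    pt = np.empty(len(idx))
    pv = np.empty(len(idx))
    for j, i in enumerate(idx):
        if 0 < i < len(v) - 1:
            denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
            delta = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom != 0 else 0.0
            pt[j] = t[i] + delta * dt
            pv[j] = v[i] - 0.25 * (v[i - 1] - v[i + 1]) * delta
        else:
            pt[j] = t[i]
            pv[j] = v[i]
    return SpikeTrain(pt, pv)


def _pulse_cfg(alpha: float, t_end: float, dt: Optional[float]) -> SolverConfig:
    return SolverConfig(dt=dt if dt is not None else default_dt(alpha), t_end=t_end)


def find_threshold(
    p: PatchParams,
    pulse_duration: float = 0.1,
    resolution: float = 0.5,
    t_end: float = 20.0,
    dt: Optional[float] = None,
    upper: float = 5000.0,
) -> float:
    """Brief-pulse spike threshold (uA/cm^2) by bisection.

    Returns the smallest amplitude, to ``resolution``, of a
    ``pulse_duration``-ms rectangular pulse at t = 0 that elicits a spike.
    """
    cfg = _pulse_cfg(p.alpha, t_end, dt)

    def spikes(amp: float) -> int:
        stim = Stimulus(kind="pulse", amplitude=amp, onset=0.0, duration=pulse_duration)
        return detect_spikes(simulate_patch(p, stim, cfg)).n_spikes

    lo, hi = 0.0, 64.0
    while spikes(hi) < 1:
        lo, hi = hi, hi * 2.0
        if hi > upper:
            raise RuntimeError(
                f"no spike up to {upper} uA/cm^2 for a {pulse_duration}-ms pulse"
            )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes(mid) >= 1:
            hi = mid
        else:
            lo = mid
    return hi


def refractory_interval(
    p: PatchParams,
    resolution: float = 0.05,
    threshold_resolution: float = 0.5,
    dt: Optional[float] = None,
    tail: float = 15.0,
) -> tuple:
    """Post-spike refractoriness probed with paired brief pulses.

    Two 0.1-ms pulses at 1.5x the single-pulse threshold are applied; the
    inter-stimulus interval is bisected (to ``resolution`` ms) for the
    smallest value still producing two spikes.  Returns
    ``(min_interval, time_to_peak, difference)`` where ``time_to_peak`` is
    the first-spike peak time and ``difference`` their gap — the interval
    between the first peak and the earliest effective second stimulus.
    """
    thr = find_threshold(p, resolution=threshold_resolution, dt=dt)
    amp = 1.5 * thr

    def spikes(interval: float) -> int:
        cfg = _pulse_cfg(p.alpha, interval + tail, dt)
        stim = Stimulus(
            kind="train", amplitude=amp, onset=0.0, duration=0.1,
            interval=interval, n_pulses=2,
        )
        return detect_spikes(simulate_patch(p, stim, cfg)).n_spikes

    lo, hi = 0.5, 25.0
    while spikes(hi) < 2:
        lo, hi = hi, hi * 2.0
        if hi > 100.0:
            raise RuntimeError("no second spike up to a 100-ms inter-stimulus interval")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes(mid) >= 2:
            hi = mid
        else:
            lo = mid

    cfg = _pulse_cfg(p.alpha, 20.0, dt)
    one = detect_spikes(
        simulate_patch(
            p, Stimulus(kind="pulse", amplitude=amp, onset=0.0, duration=0.1), cfg
        )
    )
    time_to_peak = float(one.peak_times[0])
    return hi, time_to_peak, hi - time_to_peak


def asymptotic_spike_stats(traj: Trajectory, window: float = 30.0) -> dict:
    """Asymptotic firing statistics over the final ``window`` ms.

    Returns count-based frequency ``freq`` ((spikes-1)/span, Hz), the mean
    instantaneous frequency ``freq_inst``, mean per-cycle spike amplitude
    (peak minus following trough, mV), peak current magnitudes (maximum
    depolarizing value for I_L), the Na-inactivation gate at peak |I_Na|
    (``h_peak``), and the first/final instantaneous frequency of the whole
    trace.  ``freq`` is 0 with ``spiking=False`` when fewer than two spikes
    fall in the window.
    """
    train = detect_spikes(traj)
    out = {
        "freq": 0.0,
        "freq_inst": 0.0,
        "amplitude": 0.0,
        "spiking": False,
        "freq_first": np.nan,
        "freq_final": np.nan,
        "h_peak": np.nan,
    }
    if train.n_spikes >= 2:
        f = train.inst_freq
        out["freq_first"] = float(f[0])
        out["freq_final"] = float(f[-1])
    t1 = traj.times[-1]
    t0 = t1 - window
    sel = train.peak_times >= t0
    pk = train.peak_times[sel]
    if len(pk) >= 2:
        out["spiking"] = True
        out["freq"] = 1000.0 * (len(pk) - 1) / (pk[-1] - pk[0])
        out["freq_inst"] = float(np.mean(1000.0 / np.diff(pk)))
        amps = []
        for a, b in zip(pk[:-1], pk[1:]):
            seg = (traj.times >= a) & (traj.times <= b)
            amps.append(np.max(traj.v[seg]) - np.min(traj.v[seg]))
        out["amplitude"] = float(np.mean(amps))
    wsel = traj.times >= t0
    if traj.currents:
        i_na = traj.currents["I_Na"][wsel]
        i_k = traj.currents["I_K"][wsel]
        i_l = traj.currents["I_L"][wsel]
        out["peak_I_Na"] = float(np.max(np.abs(i_na)))
        out["peak_I_K"] = float(np.max(np.abs(i_k)))
        out["peak_I_L"] = float(np.max(-i_l))
        if traj.h is not None:
            out["h_peak"] = float(traj.h[wsel][np.argmax(np.abs(i_na))])
    return out


def _is_spiking(p: PatchParams, i_app: float, cfg: SolverConfig) -> bool:
    stim = Stimulus(kind="step", amplitude=i_app, onset=0.0)
    traj = simulate_patch(p, stim, cfg)
    return asymptotic_spike_stats(traj)["spiking"]


def spiking_range(
    p: PatchParams,
    grid_resolution: float = 2.0,
    i_max: float = 200.0,
    refine: float = 0.5,
    t_end: float = 100.0,
    dt: Optional[float] = None,
) -> SpikingRange:
    """Repetitive-firing current range [I1, I2] by sweep plus bisection.

    A current counts as "spiking" when the final 30 ms of a ``t_end``-ms
    step-stimulus run contain at least two spikes.  Both limits are None
    (with the flag unset) when no grid point spikes — legitimate for very
    small fractional orders.
    """
    cfg = _pulse_cfg(p.alpha, t_end, dt)
    grid = np.arange(grid_resolution, i_max + grid_resolution / 2, grid_resolution)
    flags = np.array([_is_spiking(p, i, cfg) for i in grid])
    if not flags.any():
        return SpikingRange(None, None, refine)
    first = int(np.argmax(flags))
    last = len(flags) - 1 - int(np.argmax(flags[::-1]))

    def bisect(lo, hi, want_spiking_high):
        while hi - lo > refine:
            mid = 0.5 * (lo + hi)
            if _is_spiking(p, mid, cfg) == want_spiking_high:
                hi = mid
            else:
                lo = mid
        return hi

    i1 = grid[first] if first == 0 else bisect(grid[first - 1], grid[first], True)
    if last == len(grid) - 1:
        i2 = grid[last]
    else:
        # descending edge: bisect for the highest spiking current
        lo, hi = grid[last], grid[last + 1]
        while hi - lo > refine:
            mid = 0.5 * (lo + hi)
            if _is_spiking(p, mid, cfg):
                lo = mid
            else:
                hi = mid
        i2 = lo
    return SpikingRange(float(i1), float(i2), refine)
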