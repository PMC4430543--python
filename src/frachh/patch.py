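"""Space-clamped fractional-order Hodgkin-Huxley membrane patch.

The membrane potential v (mV, relative to rest, depolarization positive)
obeys

    Cm^alpha d^alpha v / dt^alpha = I(t) - I_Na - I_K - I_L,

with the classical squid-axon gating variables m, h, n kept first order:
non-ideal (constant-phase-element) capacitive behavior is a property of
the membrane dielectric, not of channel gating.  Cm^alpha is numerically 1
in uF/cm^2-based units, with ms^(alpha-1) absorbed into the units, so
alpha = 1 recovers the classical model unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .engine import integrate_hh
from .glcore import SolverConfig, Trajectory, gl_weights, memory_trace

__all__ = [
    "PatchParams",
    "Stimulus",
    "gating_rates",
    "steady_gates",
    "simulate_patch",
    "scaled_first_order_patch",
]


@dataclass
class PatchParams:
    """Squid-axon parameters in the rest-relative voltage convention."""

    alpha: float = 1.0
    Cm_alpha: float = 1.0        # uF/cm^2 (times ms^(alpha-1))
    g_Na: float = 120.0          # mS/cm^2
    g_K: float = 36.0
    g_L: float = 0.3
    E_Na: float = 115.0          # mV relative to rest
    E_K: float = -12.0
    E_L: float = 10.6
    conductance_scale: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # Na, K, L

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be non-negative")

    def scaled_conductances(self) -> Tuple[float, float, float]:
        sna, sk, sl = self.conductance_scale
        return self.g_Na * sna, self.g_K * sk, self.g_L * sl


@dataclass
class Stimulus:
    """Declarative applied-current protocol I(t) in uA/cm^2.

    kinds: "none"; "pulse" (one rectangular pulse); "step" (current on from
    onset until the end); "train" (n_pulses rectangular pulses whose onsets
    are `interval` ms apart).
    """

    kind: str = "none"
    amplitude: float = 0.0
    onset: float = 0.0
    duration: float = 0.1
    interval: float = 10.0
    n_pulses: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("none", "pulse", "step", "train"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.kind in ("pulse", "train") and self.duration <= 0:
            raise ValueError("pulse duration must be positive")

    def time_array(self, n_steps: int, dt: float) -> np.ndarray:
        """Amplitude at each step index (current over [t_j, t_j + dt))."""
        t = np.arange(n_steps) * dt
        out = np.zeros(n_steps)
        if self.kind == "none":
            return out
        if self.kind == "step":
            out[t >= self.onset] = self.amplitude
            return out
        n_p = 1 if self.kind == "pulse" else self.n_pulses
        for k in range(n_p):
            on = self.onset + k * self.interval
            out[(t >= on) & (t < on + self.duration)] = self.amplitude
        return out


def gating_rates(v):
    """Hodgkin-Huxley (1952) opening/closing rates at potential v.

    v is mV relative to rest; returns (alpha_m, beta_m, alpha_h, beta_h,
    alpha_n, beta_n) in 1/ms.  The removable singularities of alpha_m at
    v = 25 and alpha_n at v = 10 are filled by their series limits.
    """
    v = np.asarray(v, dtype=np.float64)
    xm = 25.0 - v
    xn = 10.0 - v
    with np.errstate(invalid="ignore", over="ignore"):
        am = np.where(
            np.abs(xm) < 1e-6, 1.0 - 0.05 * xm, 0.1 * xm / np.expm1(xm / 10.0)
        )
        an = np.where(
            np.abs(xn) < 1e-6, 0.1 - 0.005 * xn, 0.01 * xn / np.expm1(xn / 10.0)
        )
    bm = 4.0 * np.exp(-v / 18.0)
    ah = 0.07 * np.exp(-v / 20.0)
    bh = 1.0 / (np.exp((30.0 - v) / 10.0) + 1.0)
    bn = 0.125 * np.exp(-v / 80.0)
    if v.ndim == 0:
        return (float(am), float(bm), float(ah), float(bh), float(an), float(bn))
    return am, bm, ah, bh, an, bn


def steady_gates(v: float = 0.0) -> np.ndarray:
    """Steady-state (m, h, n) at a clamped potential (default: rest)."""
    am, bm, ah, bh, an, bn = gating_rates(v)
    return np.array([am / (am + bm), ah / (ah + bh), an / (an + bn)])


def _currents(p: PatchParams, v, m, h, n):
    gna, gk, gl = p.scaled_conductances()
    i_na = gna * m ** 3 * h * (v - p.E_Na)
    i_k = gk * n ** 4 * (v - p.E_K)
    i_l = gl * (v - p.E_L)
    return i_na, i_k, i_l


def simulate_patch(
    p: PatchParams,
    stim: Stimulus,
    cfg: SolverConfig,
    compute_v_mem: bool = False,
) -> Trajectory:
    """Integrate the fHH patch from rest; order alpha on v, order 1 on gates."""
    gna, gk, gl = p.scaled_conductances()
    n = cfg.n_steps
    res = integrate_hh(
        alpha=p.alpha,
        cfg=cfg,
        gna=np.array([gna]),
        gk=np.array([gk]),
        gl=np.array([gl]),
        ena=p.E_Na,
        ek=p.E_K,
        el=p.E_L,
        stim_t=stim.time_array(n, cfg.dt),
        stim_mask=np.ones(1),
        gates0=steady_gates()[None, :],
    )
    stride = cfg.record_stride
    v_full = res["v"][0]
    v = v_full[::stride].copy()
    m = res["rec_m"][:, 0]
    h = res["rec_h"][:, 0]
    ng = res["rec_n"][:, 0]
    i_na, i_k, i_l = _currents(p, v, m, h, ng)
    v_mem = None
    if compute_v_mem:
        v_mem = memory_trace(v_full, gl_weights(p.alpha, len(v_full)))[::stride]
    return Trajectory(
        times=res["times"][::stride].copy(),
        v=v,
        alpha=p.alpha,
        dt=cfg.dt,
        m=m,
        h=h,
        n=ng,
        currents={"I_Na": i_na, "I_K": i_k, "I_L": i_l},
        v_mem=v_mem,
    )


def measure_peak_currents(traj: Trajectory, window: float = 30.0) -> dict:
    """Asymptotic current peaks over the final `window` ms of a trajectory.

    Peak |I_Na| and |I_K| are magnitudes; peak I_L is the maximum
    *depolarizing* leak current (leak is depolarizing when it drives v
    upward, i.e. when I_L < 0 in the outward-positive sign convention).
    """
    t0 = traj.times[-1] - window
    sel = traj.times >= t0
    i_na = traj.currents["I_Na"][sel]
    i_k = traj.currents["I_K"][sel]
    i_l = traj.currents["I_L"][sel]
    return {
        "I_Na": float(np.max(np.abs(i_na))),
        "I_K": float(np.max(np.abs(i_k))),
        "I_L": float(np.max(-i_l)),
    }


def scaled_first_order_patch(
    p: PatchParams,
    peak_targets: dict,
    stim: Stimulus,
    cfg: SolverConfig,
    refine: int = 0,
    window: float = 30.0,
) -> Tuple[Trajectory, np.ndarray]:
    """First-order (alpha = 1) control with conductances rescaled to the
    fractional model's asymptotic peak current magnitudes.

    Peak current magnitudes are proportional to their conductances at a
    fixed voltage waveform, so each multiplier is the ratio of the target
    to the unscaled first-order peak (one proportional rescaling; targets
    from an alpha = 1 run give multipliers of exactly 1).  ``refine``
    optional damped fixed-point passes can tighten the match, but peak
    currents saturate in the first-order model and the exact-match problem
    is degenerate along a g_Na-up/g_K-down direction, so large ``refine``
    values trade waveform fidelity for peak fidelity.  The achieved
    relative peak mismatch is stored on the returned trajectory under
    ``currents["peak_residual"]``.
    """
    targets = np.array([peak_targets["I_Na"], peak_targets["I_K"], peak_targets["I_L"]])

    def run(mult):
        q = replace(p, alpha=1.0, conductance_scale=tuple(mult))
        traj = simulate_patch(q, stim, cfg)
        got = measure_peak_currents(traj, window=window)
        return traj, np.array([got["I_Na"], got["I_K"], got["I_L"]])

    _, base = run(np.ones(3))
    if np.any(base <= 0):
        raise RuntimeError(
            "scaled-conductance control: vanishing baseline peak current; "
            "cannot match targets"
        )
    mult = targets / base
    traj, meas = run(mult)
    for _ in range(refine):
        mult = mult * (targets / meas) ** 0.7
        traj, meas = run(mult)
    traj.currents["peak_residual"] = np.abs(meas - targets) / targets
    return traj, mult
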