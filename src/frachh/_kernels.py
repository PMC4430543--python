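"""Numba inner loops for the fractional Hodgkin-Huxley steppers.

Each kernel advances one near-field block of the GL scheme: the direct
history sum over the most recent ``near_len`` lags plus the precomputed
far-field accumulator ``F`` (see :mod:`frachh.glcore` and
:mod:`frachh.engine`).  Gating variables advance by forward Euler.  The
cable kernel is shared by the patch (nx = 1, no coupling) and the axon
(second-difference coupling, sealed ends); the network kernel adds
instantaneous sigmoidal synapses.

State histories are node-major, ``v[node, step]``, so the per-step history
dot product runs over contiguous memory.
"""

import numpy as np
from numba import njit

__all__ = ["hh_cable_block", "hh_network_block"]


@njit(cache=True, inline="always")
def _alpha_m(v):
    x = 25.0 - v
    if abs(x) < 1e-6:
        return 1.0 - 0.05 * x  # series limit of 0.1 x / (exp(x/10) - 1)
    return 0.1 * x / (np.expm1(x / 10.0))


@njit(cache=True, inline="always")
def _beta_m(v):
    return 4.0 * np.exp(-v / 18.0)


@njit(cache=True, inline="always")
def _alpha_h(v):
    return 0.07 * np.exp(-v / 20.0)


@njit(cache=True, inline="always")
def _beta_h(v):
    return 1.0 / (np.exp((30.0 - v) / 10.0) + 1.0)


@njit(cache=True, inline="always")
def _alpha_n(v):
    x = 10.0 - v
    if abs(x) < 1e-6:
        return 0.1 - 0.005 * x  # series limit of 0.01 x / (exp(x/10) - 1)
    return 0.01 * x / (np.expm1(x / 10.0))


@njit(cache=True, inline="always")
def _beta_n(v):
    return 0.125 * np.exp(-v / 80.0)


@njit(cache=True, inline="always")
def _clamp01(x):
    """Confine a gate to [0, 1]: the exact gate ODE never leaves the unit
    interval, so any excursion is explicit-Euler overshoot (it only occurs
    for extreme hyperpolarizing stimuli where the rates are stiff)."""
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True, fastmath=True)
def hh_cable_block(
    v,          # (nx, n_steps+1) voltage history; columns 0..s final
    F,          # (nx, n_steps+1) far-field accumulator
    c,          # GL weights, c[0] = c_1
    near_len,   # direct-sum window (1 for alpha = 1)
    s, e,       # advance steps s+1 .. e
    dt, dta,    # time step and dt**alpha
    m, h, n,    # (nx,) gate values at step s, updated in place
    gna, gk, gl,        # (nx,) conductances, mS/cm^2
    ena, ek, el,        # reversal potentials, mV relative to rest
    coup,       # axial coupling g/dx^2, mS/cm^2 (0 => space-clamped patch)
    stim_t,     # (n_steps,) stimulus amplitude at step index
    stim_mask,  # (nx,) spatial stimulus profile (0/1)
    stride, rec_m, rec_h, rec_n,  # gate recording every `stride` steps
):
    nx = v.shape[0]
    for t in range(s + 1, e + 1):
        kmax = min(near_len, t)
        amp = stim_t[t - 1]
        for i in range(nx):
            vi = v[i, t - 1]
            mi = m[i]
            hi = h[i]
            ni = n[i]
            ina = gna[i] * mi * mi * mi * hi * (vi - ena)
            ik = gk[i] * ni * ni * ni * ni * (vi - ek)
            il = gl[i] * (vi - el)
            f = amp * stim_mask[i] - ina - ik - il
            if coup > 0.0 and nx > 1:
                # sealed (zero-flux) ends via ghost-node mirroring; this
                # form conserves the plain node sum of v exactly
                if i == 0:
                    f += coup * (v[1, t - 1] - vi)
                elif i == nx - 1:
                    f += coup * (v[nx - 2, t - 1] - vi)
                else:
                    f += coup * (v[i + 1, t - 1] - 2.0 * vi + v[i - 1, t - 1])
            ssum = F[i, t]
            for k in range(kmax):
                ssum += c[k] * v[i, t - 1 - k]
            v[i, t] = ssum + dta * f
            # first-order gate dynamics (forward Euler)
            m[i] = _clamp01(mi + dt * (_alpha_m(vi) * (1.0 - mi) - _beta_m(vi) * mi))
            h[i] = _clamp01(hi + dt * (_alpha_h(vi) * (1.0 - hi) - _beta_h(vi) * hi))
            n[i] = _clamp01(ni + dt * (_alpha_n(vi) * (1.0 - ni) - _beta_n(vi) * ni))
        if t % stride == 0:
            r = t // stride
            for i in range(nx):
                rec_m[r, i] = m[i]
                rec_h[r, i] = h[i]
                rec_n[r, i] = n[i]


@njit(cache=True, fastmath=True)
def hh_network_block(
    v, F, c, near_len, s, e, dt, dta,
    m, h, n,
    gna, gk, gl, ena, ek, el,
    pre_idx,    # flat presynaptic neuron indices
    pre_exc,    # 1 if the synapse is excitatory, else 0
    offsets,    # (N+1,) slice bounds into pre_idx per postsynaptic neuron
    gsyn, esyn_ex, esyn_in, vsyn, ksyn,
    stim_t, stim_mask,
    stride, rec_m, rec_h, rec_n,
    isyn_e, isyn_i,  # (n_steps+1,) network-mean synaptic currents
):
    nx = v.shape[0]
    gates = np.empty(nx)
    for t in range(s + 1, e + 1):
        kmax = min(near_len, t)
        amp = stim_t[t - 1]
        acc_e = 0.0
        acc_i = 0.0
        # postsynaptic gates once per presynaptic neuron; far-sub-threshold
        # potentials contribute < 1e-5 and are clamped to zero
        for i in range(nx):
            vj = v[i, t - 1]
            if vj < vsyn - 12.0 * ksyn:
                gates[i] = 0.0
            else:
                gates[i] = 1.0 / (1.0 + np.exp(-(vj - vsyn) / ksyn))
        for i in range(nx):
            vi = v[i, t - 1]
            mi = m[i]
            hi = h[i]
            ni = n[i]
            ina = gna[i] * mi * mi * mi * hi * (vi - ena)
            ik = gk[i] * ni * ni * ni * ni * (vi - ek)
            il = gl[i] * (vi - el)
            se = 0.0
            si = 0.0
            for jj in range(offsets[i], offsets[i + 1]):
                gate = gates[pre_idx[jj]]
                if pre_exc[jj] == 1:
                    se += gate
                else:
                    si += gate
            ie = gsyn * se * (vi - esyn_ex)
            ii = gsyn * si * (vi - esyn_in)
            acc_e += ie
            acc_i += ii
            f = amp * stim_mask[i] - ina - ik - il - ie - ii
            ssum = F[i, t]
            for k in range(kmax):
                ssum += c[k] * v[i, t - 1 - k]
            v[i, t] = ssum + dta * f
            m[i] = _clamp01(mi + dt * (_alpha_m(vi) * (1.0 - mi) - _beta_m(vi) * mi))
            h[i] = _clamp01(hi + dt * (_alpha_h(vi) * (1.0 - hi) - _beta_h(vi) * hi))
            n[i] = _clamp01(ni + dt * (_alpha_n(vi) * (1.0 - ni) - _beta_n(vi) * ni))
        isyn_e[t] = acc_e / nx
        isyn_i[t] = acc_i / nx
        if t % stride == 0:
            r = t // stride
            for i in range(nx):
                rec_m[r, i] = m[i]
                rec_h[r, i] = h[i]
                rec_n[r, i] = n[i]
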