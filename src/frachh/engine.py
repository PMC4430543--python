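"""Shared driver for the fractional Hodgkin-Huxley numba kernels.

Couples the near-field block kernels in :mod:`frachh._kernels` with the
hierarchical FFT far-field accumulation of the full GL memory sum.  The
result is bit-for-bit a rearrangement of the direct O(n^2) history sum
(verified against a naive reference in the test suite).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from . import _kernels
from .glcore import NumericalInstabilityError, SolverConfig, V_ABORT, gl_weight_array

__all__ = ["integrate_hh"]


def _far_levels(block: int, n_steps: int, c: np.ndarray) -> dict:
    """Per-level FFT plans: the weight-slice transform is reused by every
    panel of its level, so it is computed once here."""
    levels = {}
    bl = block
    n = n_steps
    while bl < n:
        w = c[bl : min(2 * bl, n)]
        if len(w):
            conv_len = bl + len(w) - 1
            nfft = next_fast_len(conv_len)
            levels[bl] = (conv_len, nfft, rfft(w, nfft))
        bl *= 2
    return levels


def _far_update(v: np.ndarray, F: np.ndarray, levels: dict, m: int, n: int):
    """Fold history panels ending at column ``m`` into the accumulator."""
    if m == 0:
        return
    for bl, (conv_len, nfft, w_hat) in levels.items():
        if m % bl != 0:
            continue
        # chunk wide systems so large-panel FFT scratch stays bounded
        nx = v.shape[0]
        chunk = max(1, min(nx, int(4e7 // max(nfft, 1))))
        t0 = m + 1
        t1 = min(t0 + conv_len, n + 1)
        for a in range(0, nx, chunk):
            b = min(a + chunk, nx)
            conv = irfft(rfft(v[a:b, m - bl : m], nfft, axis=1) * w_hat, nfft, axis=1)
            F[a:b, t0:t1] += conv[:, : t1 - t0]


def _pick_block(n_steps: int, nx: int) -> int:
    if n_steps <= 4096:
        return n_steps
    return 128 if nx >= 16 else 1024


def integrate_hh(
    alpha: float,
    cfg: SolverConfig,
    gna: np.ndarray,
    gk: np.ndarray,
    gl: np.ndarray,
    ena: float,
    ek: float,
    el: float,
    stim_t: np.ndarray,
    stim_mask: np.ndarray,
    gates0: np.ndarray,
    coup: float = 0.0,
    network: Optional[dict] = None,
) -> dict:
    """Integrate the (f)HH equations for ``nx`` coupled nodes.

    Membrane potential advances with fractional order ``alpha`` (GL scheme,
    full memory unless ``cfg.memory_policy`` truncates it); gates advance
    first order.  ``coup`` is the discrete axial coupling g/dx^2 in mS/cm^2;
    ``network`` carries flat synaptic adjacency arrays for the network
    kernel.

    Returns raw arrays: full-resolution ``v`` (node-major), gate histories
    at ``cfg.record_stride``, and for networks the mean synaptic currents.
    """
    nx = len(gates0)
    n = cfg.n_steps
    dt = cfg.dt
    dta = dt ** alpha

    c = gl_weight_array(alpha, n)
    if isinstance(cfg.memory_policy, int):
        c = c.copy()
        c[cfg.memory_policy :] = 0.0

    if alpha == 1.0:
        B = n
        near = 1
        levels = {}
    else:
        B = _pick_block(n, nx)
        near = min(B, n)
        levels = _far_levels(B, n, c)

    v = np.zeros((nx, n + 1))
    F = np.zeros((nx, n + 1))
    m = np.ascontiguousarray(gates0[:, 0].copy())
    h = np.ascontiguousarray(gates0[:, 1].copy())
    ng = np.ascontiguousarray(gates0[:, 2].copy())

    stride = cfg.record_stride
    n_rec = n // stride + 1
    rec_m = np.empty((n_rec, nx))
    rec_h = np.empty((n_rec, nx))
    rec_n = np.empty((n_rec, nx))
    rec_m[0], rec_h[0], rec_n[0] = m, h, ng

    if network is not None:
        isyn_e = np.zeros(n + 1)
        isyn_i = np.zeros(n + 1)

    stim_t = np.ascontiguousarray(stim_t, dtype=np.float64)
    stim_mask = np.ascontiguousarray(stim_mask, dtype=np.float64)
    gna = np.ascontiguousarray(gna, dtype=np.float64)
    gk = np.ascontiguousarray(gk, dtype=np.float64)
    gl = np.ascontiguousarray(gl, dtype=np.float64)

    try:
        for s in range(0, n, B):
            _far_update(v, F, levels, s, n)
            e = min(s + B, n)
            if network is None:
                _kernels.hh_cable_block(
                    v, F, c, near, s, e, dt, dta, m, h, ng,
                    gna, gk, gl, float(ena), float(ek), float(el),
                    float(coup), stim_t, stim_mask,
                    stride, rec_m, rec_h, rec_n,
                )
            else:
                _kernels.hh_network_block(
                    v, F, c, near, s, e, dt, dta, m, h, ng,
                    gna, gk, gl, float(ena), float(ek), float(el),
                    network["pre_idx"], network["pre_exc"], network["offsets"],
                    network["gsyn"], network["esyn_ex"], network["esyn_in"],
                    network["vsyn"], network["ksyn"],
                    stim_t, stim_mask,
                    stride, rec_m, rec_h, rec_n,
                    isyn_e, isyn_i,
                )
            blk = v[:, s + 1 : e + 1]
            if not np.all(np.isfinite(blk)) or np.abs(blk).max() > V_ABORT:
                col_bad = ~np.all(np.isfinite(blk), axis=0) | (
                    np.abs(blk).max(axis=0) > V_ABORT
                )
                bad = s + 1 + int(np.argmax(col_bad))
                raise NumericalInstabilityError(bad, bad * dt, dt)
    except ZeroDivisionError:
        # numba surfaces divergent states as scalar division errors
        # inside the rate functions before the block check runs
        raise NumericalInstabilityError(-1, float("nan"), dt) from None

    out = {
        "v": v,
        "times": np.arange(n + 1) * dt,
        "rec_m": rec_m,
        "rec_h": rec_h,
        "rec_n": rec_n,
        "weights": c,
    }
    if network is not None:
        out["isyn_e"] = isyn_e
        out["isyn_i"] = isyn_i
    return out
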