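"""Shared fixtures and independent reference implementations.

The classical Hodgkin-Huxley forward-Euler integrator here is written
directly from the standard 1952 rate equations and shares no code with
the package; it serves as the independent oracle for alpha = 1
reductions.
"""

import math

import numpy as np
import pytest


def hh_rates_reference(v):
    """Standard squid-axon rates, rest-relative convention (independent)."""
    am = 1.0 if abs(25.0 - v) < 1e-12 else 0.1 * (25.0 - v) / (math.exp((25.0 - v) / 10.0) - 1.0)
    bm = 4.0 * math.exp(-v / 18.0)
    ah = 0.07 * math.exp(-v / 20.0)
    bh = 1.0 / (math.exp((30.0 - v) / 10.0) + 1.0)
    an = 0.1 if abs(10.0 - v) < 1e-12 else 0.01 * (10.0 - v) / (math.exp((10.0 - v) / 10.0) - 1.0)
    bn = 0.125 * math.exp(-v / 80.0)
    return am, bm, ah, bh, an, bn


def classical_hh_euler(dt, t_end, i_of_t, gna=120.0, gk=36.0, gl=0.3,
                       ena=115.0, ek=-12.0, el=10.6):
    """Forward-Euler classical HH from rest; returns (times, v) arrays."""
    n = int(round(t_end / dt))
    am, bm, ah, bh, an, bn = hh_rates_reference(0.0)
    m = am / (am + bm)
    h = ah / (ah + bh)
    ng = an / (an + bn)
    v = np.zeros(n + 1)
    for k in range(n):
        vi = v[k]
        ina = gna * m ** 3 * h * (vi - ena)
        ik = gk * ng ** 4 * (vi - ek)
        il = gl * (vi - el)
        v[k + 1] = vi + dt * (i_of_t(k * dt) - ina - ik - il)
        am, bm, ah, bh, an, bn = hh_rates_reference(vi)
        m += dt * (am * (1 - m) - bm * m)
        h += dt * (ah * (1 - h) - bh * h)
        ng += dt * (an * (1 - ng) - bn * ng)
    return np.arange(n + 1) * dt, v


@pytest.fixture(scope="session")
def classical_reference():
    return classical_hh_euler


@pytest.fixture(scope="session")
def rates_reference():
    return hh_rates_reference
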