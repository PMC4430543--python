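"""Grunwald-Letnikov weights, integrator and memory trace."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from frachh.analytic import PassiveParams, step_response
from frachh.glcore import (
    NumericalInstabilityError,
    SolverConfig,
    gl_integrate,
    gl_weight_array,
    gl_weights,
    memory_trace,
)


def closed_form_weights(alpha, n):
    """Binomial expression (-1)^(k-1) Gamma(a+1)/(Gamma(k+1) Gamma(a-k+2-1));
    evaluated through log-gamma with the reflection formula — independent of
    the package's recursion."""
    k = np.arange(1, n + 1, dtype=float)
    if alpha == 1.0:
        out = np.zeros(n)
        out[0] = 1.0
        return out
    # |c_k| = Gamma(a+1) / (Gamma(k+1) |Gamma(a-k+1)|); Gamma(a-k+1) has sign
    # (-1)^(k-1) for 0<a<1, so c_k = Gamma(a+1)/(Gamma(k+1)|Gamma(a-k+1)|).
    # Reflection: |Gamma(a-k+1)| = pi / (|sin(pi(a-k+1))| Gamma(k-a))
    log_abs = (
        gammaln(alpha + 1.0)
        - gammaln(k + 1.0)
        - (np.log(np.pi) - np.log(np.abs(np.sin(np.pi * (alpha - k + 1.0)))) - gammaln(k - alpha))
    )
    out = np.exp(log_abs)
    out[0] = alpha
    return out


class TestWeights:
    def test_first_weight_is_alpha(self):
        assert gl_weights(0.5, 1).weights.tolist() == [0.5]

    def test_integer_order_is_local(self):
        np.testing.assert_array_equal(gl_weights(1.0, 5).weights, [1, 0, 0, 0, 0])

    def test_second_weight_closed_form(self):
        # alpha(alpha-1)/2! with alternating sign gives 0.125 at alpha=0.5
        assert gl_weight_array(0.5, 2)[1] == pytest.approx(0.125, abs=1e-15)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.7, 0.9])
    def test_recursion_matches_binomial_expression(self, alpha):
        c = gl_weight_array(alpha, 200)
        ref = closed_form_weights(alpha, 200)
        np.testing.assert_allclose(c, ref, rtol=1e-10)

    @given(alpha=st.floats(0.05, 0.999))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_weight_invariants(self, alpha):
        c = gl_weight_array(alpha, 500)
        assert np.all(c > 0)
        assert np.all(np.diff(c) < 0)
        s = np.cumsum(c)
        assert np.all(s <= 1.0 + 1e-12)
        assert s[-1] > s[10]

    @pytest.mark.parametrize("alpha", [0.4, 0.7])
    def test_normalization_tail_bound(self, alpha):
        from scipy.special import gamma
        n = 10 ** 6
        s = float(np.sum(gl_weight_array(alpha, n)))
        assert abs(1.0 - s) < 10.0 * n ** (-alpha) / gamma(1.0 - alpha)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gl_weight_array(0.0, 5)
        with pytest.raises(ValueError):
            gl_weight_array(1.2, 5)
        with pytest.raises(ValueError):
            gl_weight_array(0.5, 0)


class TestGlIntegrate:
    def test_zero_rhs_stays_zero(self):
        cfg = SolverConfig(dt=0.01, t_end=1.0)
        traj = gl_integrate(lambda t, y: np.zeros(2), [0.0, 0.0], [0.6, 0.6], cfg)
        assert np.all(traj.v == 0.0)

    def test_integer_order_reduces_to_forward_euler(self):
        # dv/dt = -v + 1 from 0; independent explicit Euler loop
        cfg = SolverConfig(dt=1e-3, t_end=2.0)
        traj = gl_integrate(lambda t, y: 1.0 - y, [0.0], [1.0], cfg)
        y = 0.0
        ref = [0.0]
        for _ in range(cfg.n_steps):
            y += 1e-3 * (1.0 - y)
            ref.append(y)
        np.testing.assert_allclose(traj.v, ref, atol=1e-12)

    def test_fractional_passive_membrane_matches_mittag_leffler(self):
        # tau^a dv^a/dt^a = -v + Rm*Im u(t): GL solution vs analytic step
        # response within 1% relative over [0.01, 5] tau
        alpha = 0.6
        cfg = SolverConfig(dt=1e-3, t_end=5.0)
        traj = gl_integrate(lambda t, y: 1.0 - y, [0.0], [alpha], cfg)
        p = PassiveParams(alpha=alpha)
        sel = traj.times >= 0.01
        ref = step_response(traj.times[sel], p, Im=1.0)
        rel = np.abs(traj.v[sel] - ref) / np.abs(ref)
        assert rel.max() < 0.01

    def test_first_order_convergence_on_refinement(self):
        alpha = 0.6
        errs = []
        p = PassiveParams(alpha=alpha)
        ref = step_response(np.array([1.0]), p)[0]
        for dt in (4e-3, 2e-3, 1e-3):
            cfg = SolverConfig(dt=dt, t_end=1.0)
            traj = gl_integrate(lambda t, y: 1.0 - y, [0.0], [alpha], cfg)
            errs.append(abs(traj.v[-1] - ref))
        assert errs[1] < errs[0]
        assert errs[2] < errs[1]
        # halving dt reduces the error at least ~2x in the smooth regime
        assert errs[0] / errs[2] > 3.0

    def test_truncated_memory_error_bounded_by_dropped_tail(self):
        alpha = 0.5
        L = 50
        cfg_full = SolverConfig(dt=5e-3, t_end=2.0)
        cfg_trunc = SolverConfig(dt=5e-3, t_end=2.0, memory_policy=L)
        full = gl_integrate(lambda t, y: 1.0 - y, [0.0], [alpha], cfg_full)
        trunc = gl_integrate(lambda t, y: 1.0 - y, [0.0], [alpha], cfg_trunc)
        n = cfg_full.n_steps
        tail = np.sum(gl_weight_array(alpha, n)[L:])
        ymax = np.abs(full.v).max()
        # worst-case accumulated drop per step, summed over the run
        assert np.abs(full.v - trunc.v).max() <= tail * ymax * n

    def test_nonzero_fractional_initial_condition_rejected(self):
        cfg = SolverConfig(dt=0.01, t_end=0.5)
        with pytest.raises(ValueError):
            gl_integrate(lambda t, y: -y, [1.0], [0.5], cfg)

    def test_instability_reported_with_step_and_dt(self):
        cfg = SolverConfig(dt=0.5, t_end=50.0)
        with pytest.raises(NumericalInstabilityError) as err:
            gl_integrate(lambda t, y: 100.0 * y + 1.0, [0.0], [0.9], cfg)
        assert err.value.dt == 0.5
        assert err.value.step > 0


class TestMemoryTrace:
    def test_first_two_entries_are_zero(self):
        v = np.arange(10.0)
        out = memory_trace(v, gl_weights(0.6, 10))
        assert out[0] == 0.0 and out[1] == 0.0

    def test_integer_order_has_no_memory(self):
        v = np.random.default_rng(0).normal(size=50)
        out = memory_trace(v, gl_weights(1.0, 50))
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_history_sums_weight_tail(self):
        # v == c gives v_mem(t_{n+1}) = c * sum_{k=2}^{n+1} c_k
        c_val = 3.0
        n = 40
        w = gl_weights(0.7, n + 1)
        out = memory_trace(np.full(n, c_val), w)
        for m in range(2, n):
            expect = c_val * np.sum(w.weights[1:m])
            assert out[m] == pytest.approx(expect, rel=1e-12)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=30)
        alpha = 0.45
        w = gl_weights(alpha, 30)
        out = memory_trace(v, w)
        c = w.weights
        for m in range(2, 30):
            direct = sum(c[k] * v[m - 1 - k] for k in range(1, m))
            assert out[m] == pytest.approx(direct, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            memory_trace(np.zeros(10), gl_weights(0.5, 3))


class TestFastHistoryScheme:
    """The hierarchical near/far evaluation must equal the naive sum."""

    @pytest.mark.parametrize(
        "alpha,dt,t_end,amp",
        # at alpha=0.35 a strong pulse rings near the stability edge and
        # round-off differences amplify dynamically; use a mild pulse there
        [(0.35, 1e-4, 2.0, 50.0), (0.6, 2e-3, 12.0, 200.0), (0.85, 2e-3, 12.0, 200.0)],
    )
    def test_patch_equals_naive_direct_sum(self, alpha, dt, t_end, amp, rates_reference):
        from frachh.patch import PatchParams, Stimulus, simulate_patch

        stim = Stimulus(kind="pulse", amplitude=amp, onset=0.5, duration=0.1)
        cfg = SolverConfig(dt=dt, t_end=t_end)
        n = cfg.n_steps
        c = gl_weight_array(alpha, n)
        stim_arr = stim.time_array(n, dt)
        am, bm, ah, bh, an, bn = rates_reference(0.0)
        m, h, ng = am / (am + bm), ah / (ah + bh), an / (an + bn)
        v = np.zeros(n + 1)
        dta = dt ** alpha
        for t in range(1, n + 1):
            vi = v[t - 1]
            f = (stim_arr[t - 1] - 120 * m ** 3 * h * (vi - 115)
                 - 36 * ng ** 4 * (vi + 12) - 0.3 * (vi - 10.6))
            v[t] = np.dot(c[:t], v[t - 1::-1]) + dta * f
            am, bm, ah, bh, an, bn = rates_reference(vi)
            m += dt * (am * (1 - m) - bm * m)
            h += dt * (ah * (1 - h) - bh * h)
            ng += dt * (an * (1 - ng) - bn * ng)
        traj = simulate_patch(PatchParams(alpha=alpha), stim, cfg)
        assert np.max(np.abs(traj.v - v)) < 1e-9
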