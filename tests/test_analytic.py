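"""Mittag-Leffler evaluation and fractional passive-membrane theory."""

import numpy as np
import pytest

from frachh.analytic import (
    ImpulseResponse,
    PassiveParams,
    cable_green,
    cable_step_norm,
    impedance,
    mittag_leffler,
    pseudo_velocity,
    step_response,
    strength_duration,
)

import mpmath


def ml_series_highprec(alpha, beta, z):
    """Arbitrary-precision truncated power series (independent oracle).

    The alternating sum needs terms well past the magnitude peak near
    k = |z|^(1/alpha)/alpha and working precision beyond the peak height.
    """
    u = abs(z) ** (1.0 / alpha)
    dps = int(max(60, 0.8 * u + 60))
    kmax = int(max(400, 6 * u / alpha))
    with mpmath.workdps(dps):
        aa, bb, zz = map(mpmath.mpf, (alpha, beta, z))
        return float(mpmath.fsum(
            zz ** k / mpmath.gamma(aa * k + bb) for k in range(kmax)
        ))


class TestMittagLeffler:
    @pytest.mark.parametrize("z", [-2.0, 0.0, 1.0])
    def test_order_one_is_exponential(self, z):
        assert mittag_leffler(1.0, 1.0, z) == pytest.approx(np.exp(z), rel=1e-14)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_value_at_zero_is_reciprocal_gamma(self, beta):
        from scipy.special import gamma
        assert mittag_leffler(0.7, beta, 0.0) == pytest.approx(1 / gamma(beta), rel=1e-14)

    def test_half_order_at_minus_one(self):
        # frozen from a 200-term arbitrary-precision series; equals e*erfc(1)
        assert mittag_leffler(0.5, 1.0, -1.0) == pytest.approx(
            0.427583576155807, abs=1e-12
        )

    # y chosen per order so the arbitrary-precision oracle stays practical
    # (its working precision grows like y^(1/alpha) digits)
    @pytest.mark.parametrize("alpha,ys", [
        (0.4, (0.3, 2.0, 5.0, 8.0)),
        (0.6, (0.3, 2.0, 5.0, 12.0)),
        (0.8, (0.3, 2.0, 5.0, 12.0, 35.0)),
        (0.95, (0.3, 2.0, 5.0, 12.0, 35.0)),
    ])
    @pytest.mark.parametrize("beta_kind", ["one", "alpha"])
    def test_negative_axis_against_highprec_series(self, alpha, ys, beta_kind):
        beta = 1.0 if beta_kind == "one" else alpha
        for y in ys:
            ref = ml_series_highprec(alpha, beta, -y)
            got = mittag_leffler(alpha, beta, -y)
            assert got == pytest.approx(ref, rel=1e-8), f"y={y}"

    def test_positive_argument_growth(self):
        assert mittag_leffler(0.5, 1.0, 2.0) == pytest.approx(
            ml_series_highprec(0.5, 1.0, 2.0), rel=1e-10
        )

    def test_invalid_orders_rejected(self):
        with pytest.raises(ValueError):
            mittag_leffler(-0.5, 1.0, 0.3)
        with pytest.raises(ValueError):
            mittag_leffler(0.5, 0.0, 0.3)


class TestStepResponse:
    def test_zero_at_time_zero(self):
        assert step_response(0.0, PassiveParams(alpha=0.6)) == 0.0

    def test_order_one_is_exponential_charging(self):
        t = np.linspace(0, 5, 30)
        p = PassiveParams(alpha=1.0, Rm=2.0)
        np.testing.assert_allclose(
            step_response(t, p, Im=3.0), 6.0 * (1 - np.exp(-t / 2.0)), rtol=1e-12
        )

    def test_monotone_and_saturating(self):
        t = np.geomspace(1e-3, 200, 120)
        v = step_response(t, PassiveParams(alpha=0.5))
        assert np.all(np.diff(v) > 0)
        assert v[-1] == pytest.approx(1.0, abs=0.05)

    def test_fractional_membrane_charges_faster_early_then_slower(self):
        p6, p1 = PassiveParams(alpha=0.6), PassiveParams(alpha=1.0)
        assert step_response(0.05, p6) > step_response(0.05, p1)
        assert step_response(20.0, p6) < step_response(20.0, p1)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            step_response(-1.0, PassiveParams())


class TestStrengthDuration:
    def test_order_one_closed_form(self):
        d = np.geomspace(0.01, 50, 40)
        np.testing.assert_allclose(
            strength_duration(d, 1.0), 1.0 / (1.0 - np.exp(-d)), rtol=1e-12
        )

    def test_long_duration_approaches_rheobase(self):
        # the residual tail scales like d^-alpha, so the duration needed for
        # a 1% approach grows rapidly as the order drops
        assert strength_duration(100.0, 0.9) == pytest.approx(1.0, rel=0.01)
        assert strength_duration(1e4, 0.6) == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("alpha", [0.5, 0.8])
    def test_short_duration_power_law_slope(self, alpha):
        d = np.geomspace(1e-4, 1e-2, 20)
        i_t = strength_duration(d, alpha)
        slope = np.polyfit(np.log(d), np.log(i_t), 1)[0]
        assert slope == pytest.approx(-alpha, abs=0.05)

    def test_monotone_decreasing(self):
        d = np.geomspace(1e-3, 100, 60)
        assert np.all(np.diff(strength_duration(d, 0.7)) < 0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            strength_duration(0.0, 0.5)

    def test_threshold_current_recharges_to_rheobase_voltage(self):
        # plugging I_t(d) into the step response at t = d gives V = Rm*I_rheo
        p = PassiveParams(alpha=0.65)
        for d in (0.1, 1.0, 10.0):
            i_t = strength_duration(d, 0.65)
            assert step_response(d, p, Im=i_t) == pytest.approx(1.0, rel=1e-9)


class TestImpedance:
    def test_dc_limit_is_membrane_resistance(self):
        p = PassiveParams(alpha=0.5, Rm=3.0)
        assert impedance(0.0, p) == pytest.approx(3.0)
        # the DC approach goes like omega^alpha, hence the tiny frequency
        assert abs(impedance(1e-8, p)) / p.Rm == pytest.approx(1.0, abs=1e-3)

    def test_phase_minus_45_for_half_order(self):
        z = impedance(1e4, PassiveParams(alpha=0.5))
        assert np.degrees(np.angle(z)) == pytest.approx(-45.0, abs=1.0)

    @pytest.mark.parametrize("alpha", [0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
    def test_high_frequency_phase_is_constant_phase_element(self, alpha):
        z = impedance(1e4, PassiveParams(alpha=alpha))
        assert np.degrees(np.angle(z)) == pytest.approx(-90.0 * alpha, abs=1.0)

    def test_low_pass_magnitude(self):
        w = np.geomspace(1e-2, 1e4, 50)
        mag = np.abs(impedance(w, PassiveParams(alpha=0.6)))
        assert np.all(np.diff(mag) < 0)


class TestAlphaContinuity:
    def test_near_integer_order_matches_classical_forms(self):
        t = np.array([0.1, 1.0, 3.0])
        v = step_response(t, PassiveParams(alpha=0.999))
        np.testing.assert_allclose(v, 1 - np.exp(-t), rtol=0.01)
        z = impedance(10.0, PassiveParams(alpha=0.999))
        z1 = impedance(10.0, PassiveParams(alpha=1.0))
        assert abs(z - z1) / abs(z1) < 0.01


class TestCableGreen:
    def test_order_one_matches_classical_kernel(self):
        ir = cable_green(1.0, np.array([0.0, 0.5, 1.0]), np.array([0.05, 1.0]))
        for i, t in enumerate(ir.t_grid):
            ref = np.exp(-t - ir.x_grid ** 2 / (4 * t)) / np.sqrt(4 * np.pi * t)
            np.testing.assert_allclose(ir.G[i], ref, rtol=1e-4, atol=1e-9)

    def test_spatial_symmetry(self):
        x = np.linspace(-2, 2, 41)
        ir = cable_green(0.6, x, np.array([0.05, 0.5]))
        np.testing.assert_allclose(ir.G, ir.G[:, ::-1], atol=1e-12)

    def test_fractional_kernel_has_heavier_spatial_tails(self):
        x = np.array([2.0])
        g6 = cable_green(0.6, x, np.array([0.05])).G[0, 0]
        g1 = cable_green(1.0, x, np.array([0.05])).G[0, 0]
        assert g6 > 10 * g1

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            cable_green(0.6, [0.0], [0.0])


class TestCableStepResponse:
    def test_matches_independent_laplace_inversion(self):
        # oracle: Talbot inversion of exp(-|x| sqrt(s^a+1))/(2 s sqrt(s^a+1))
        for alpha, x, t in [(0.4, 1.0, 0.5), (0.6, 2.0, 2.0), (1.0, 0.5, 0.5)]:
            f = lambda s: mpmath.e ** (-x * mpmath.sqrt(s ** alpha + 1)) / (
                2 * s * mpmath.sqrt(s ** alpha + 1)
            )
            ref = float(mpmath.invertlaplace(f, t, method="talbot"))
            ref /= 0.5 * np.exp(-x)
            got = cable_step_norm(alpha, x, np.array([t]))[0]
            assert got == pytest.approx(ref, abs=1e-6)

    def test_saturates_to_local_steady_state(self):
        for alpha in (1.0, 0.6):
            r = cable_step_norm(alpha, 1.0, np.array([500.0]))[0]
            assert r == pytest.approx(1.0, abs=0.05)


class TestPseudoVelocity:
    def test_classical_cable_half_activation_speed(self):
        assert pseudo_velocity(1.0) == pytest.approx(2.0, rel=0.10)

    def test_continuity_near_order_one(self):
        assert pseudo_velocity(0.95) == pytest.approx(pseudo_velocity(1.0), rel=0.25)
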