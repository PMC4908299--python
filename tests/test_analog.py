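import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsn.analog import (AnalogFastSubsystem, AnalogSNParams, AnalogSNState,
                        DivergenceError, SigmoidSpec, TanhSpec,
                        TauCellParams, analog_jacobian, analog_nullclines,
                        analog_vector_field, integrate_analog,
                        sigmoid_current, tanh_current, tau_cell_response)
from qsn.common import StimulusProtocol, ThermalConstants

CONSTS = ThermalConstants()
nA = 1e-9


def make_params(**kw):
    base = dict(C_v=2e-12, I_a=0.1 * nA, tau_n=3e-4, tau_q=0.05,
                fm=SigmoidSpec(4 * nA, 0.0), fn=SigmoidSpec(4 * nA, 0.04),
                fq=SigmoidSpec(0.1 * nA, 0.05), g=TanhSpec(1 * nA, -0.03))
    base.update(kw)
    return AnalogSNParams(**base)


class TestSigmoidCurrent:
    def test_midpoint_is_half_amplitude(self):
        assert math.isclose(
            sigmoid_current(SigmoidSpec(1 * nA, 0.3), CONSTS, 0.3),
            0.5 * nA)

    def test_saturation(self):
        assert sigmoid_current(SigmoidSpec(1 * nA, 0.3), CONSTS, 1.0) \
            > 0.999 * nA

    def test_against_direct_formula(self):
        # independent high-precision evaluation of the exponential form
        M, delta, v = 1 * nA, 0.3, 0.35
        expect = M / (1.0 + math.exp(-(0.7 / 0.026) * (v - delta)))
        assert math.isclose(expect, 0.7935e-9, rel_tol=1e-3)
        got = sigmoid_current(SigmoidSpec(M, delta), CONSTS, v)
        assert math.isclose(got, expect, rel_tol=1e-14)

    def test_monotone_on_grid(self):
        vs = np.linspace(-0.5, 0.5, 1000)
        f = sigmoid_current(SigmoidSpec(2 * nA, 0.1), CONSTS, vs)
        assert np.all(np.diff(f) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_current(SigmoidSpec(1 * nA, 0.0), CONSTS, float("nan"))


class TestTanhCurrent:
    def test_odd_about_theta(self):
        spec = TanhSpec(1 * nA, 0.0)
        assert tanh_current(spec, CONSTS, 0.0) == 0.0
        a = tanh_current(spec, CONSTS, 0.07)
        b = tanh_current(spec, CONSTS, -0.07)
        assert math.isclose(a, -b, rel_tol=1e-12)

    def test_saturation(self):
        spec = TanhSpec(1 * nA, 0.0)
        assert tanh_current(spec, CONSTS, 5.0) > 0.999 * nA
        assert tanh_current(spec, CONSTS, -5.0) < -0.999 * nA

    def test_equals_tanh_closed_form(self):
        # g(v) = S*tanh(a/2), a = kou*(v-theta)/(1+1/kappa)
        S, v = 1 * nA, 0.05
        a = CONSTS.kou * v / (1 + 1 / CONSTS.kappa)
        expect = S * math.tanh(a / 2)
        assert math.isclose(expect, 0.2703e-9, rel_tol=1e-3)
        got = tanh_current(TanhSpec(S, 0.0), CONSTS, v)
        assert math.isclose(got, expect, rel_tol=1e-14)

    def test_shallower_than_sigmoid(self):
        # the (1+1/kappa) factor makes the rise wider than the sigmoid's
        v = 0.02
        s = sigmoid_current(SigmoidSpec(2 * nA, 0.0), CONSTS, v) - 1 * nA
        g = tanh_current(TanhSpec(1 * nA, 0.0), CONSTS, v)
        assert 0 < g < s


class TestVectorField:
    def test_null_system_is_zero(self):
        p = make_params(I_a=0.0, fm=SigmoidSpec(0.0, 0.0),
                        fn=SigmoidSpec(0.0, 0.0), fq=SigmoidSpec(0.0, 0.0),
                        g=TanhSpec(0.0, 0.0))
        dv, dn, dq = analog_vector_field(p, AnalogSNState(0.05, 0.0, 0.0),
                                         0.0)
        assert dv == dn == dq == 0.0

    def test_matches_independent_reimplementation(self, rng):
        p = make_params()
        for _ in range(5):
            v = rng.uniform(-0.3, 0.3)
            n = rng.uniform(0, 4) * nA
            q = rng.uniform(0, 1) * nA
            I = rng.uniform(-1, 1) * nA
            kou = CONSTS.kou
            fm = 4 * nA / (1 + math.exp(-kou * v))
            fn = 4 * nA / (1 + math.exp(-kou * (v - 0.04)))
            fq = 0.1 * nA / (1 + math.exp(-kou * (v - 0.05)))
            a = kou * (v + 0.03) / (1 + 1 / 0.7)
            g = 1 * nA * (1 - math.exp(-a)) / (1 + math.exp(-a))
            dv, dn, dq = analog_vector_field(p, AnalogSNState(v, n, q), I)
            assert math.isclose(dv, (-g + fm - n - q + 0.1 * nA + I) / 2e-12,
                                rel_tol=1e-12)
            assert math.isclose(dn, (fn - n) / 3e-4, rel_tol=1e-12)
            assert math.isclose(dq, (fq - q) / 0.05, rel_tol=1e-12)

    def test_vanishes_at_solver_equilibria(self):
        from qsn.dynamics import find_equilibria
        p = make_params()
        fast = AnalogFastSubsystem(p, q=0.7 * nA, v_range=(-0.35, 0.42))
        for e in find_equilibria(fast):
            dv, dn = fast.rhs(e.v, e.w)
            scale = p.current_scale / p.C_v
            assert abs(dv) < 1e-10 * scale
            assert abs(dn) < 1e-10 * p.current_scale / p.tau_n

    def test_jacobian_matches_finite_differences(self, rng):
        p = make_params()
        s = AnalogSNState(0.01, 1 * nA, 0.5 * nA)
        J = analog_jacobian(p, s)
        eps_v, eps_i = 1e-8, 1e-15
        for col, (dx, wrap) in enumerate([
                (eps_v, lambda d: AnalogSNState(s.v + d, s.n, s.q)),
                (eps_i, lambda d: AnalogSNState(s.v, s.n + d, s.q)),
                (eps_i, lambda d: AnalogSNState(s.v, s.n, s.q + d))]):
            f1 = np.array(analog_vector_field(p, wrap(dx), 0.0))
            f0 = np.array(analog_vector_field(p, wrap(-dx), 0.0))
            fd = (f1 - f0) / (2 * dx)
            assert np.allclose(J[:, col], fd, rtol=1e-5, atol=1e-3)


class TestNullclines:
    def test_flat_vnull_when_curves_off(self):
        p = make_params(fm=SigmoidSpec(0.0, 0.0), g=TanhSpec(0.0, 0.0))
        vn, _, _ = analog_nullclines(p, np.linspace(-0.2, 0.2, 50), 0.0, 0.0)
        assert np.allclose(vn, p.I_a)

    def test_nnull_midpoint(self):
        p = make_params()
        _, nn, _ = analog_nullclines(p, 0.04)
        assert math.isclose(nn, 2 * nA, rel_tol=1e-12)

    def test_vnull_reduces_to_printed_form_at_q_zero(self):
        p = make_params()
        vs = np.linspace(-0.2, 0.2, 20)
        vn0, _, _ = analog_nullclines(p, vs, q=0.0)
        vnq, _, _ = analog_nullclines(p, vs, q=0.3 * nA)
        assert np.allclose(vn0 - vnq, 0.3 * nA)

    def test_square_wave_preset_vnull_is_n_shaped(self, square_wave):
        fast = square_wave.planar()
        vs = np.linspace(*fast.v_range, 800)
        d = np.diff(fast.vnull(vs, 0.0))
        changes = np.count_nonzero(np.sign(d[:-1]) != np.sign(d[1:]))
        assert changes == 2


class TestTauCell:
    def test_constant_input_fixed_point(self):
        tc = TauCellParams(1e-12, 1 * nA)
        traj = tau_cell_response(tc, CONSTS, StimulusProtocol.constant(2 * nA),
                                 I_out0=2 * nA, T=1e-3)
        assert np.allclose(traj.states[:, 0], 2 * nA)

    def test_step_reaches_632_percent_at_tau(self):
        tc = TauCellParams(1e-12, 1 * nA)
        tau = tc.time_constant(CONSTS)
        traj = tau_cell_response(tc, CONSTS, StimulusProtocol.constant(1 * nA),
                                 I_out0=0.0, T=tau, dt=tau / 1000)
        expect = (1 - math.exp(-1.0)) * nA
        assert math.isclose(traj.states[-1, 0], expect, rel_tol=1e-6)

    def test_step_matches_closed_form_everywhere(self):
        tc = TauCellParams(2e-12, 0.5 * nA)
        tau = tc.time_constant(CONSTS)
        I0 = 3 * nA
        traj = tau_cell_response(tc, CONSTS, StimulusProtocol.constant(I0),
                                 I_out0=0.0, T=5 * tau, dt=tau / 100)
        for k in np.linspace(10, traj.t.size - 1, 10).astype(int):
            expect = I0 * (1 - math.exp(-traj.t[k] / tau))
            assert math.isclose(traj.states[k, 0], expect, rel_tol=1e-9)


class TestIntegration:
    def test_null_system_constant_trajectory(self):
        p = make_params(I_a=0.0, fm=SigmoidSpec(0.0, 0.0),
                        fn=SigmoidSpec(0.0, 0.0), fq=SigmoidSpec(0.0, 0.0),
                        g=TanhSpec(0.0, 0.0))
        traj = integrate_analog(p, AnalogSNState(0.02, 0.0, 0.0),
                                StimulusProtocol.none(), dt=1e-5, T=1e-3)
        assert np.allclose(traj.v, 0.02)

    def test_n_relaxes_exponentially_with_frozen_v(self):
        # a huge C_v freezes v, so n(t) -> f_n(v0) with time constant tau_n
        p = make_params(C_v=1.0)
        v0 = 0.1
        traj = integrate_analog(p, AnalogSNState(v0, 0.0, 0.0),
                                StimulusProtocol.none(), dt=1e-6, T=1.5e-3)
        fn = sigmoid_current(p.fn, CONSTS, v0)
        expect = fn * (1 - np.exp(-traj.t / p.tau_n))
        assert np.max(np.abs(traj["n"] - expect)) < 1e-5 * fn

    def test_divergence_reported_with_time(self):
        p = make_params()
        with pytest.raises(DivergenceError) as err:
            integrate_analog(p, AnalogSNState(-0.1, 0.0, 0.0),
                             StimulusProtocol.constant(5 * nA),
                             dt=1e-6, T=0.05, vmax=0.05)
        assert err.value.t_blow > 0

    def test_rk4_step_halving_consistency(self):
        # halving dt changes the endpoint at 4th order on a smooth run
        p = make_params()
        s0 = AnalogSNState(-0.2, 0.5 * nA, 0.2 * nA)
        ends = []
        for dt in (4e-6, 2e-6, 1e-6):
            traj = integrate_analog(p, s0, StimulusProtocol.none(),
                                    dt=dt, T=2e-3)
            ends.append(traj.states[-1])
        e1 = np.abs(ends[0][0] - ends[2][0])
        e2 = np.abs(ends[1][0] - ends[2][0])
        assert e2 < e1 / 8  # >= 4th-order would give 16; allow margin

    @settings(max_examples=10, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(-0.5e-9, 0.5e-9))
    def test_n_q_forward_invariant(self, frac, I):
        p = make_params()
        s0 = AnalogSNState(-0.1, frac * p.fn.M, frac * p.fq.M)
        traj = integrate_analog(p, s0, StimulusProtocol.constant(I),
                                dt=1e-5, T=5e-3)
        eps = 1e-15
        assert np.all(traj["n"] >= -eps)
        assert np.all(traj["n"] <= p.fn.M + eps)
        assert np.all(traj["q"] >= -eps)
        assert np.all(traj["q"] <= p.fq.M + eps)
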