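"""Three-variable analog silicon-neuron model.

The membrane equation integrates a steep rising sigmoid f_m(v) (differential
pair), a shallower odd-symmetric curve g(v) (transconductance amplifier), and
two first-order recovery currents n and q driven by sigmoids f_n, f_q through
Tau-cell (leaky current-mode) integrators:

    C_v dv/dt = -g(v) + f_m(v) - n - q + I_a + I_stim
      dn/dt   = (f_n(v) - n) / tau_n
      dq/dt   = (f_q(v) - q) / tau_q

v and n form the fast spike-generation subsystem; q is a slow negative
feedback whose placement against the fast subsystem's attractors produces
regular spiking, square-wave bursting, or elliptic bursting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .common import (DivergenceError, StimulusProtocol, ThermalConstants,
                     Trajectory)

__all__ = [
    "SigmoidSpec", "TanhSpec", "AnalogSNParams", "AnalogSNState",
    "TauCellParams", "sigmoid_current", "tanh_current", "analog_vector_field",
    "analog_nullclines", "tau_cell_response", "integrate_analog",
    "AnalogFastSubsystem",
]

DEFAULT_DT = 1e-5  # s; fixed-step RK4
DIVERGENCE_BOUND = 10.0  # volts


@dataclass(frozen=True)
class SigmoidSpec:
    """Saturating V-I curve of a differential pair: amplitude M, midpoint delta."""

    M: float
    delta: float

    def __post_init__(self):
        if self.M < 0:
            raise ValueError("sigmoid amplitude M must be >= 0")


@dataclass(frozen=True)
class TanhSpec:
    """Odd-symmetric V-I curve of a transconductance amplifier."""

    S: float
    theta_v: float

    def __post_init__(self):
        if self.S < 0:
            raise ValueError("tanh amplitude S must be >= 0")


@dataclass(frozen=True)
class TauCellParams:
    """Current-mode first-order low-pass with time constant C*U_T/I_tau."""

    C: float
    I_tau: float

    def __post_init__(self):
        if self.C <= 0 or self.I_tau <= 0:
            raise ValueError("Tau-cell C and I_tau must be positive")

    def time_constant(self, consts: ThermalConstants) -> float:
        return self.C * consts.U_T / self.I_tau


@dataclass(frozen=True)
class AnalogSNParams:
    C_v: float
    I_a: float
    tau_n: float
    tau_q: float
    fm: SigmoidSpec
    fn: SigmoidSpec
    fq: SigmoidSpec
    g: TanhSpec
    consts: ThermalConstants = ThermalConstants()

    def __post_init__(self):
        if self.C_v <= 0:
            raise ValueError("C_v must be positive")
        if self.tau_n <= 0 or self.tau_q <= 0:
            raise ValueError("tau_n and tau_q must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.C_v, self.I_a, self.tau_n, self.tau_q,
            self.fm.M, self.fm.delta, self.fn.M, self.fn.delta,
            self.fq.M, self.fq.delta, self.g.S, self.g.theta_v,
            self.consts.U_T, self.consts.kappa,
        ])

    def with_(self, **kw) -> "AnalogSNParams":
        """Copy with named scalar overrides, e.g. with_(M_q=1e-9, I_a=...)."""
        out = self
        for key, val in kw.items():
            if key in ("C_v", "I_a", "tau_n", "tau_q"):
                out = replace(out, **{key: val})
            elif key.startswith("M_") or key.startswith("delta_"):
                which, curve = key.split("_")
                spec = getattr(out, "f" + curve)
                out = replace(out, **{"f" + curve: replace(
                    spec, **{"M" if which == "M" else "delta": val})})
            elif key == "S":
                out = replace(out, g=replace(out.g, S=val))
            elif key == "theta_v":
                out = replace(out, g=replace(out.g, theta_v=val))
            else:
                raise KeyError(key)
        return out

    @property
    def current_scale(self) -> float:
        return max(self.fm.M, self.fn.M, self.fq.M, self.g.S,
                   abs(self.I_a), 1e-15)


@dataclass(frozen=True)
class AnalogSNState:
    v: float
    n: float
    q: float

    def as_tuple(self):
        return (self.v, self.n, self.q)


def _require_finite(v):
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")


def sigmoid_current(spec: SigmoidSpec, consts: ThermalConstants, v):
    """f_x(v) = M_x / (1 + exp(-(kappa/U_T)(v - delta_x)))."""
    _require_finite(v)
    t = np.clip(-consts.kou * (np.asarray(v, dtype=float) - spec.delta),
                -700.0, 700.0)
    out = spec.M / (1.0 + np.exp(t))
    return out if out.ndim else float(out)


def sigmoid_slope(spec: SigmoidSpec, consts: ThermalConstants, v):
    """Analytic df_x/dv."""
    f = sigmoid_current(spec, consts, v)
    if spec.M == 0:
        return np.zeros_like(np.asarray(v, dtype=float)) if np.ndim(v) else 0.0
    return consts.kou * f * (1.0 - f / spec.M)


def tanh_current(spec: TanhSpec, consts: ThermalConstants, v):
    """g(v) = S (1 - e^-a)/(1 + e^-a), a = (kappa/U_T)(v - theta_v)/(1 + 1/kappa).

    Equals S*tanh(a/2); shallower than the differential-pair sigmoid by the
    (1 + 1/kappa) factor and odd-symmetric about theta_v.
    """
    _require_finite(v)
    a = consts.kou * (np.asarray(v, dtype=float) - spec.theta_v) \
        / (1.0 + 1.0 / consts.kappa)
    out = spec.S * np.tanh(0.5 * a)
    return out if out.ndim else float(out)


def tanh_slope(spec: TanhSpec, consts: ThermalConstants, v):
    a = consts.kou * (np.asarray(v, dtype=float) - spec.theta_v) \
        / (1.0 + 1.0 / consts.kappa)
    k = 0.5 * consts.kou / (1.0 + 1.0 / consts.kappa)
    out = spec.S * k / np.cosh(0.5 * a) ** 2
    return out if out.ndim else float(out)


def analog_vector_field(p: AnalogSNParams, s: AnalogSNState, I_stim: float):
    """(dv/dt, dn/dt, dq/dt) of the full three-variable model."""
    return _kernels.analog_rhs(p.as_array(), s.v, s.n, s.q, I_stim)


def analog_jacobian(p: AnalogSNParams, s: AnalogSNState) -> np.ndarray:
    """Analytic 3x3 Jacobian at a state (independent of I_stim)."""
    fm1 = sigmoid_slope(p.fm, p.consts, s.v)
    fn1 = sigmoid_slope(p.fn, p.consts, s.v)
    fq1 = sigmoid_slope(p.fq, p.consts, s.v)
    g1 = tanh_slope(p.g, p.consts, s.v)
    return np.array([
        [(-g1 + fm1) / p.C_v, -1.0 / p.C_v, -1.0 / p.C_v],
        [fn1 / p.tau_n, -1.0 / p.tau_n, 0.0],
        [fq1 / p.tau_q, 0.0, -1.0 / p.tau_q],
    ])


def analog_nullclines(p: AnalogSNParams, v, q: float = 0.0,
                      I_stim: float = 0.0):
    """Nullcline ordinates at membrane voltage(s) v.

    Returns (n on the v-nullcline, n on the n-nullcline, q on the
    q-nullcline). The v-nullcline is taken in the fast-subsystem view with q
    held as a parameter, n = f_m(v) - g(v) - q + I_a + I_stim; at q = 0 this
    reduces to the q-absorbed form n = f_m(v) - g(v) + I_a + I_stim.
    """
    vn = (sigmoid_current(p.fm, p.consts, v) - tanh_current(p.g, p.consts, v)
          - q + p.I_a + I_stim)
    nn = sigmoid_current(p.fn, p.consts, v)
    qn = sigmoid_current(p.fq, p.consts, v)
    return vn, nn, qn


def tau_cell_response(tc: TauCellParams, consts: ThermalConstants,
                      I_in: StimulusProtocol, I_out0: float, T: float,
                      dt: float = DEFAULT_DT) -> Trajectory:
    """Integrate dI_out/dt = (I_in - I_out) / (C U_T / I_tau).

    The response within each piecewise-constant input segment is evaluated
    exactly (exponential relaxation), so the samples carry no scheme error.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    tau = tc.time_constant(consts)
    t = np.arange(0.0, T + 0.5 * dt, dt)
    out = np.empty_like(t)
    out[0] = I_out0
    for i in range(1, t.size):
        target = I_in.amplitude(t[i - 1])
        out[i] = target + (out[i - 1] - target) * math.exp(-dt / tau)
    return Trajectory(t, out[:, None], ("I_out",), dt,
                      meta={"tau": tau})


def integrate_analog(p: AnalogSNParams, s0: AnalogSNState,
                     stim: StimulusProtocol, dt: float = DEFAULT_DT,
                     T: float = 0.1,
                     vmax: float = DIVERGENCE_BOUND) -> Trajectory:
    """Fixed-step RK4 trajectory of the full model from t=0 to T."""
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    nsteps = int(round(T / dt))
    s0arr, s1arr, amparr = stim.arrays()
    out, i_blow = _kernels.integrate_analog(
        p.as_array(), s0.v, s0.n, s0.q, s0arr, s1arr, amparr, dt, nsteps, vmax)
    if i_blow >= 0:
        raise DivergenceError(i_blow * dt)
    t = np.arange(nsteps + 1) * dt
    return Trajectory(t, out, ("v", "n", "q"), dt)


class AnalogFastSubsystem:
    """Planar (v, n) view of the model with q frozen as a parameter.

    This is the object the dynamics toolkit analyses: the slow variable acts
    on the spike-generation subsystem exactly like a negative stimulus
    current.
    """

    ndim = 2
    slow_name = "q"

    def __init__(self, params: AnalogSNParams, q: float = 0.0,
                 v_range=(-0.3, 0.4), dt: float = DEFAULT_DT,
                 spike_threshold: float = 0.0):
        self.params = params
        self.q = q
        self.v_range = tuple(v_range)
        self.dt = dt
        self.spike_threshold = spike_threshold

    def with_slow(self, q: float) -> "AnalogFastSubsystem":
        return AnalogFastSubsystem(self.params, q, self.v_range, self.dt,
                                   self.spike_threshold)

    @property
    def current_scale(self) -> float:
        return self.params.current_scale

    def rhs(self, v: float, n: float, I: float = 0.0):
        dv, dn, _ = _kernels.analog_rhs(self.params.as_array(), v, n, self.q, I)
        return dv, dn

    def jac(self, v: float, n: float, I: float = 0.0) -> np.ndarray:
        p = self.params
        fm1 = sigmoid_slope(p.fm, p.consts, v)
        fn1 = sigmoid_slope(p.fn, p.consts, v)
        g1 = tanh_slope(p.g, p.consts, v)
        return np.array([[(-g1 + fm1) / p.C_v, -1.0 / p.C_v],
                         [fn1 / p.tau_n, -1.0 / p.tau_n]])

    def vnull(self, v, I: float = 0.0):
        vn, _, _ = analog_nullclines(self.params, v, self.q, I)
        return vn

    def wnull(self, v):
        return sigmoid_current(self.params.fn, self.params.consts, v)

    def simulate(self, v0: float, w0: float, stim: StimulusProtocol,
                 T: float, dt: float | None = None) -> Trajectory:
        dt = self.dt if dt is None else dt
        nsteps = int(round(T / dt))
        s0arr, s1arr, amparr = stim.arrays()
        out, i_blow = _kernels.integrate_analog_fast(
            self.params.as_array(), self.q, v0, w0, s0arr, s1arr, amparr,
            dt, nsteps, DIVERGENCE_BOUND)
        if i_blow >= 0:
            raise DivergenceError(i_blow * dt)
        t = np.arange(nsteps + 1) * dt
        return Trajectory(t, out, ("v", "n"), dt)
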