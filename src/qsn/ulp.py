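"""Two-variable ultralow-power analog silicon nerve membrane.

Both state variables are voltages across capacitors; all interactions are
subthreshold-MOSFET sigmoids:

    C_v dv/dt = f_v(v) - g_v(v) + I_av - r(n) + I_stim
    C_n dn/dt = f_n(v) - g_n(v) + I_an - r(n)

with f_x a differential-pair sigmoid, g_x a cascode sigmoid whose plateau is
I_0P * R_x20 * exp((kappa/U_T) theta_x), and r a strictly increasing sigmoid
in n. Substituting ntilde = r(n) gives an equivalent planar system whose
v-nullcline is ntilde = f_v - g_v + I_av + I_stim, which is what the
dynamics toolkit analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .common import (DivergenceError, StimulusProtocol, ThermalConstants,
                     Trajectory)

__all__ = [
    "ULPCurveSpec", "ULPSNParams", "ULPSNState", "ulp_f", "ulp_g", "ulp_r",
    "ulp_r_prime", "ulp_r_inverse", "ulp_vector_field",
    "ulp_transformed_vector_field", "integrate_ulp", "ULPPlanar",
]

DEFAULT_DT = 2e-6  # s
DIVERGENCE_BOUND = 10.0


@dataclass(frozen=True)
class ULPCurveSpec:
    """Per-variable curve bundle: f_x sigmoid (M, delta) and g_x cascode
    sigmoid (R20, R21, theta)."""

    M: float
    delta: float
    R20: float = 1.0
    R21: float = 1.0
    theta: float = 0.0

    def __post_init__(self):
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if self.R20 not in (0.5, 1.0):
            raise ValueError("R20 must be 0.5 or 1")
        if self.R21 not in (1.0, 2.0):
            raise ValueError("R21 must be 1 or 2")


@dataclass(frozen=True)
class ULPSNParams:
    C_v: float
    C_n: float
    I_av: float
    I_an: float
    I_0P: float
    curve_v: ULPCurveSpec
    curve_n: ULPCurveSpec
    theta_r: float
    consts: ThermalConstants = ThermalConstants()

    def __post_init__(self):
        if self.C_v <= 0 or self.C_n <= 0 or self.I_0P <= 0:
            raise ValueError("C_v, C_n, I_0P must be positive")

    def as_array(self) -> np.ndarray:
        cv, cn = self.curve_v, self.curve_n
        return np.array([
            self.C_v, self.C_n, self.I_av, self.I_an, self.I_0P,
            cv.M, cv.delta, cv.R20, cv.R21, cv.theta,
            cn.M, cn.delta, cn.R20, cn.R21, cn.theta,
            self.theta_r, self.consts.U_T, self.consts.kappa,
        ])

    @property
    def r_plateau(self) -> float:
        """Upper limit of r(n) = I_0P * exp((kappa/U_T) theta_r)."""
        return self.I_0P * math.exp(self.consts.kou * self.theta_r)

    @property
    def current_scale(self) -> float:
        return max(self.curve_v.M, self.curve_n.M, self.r_plateau,
                   abs(self.I_av), abs(self.I_an), 1e-15)

    def with_(self, **kw) -> "ULPSNParams":
        out = self
        for key, val in kw.items():
            if key in ("C_v", "C_n", "I_av", "I_an", "I_0P", "theta_r"):
                out = replace(out, **{key: val})
            elif key.endswith(("_v", "_n")) and key[:-2] in (
                    "M", "delta", "R20", "R21", "theta"):
                attr = "curve_" + key[-1]
                spec = getattr(out, attr)
                out = replace(out, **{attr: replace(spec, **{key[:-2]: val})})
            else:
                raise KeyError(key)
        return out


@dataclass(frozen=True)
class ULPSNState:
    v: float
    n: float


def ulp_f(curve: ULPCurveSpec, consts: ThermalConstants, v):
    """f_x(v) = M_x / (1 + exp(-(kappa/U_T)(v - delta_x)))."""
    t = np.clip(-consts.kou * (np.asarray(v, dtype=float) - curve.delta),
                -700.0, 700.0)
    out = curve.M / (1.0 + np.exp(t))
    return out if out.ndim else float(out)


def ulp_f_slope(curve: ULPCurveSpec, consts: ThermalConstants, v):
    f = ulp_f(curve, consts, v)
    if curve.M == 0:
        return 0.0 * f
    return consts.kou * f * (1.0 - f / curve.M)


def ulp_g(curve: ULPCurveSpec, consts: ThermalConstants, I_0P: float, v):
    """g_x(v) = I_0P R20 e^{(k/U_T)theta} / (1 + R21 e^{-(k/U_T)(v-theta)})."""
    A = I_0P * curve.R20 * math.exp(min(consts.kou * curve.theta, 700.0))
    t = np.clip(-consts.kou * (np.asarray(v, dtype=float) - curve.theta),
                -700.0, 700.0)
    out = A / (1.0 + curve.R21 * np.exp(t))
    return out if out.ndim else float(out)


def ulp_g_slope(curve: ULPCurveSpec, consts: ThermalConstants, I_0P: float, v):
    A = I_0P * curve.R20 * math.exp(min(consts.kou * curve.theta, 700.0))
    g = ulp_g(curve, consts, I_0P, v)
    return consts.kou * g * (1.0 - g / A)


def ulp_r(theta_r: float, consts: ThermalConstants, I_0P: float, n):
    """r(n) = I_0P e^{(k/U_T)theta_r} / (1 + e^{-(k/U_T)(n - theta_r)})."""
    P = I_0P * math.exp(min(consts.kou * theta_r, 700.0))
    t = np.clip(-consts.kou * (np.asarray(n, dtype=float) - theta_r),
                -700.0, 700.0)
    out = P / (1.0 + np.exp(t))
    return out if out.ndim else float(out)


def ulp_r_prime(theta_r: float, consts: ThermalConstants, I_0P: float, n):
    """dr/dn > 0 everywhere (r is strictly increasing, hence invertible)."""
    P = I_0P * math.exp(min(consts.kou * theta_r, 700.0))
    r = ulp_r(theta_r, consts, I_0P, n)
    return consts.kou * r * (1.0 - r / P)


def ulp_r_inverse(theta_r: float, consts: ThermalConstants, I_0P: float,
                  ntilde):
    """Closed-form logit inverse of r; domain (0, plateau)."""
    P = I_0P * math.exp(min(consts.kou * theta_r, 700.0))
    nt = np.asarray(ntilde, dtype=float)
    if np.any(nt <= 0) or np.any(nt >= P):
        raise ValueError("ntilde outside the open range of r")
    out = theta_r + np.log(nt / (P - nt)) / consts.kou
    return out if out.ndim else float(out)


def ulp_vector_field(p: ULPSNParams, s: ULPSNState, I_stim: float = 0.0):
    """(dv/dt, dn/dt) of the raw system."""
    return _kernels.ulp_rhs(p.as_array(), s.v, s.n, I_stim)


def ulp_transformed_vector_field(p: ULPSNParams, v: float, n_tilde: float,
                                 I_stim: float = 0.0):
    """(dv/dt, dntilde/dt) of the transformed system; n_tilde in range(r)."""
    if not (0.0 < n_tilde < p.r_plateau):
        raise ValueError("n_tilde outside range of r")
    return _kernels.ulp_rhs_tilde(p.as_array(), v, n_tilde, I_stim)


def integrate_ulp(p: ULPSNParams, s0, stim: StimulusProtocol,
                  dt: float = DEFAULT_DT, T: float = 0.05,
                  transformed: bool = False,
                  vmax: float = DIVERGENCE_BOUND) -> Trajectory:
    """RK4 trajectory of the raw (v, n) or transformed (v, ntilde) system.

    For the raw system the derived column ntilde = r(n) is appended, so both
    routes produce directly comparable traces.
    """
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    v0, n0 = s0
    nsteps = int(round(T / dt))
    s0arr, s1arr, amparr = stim.arrays()
    out, i_blow = _kernels.integrate_ulp(
        p.as_array(), v0, n0, s0arr, s1arr, amparr, dt, nsteps, vmax,
        transformed)
    if i_blow >= 0:
        raise DivergenceError(i_blow * dt)
    t = np.arange(nsteps + 1) * dt
    if transformed:
        return Trajectory(t, out, ("v", "ntilde"), dt)
    nt = ulp_r(p.theta_r, p.consts, p.I_0P, out[:, 1])
    states = np.column_stack([out, nt])
    return Trajectory(t, states, ("v", "n", "ntilde"), dt)


class ULPPlanar:
    """Planar view in (v, ntilde) coordinates for the dynamics toolkit."""

    ndim = 2
    slow_name = None

    def __init__(self, params: ULPSNParams, v_range=(0.0, 1.0),
                 dt: float = DEFAULT_DT, spike_threshold: float = 0.5):
        self.params = params
        self.v_range = tuple(v_range)
        self.dt = dt
        self.spike_threshold = spike_threshold

    @property
    def current_scale(self) -> float:
        return self.params.current_scale

    def rhs(self, v: float, nt: float, I: float = 0.0):
        return _kernels.ulp_rhs_tilde(self.params.as_array(), v, nt, I)

    def jac(self, v: float, nt: float, I: float = 0.0) -> np.ndarray:
        p = self.params
        c = p.consts
        P = p.r_plateau
        fv1 = ulp_f_slope(p.curve_v, c, v)
        gv1 = ulp_g_slope(p.curve_v, c, p.I_0P, v)
        fn1 = ulp_f_slope(p.curve_n, c, v)
        gn1 = ulp_g_slope(p.curve_n, c, p.I_0P, v)
        fn = ulp_f(p.curve_n, c, v)
        gn = ulp_g(p.curve_n, c, p.I_0P, v)
        rp = c.kou * nt * (P - nt) / P
        rp_d = c.kou * (P - 2.0 * nt) / P
        resid = fn - gn + p.I_an - nt
        return np.array([
            [(fv1 - gv1) / p.C_v, -1.0 / p.C_v],
            [rp * (fn1 - gn1) / p.C_n, (rp_d * resid - rp) / p.C_n],
        ])

    def vnull(self, v, I: float = 0.0):
        p = self.params
        return (ulp_f(p.curve_v, p.consts, v)
                - ulp_g(p.curve_v, p.consts, p.I_0P, v) + p.I_av + I)

    def wnull(self, v):
        p = self.params
        return (ulp_f(p.curve_n, p.consts, v)
                - ulp_g(p.curve_n, p.consts, p.I_0P, v) + p.I_an)

    def simulate(self, v0: float, w0: float, stim: StimulusProtocol,
                 T: float, dt: float | None = None) -> Trajectory:
        dt = self.dt if dt is None else dt
        p = self.params
        eps = 1e-9 * p.r_plateau
        w0 = float(np.clip(w0, eps, p.r_plateau - eps))
        nsteps = int(round(T / dt))
        s0arr, s1arr, amparr = stim.arrays()
        out, i_blow = _kernels.integrate_ulp(
            p.as_array(), v0, w0, s0arr, s1arr, amparr, dt, nsteps,
            DIVERGENCE_BOUND, True)
        if i_blow >= 0:
            raise DivergenceError(i_blow * dt)
        t = np.arange(nsteps + 1) * dt
        return Trajectory(t, out, ("v", "ntilde"), dt)
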