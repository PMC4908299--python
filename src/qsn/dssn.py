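"""Digital spiking silicon neuron (DSSN): piecewise-quadratic planar model.

    dv/dt = (phi/tau) (f(v) - n + I_0 + I_stim)
    dn/dt = (g(v) - n) / tau

f branches at v = 0 and g at v = r_g, each branch a(v-b)^2 + c. The
piecewise-quadratic f replaces the cubic of polynomial qualitative models so
a hardware step needs only one variable-variable multiplication. The model
is integrated by forward Euler, in double precision or in emulated
fixed-point arithmetic where every multiply/add result is quantized.

Spikes are defined as upward crossings of v through 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .common import (DivergenceError, SpikeTrain, StimulusProtocol,
                     Trajectory, spike_times)
from .fixedpoint import FixedPointFormat, FixedPointOverflowError, quantize

__all__ = ["DSSNParams", "DSSNState", "dssn_f", "dssn_g",
           "dssn_vector_field", "euler_step", "integrate_dssn",
           "dssn_spike_times", "DSSNPlanar", "NETWORK_DT"]

NETWORK_DT = 375e-6  # s; the network-experiment integration step
SPIKE_THRESHOLD = 0.0
DIVERGENCE_BOUND = 16.0


@dataclass(frozen=True)
class DSSNParams:
    phi: float
    tau: float
    I_0: float
    a_fn: float
    b_fn: float
    c_fn: float
    a_fp: float
    b_fp: float
    c_fp: float
    a_gn: float
    b_gn: float
    c_gn: float
    a_gp: float
    b_gp: float
    c_gp: float
    r_g: float
    continuity_bound: float = 1e-9

    def __post_init__(self):
        if self.tau <= 0 or self.phi <= 0:
            raise ValueError("tau and phi must be positive")
        rf, rg = self.continuity_residuals()
        if max(abs(rf), abs(rg)) > self.continuity_bound:
            raise ValueError(
                f"piecewise branches discontinuous: |f(0-)-f(0+)|={abs(rf):g},"
                f" |g(rg-)-g(rg+)|={abs(rg):g}")

    def continuity_residuals(self):
        rf = (self.a_fn * self.b_fn ** 2 + self.c_fn) \
            - (self.a_fp * self.b_fp ** 2 + self.c_fp)
        rg = (self.a_gn * (self.r_g - self.b_gn) ** 2 + self.c_gn) \
            - (self.a_gp * (self.r_g - self.b_gp) ** 2 + self.c_gp)
        return rf, rg

    def as_array(self) -> np.ndarray:
        return np.array([
            self.phi, self.tau, self.I_0,
            self.a_fn, self.b_fn, self.c_fn, self.a_fp, self.b_fp, self.c_fp,
            self.a_gn, self.b_gn, self.c_gn, self.a_gp, self.b_gp, self.c_gp,
            self.r_g,
        ])

    def with_(self, **kw) -> "DSSNParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DSSNState:
    v: float
    n: float


def _branch_quad(v, a_lo, b_lo, c_lo, a_hi, b_hi, c_hi, split):
    v = np.asarray(v, dtype=float)
    lo = a_lo * (v - b_lo) ** 2 + c_lo
    hi = a_hi * (v - b_hi) ** 2 + c_hi
    out = np.where(v < split, lo, hi)
    return out if out.ndim else float(out)


def dssn_f(p: DSSNParams, v):
    return _branch_quad(v, p.a_fn, p.b_fn, p.c_fn, p.a_fp, p.b_fp, p.c_fp, 0.0)


def dssn_g(p: DSSNParams, v):
    return _branch_quad(v, p.a_gn, p.b_gn, p.c_gn, p.a_gp, p.b_gp, p.c_gp,
                        p.r_g)


def dssn_f_slope(p: DSSNParams, v):
    v = np.asarray(v, dtype=float)
    out = np.where(v < 0.0, 2.0 * p.a_fn * (v - p.b_fn),
                   2.0 * p.a_fp * (v - p.b_fp))
    return out if out.ndim else float(out)


def dssn_g_slope(p: DSSNParams, v):
    v = np.asarray(v, dtype=float)
    out = np.where(v < p.r_g, 2.0 * p.a_gn * (v - p.b_gn),
                   2.0 * p.a_gp * (v - p.b_gp))
    return out if out.ndim else float(out)


def dssn_vector_field(p: DSSNParams, s: DSSNState, I_stim: float = 0.0):
    return _kernels.dssn_rhs(p.as_array(), s.v, s.n, I_stim)


def euler_step(p: DSSNParams, s: DSSNState, I_stim: float, dt: float,
               fmt: FixedPointFormat | None = None) -> DSSNState:
    """One forward-Euler step; with fmt, every arithmetic result is quantized."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if fmt is None:
        dv, dn = _kernels.dssn_rhs(p.as_array(), s.v, s.n, I_stim)
        return DSSNState(s.v + dt * dv, s.n + dt * dn)
    v, n = quantize(s.v, fmt), quantize(s.n, fmt)
    v2, n2 = _kernels.dssn_euler_fx(
        p.as_array(), v, n, I_stim, dt, fmt.scale, fmt.min_value,
        fmt.max_value, fmt.rounding == "nearest")
    if fmt.overflow == "error" and (abs(v2) >= fmt.max_value
                                    or abs(n2) >= fmt.max_value):
        raise FixedPointOverflowError("fixed-point state saturated")
    return DSSNState(v2, n2)


def integrate_dssn(p: DSSNParams, s0: DSSNState, stim: StimulusProtocol,
                   dt: float = NETWORK_DT, T: float = 1.0,
                   fmt: FixedPointFormat | None = None,
                   vmax: float = DIVERGENCE_BOUND) -> Trajectory:
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    nsteps = int(round(T / dt))
    s0arr, s1arr, amparr = stim.arrays()
    if fmt is None:
        out, i_blow = _kernels.integrate_dssn(
            p.as_array(), s0.v, s0.n, s0arr, s1arr, amparr, dt, nsteps, vmax,
            False, 1.0, -1.0, 1.0, False)
    else:
        out, i_blow = _kernels.integrate_dssn(
            p.as_array(), s0.v, s0.n, s0arr, s1arr, amparr, dt, nsteps, vmax,
            True, fmt.scale, fmt.min_value, fmt.max_value,
            fmt.rounding == "nearest")
    if i_blow >= 0:
        raise DivergenceError(i_blow * dt)
    t = np.arange(nsteps + 1) * dt
    return Trajectory(t, out, ("v", "n"), dt,
                      meta={"fixed_point": fmt is not None})


def dssn_spike_times(traj: Trajectory) -> SpikeTrain:
    """Spike times: upward crossings of v through 0, linearly interpolated."""
    return SpikeTrain(spike_times(traj.t, traj.v, SPIKE_THRESHOLD))


class DSSNPlanar:
    """Dynamics-toolkit adapter (the DSSN is already planar)."""

    ndim = 2
    slow_name = None

    def __init__(self, params: DSSNParams, v_range=(-1.2, 1.4),
                 dt: float = NETWORK_DT, spike_threshold: float = SPIKE_THRESHOLD):
        self.params = params
        self.v_range = tuple(v_range)
        self.dt = dt
        self.spike_threshold = spike_threshold

    @property
    def current_scale(self) -> float:
        return 1.0  # the model is dimensionless with O(1) nullclines

    def rhs(self, v: float, n: float, I: float = 0.0):
        return _kernels.dssn_rhs(self.params.as_array(), v, n, I)

    def jac(self, v: float, n: float, I: float = 0.0) -> np.ndarray:
        p = self.params
        return np.array([
            [p.phi / p.tau * dssn_f_slope(p, v), -p.phi / p.tau],
            [dssn_g_slope(p, v) / p.tau, -1.0 / p.tau],
        ])

    def vnull(self, v, I: float = 0.0):
        return dssn_f(self.params, v) + self.params.I_0 + I

    def wnull(self, v):
        return dssn_g(self.params, v)

    def simulate(self, v0: float, w0: float, stim: StimulusProtocol,
                 T: float, dt: float | None = None) -> Trajectory:
        dt = self.dt if dt is None else dt
        return integrate_dssn(self.params, DSSNState(v0, w0), stim,
                              dt=dt, T=T)
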