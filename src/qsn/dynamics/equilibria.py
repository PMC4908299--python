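"""Equilibria of planar fast subsystems: location, Jacobian, stability."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["Equilibrium", "find_equilibria", "jacobian"]

RESIDUAL_RTOL = 1e-10  # on the model's current scale
STABILITY_ATOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    v: float
    w: float
    eigenvalues: tuple
    label: str

    @property
    def stable(self) -> bool:
        return self.label.startswith("stable")

    @property
    def is_saddle(self) -> bool:
        return self.label == "saddle"


def _classify(eigs: np.ndarray, scale: float) -> str:
    re = np.real(eigs)
    im = np.imag(eigs)
    tol = STABILITY_ATOL * max(scale, 1.0)
    if np.all(np.abs(im) < tol) and re.min() < -tol < tol < re.max():
        return "saddle"
    focus = np.any(np.abs(im) > tol)
    if np.max(re) < 0:
        return "stable_focus" if focus else "stable_node"
    return "unstable_focus" if focus else "unstable_node"


def jacobian(model, state, I_stim: float = 0.0,
             slow_value: float | None = None) -> np.ndarray:
    """Analytic Jacobian of the planar vector field at ``state = (v, w)``."""
    if slow_value is not None:
        model = model.with_slow(slow_value)
    return model.jac(state[0], state[1], I_stim)


def find_equilibria(model, I_stim: float = 0.0,
                    slow_value: float | None = None,
                    v_range=None, grid: int = 2001) -> list:
    """All equilibria of the planar system in v_range.

    Roots of h(v) = vnull(v) - wnull(v) are bracketed by sign changes on a
    dense grid and polished with Brent's method; each is classified from the
    eigenvalues of the analytic Jacobian. Near-tangencies of the nullclines
    that produce no sign change (unresolved double roots) trigger a warning.
    """
    if slow_value is not None:
        model = model.with_slow(slow_value)
    lo, hi = v_range if v_range is not None else model.v_range
    vs = np.linspace(lo, hi, grid)
    h = np.asarray(model.vnull(vs, I_stim)) - np.asarray(model.wnull(vs))
    scale = model.current_scale

    def hfun(v):
        return float(model.vnull(v, I_stim) - model.wnull(v))

    roots = []
    sign = np.sign(h)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(hfun, vs[i], vs[i + 1], xtol=1e-15, rtol=1e-15))
    for i in np.nonzero(h == 0.0)[0]:
        roots.append(float(vs[i]))
    roots = sorted(roots)

    # flag grid-local minima of |h| that hug zero without crossing
    absh = np.abs(h)
    interior = (absh[1:-1] <= absh[:-2]) & (absh[1:-1] <= absh[2:])
    for i in np.nonzero(interior)[0] + 1:
        if absh[i] < 1e-8 * scale and sign[i - 1] == sign[i + 1] != 0:
            if not any(abs(vs[i] - r) < 2 * (vs[1] - vs[0]) for r in roots):
                warnings.warn(
                    f"possible unresolved double root near v = {vs[i]:.6g}",
                    RuntimeWarning, stacklevel=2)

    out = []
    for v in roots:
        w = float(model.wnull(v))
        resid = abs(hfun(v))
        if resid > RESIDUAL_RTOL * scale:
            warnings.warn(f"equilibrium residual {resid:g} above tolerance",
                          RuntimeWarning, stacklevel=2)
        eigs = np.linalg.eigvals(model.jac(v, w, I_stim))
        rate_scale = float(np.max(np.abs(eigs)))
        out.append(Equilibrium(v, w, tuple(eigs),
                               _classify(eigs, rate_scale)))
    return out
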