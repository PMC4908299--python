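"""Limit-cycle detection by forward simulation and spike-return analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..common import StimulusProtocol, spike_times
from .equilibria import find_equilibria

__all__ = ["LimitCycle", "detect_limit_cycle"]


@dataclass
class LimitCycle:
    v_min: float
    v_max: float
    period: float
    settled: bool
    end_state: tuple


def _default_start(model, I):
    """Perturbed start: displaced from the rightmost equilibrium, or mid-range."""
    eqs = find_equilibria(model, I)
    lo, hi = model.v_range
    if eqs:
        e = eqs[-1]
        return (e.v + 0.35 * (hi - e.v), e.w)
    return (0.5 * (lo + hi), float(model.wnull(0.5 * (lo + hi))))


def detect_limit_cycle(model, I: float = 0.0, T: float = 1.0,
                       dt: float | None = None, start=None,
                       rel_tol: float = 0.02, n_check: int = 5):
    """Simulate from a perturbed start and accept a cycle when successive
    spike-based return times agree within ``rel_tol``.

    Returns a LimitCycle (settled False = spiking but not converged within
    T: the sample is indeterminate) or None when the run ends subthreshold.
    """
    if start is None:
        start = _default_start(model, I)
    traj = model.simulate(start[0], start[1], StimulusProtocol.constant(I),
                          T, dt=dt)
    end_state = (float(traj.states[-1, 0]), float(traj.states[-1, 1]))
    half = traj.t[-1] * 0.5
    spk = spike_times(traj.t, traj.v, model.spike_threshold)
    spk = spk[spk >= half]
    if spk.size < 3:
        return None
    isis = np.diff(spk[-min(n_check + 1, spk.size):])
    period = float(np.mean(isis))
    settled = bool((isis.max() - isis.min()) < rel_tol * period)
    mask = traj.t >= spk[-1] - period
    return LimitCycle(float(traj.v[mask].min()), float(traj.v[mask].max()),
                      period, settled, end_state)
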