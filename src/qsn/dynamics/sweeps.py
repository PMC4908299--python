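"""One-parameter bifurcation sweeps with structural event detection.

Sweep-and-detect continuation: at each parameter sample the equilibria are
located and classified and a stable limit cycle is sought by forward
simulation (warm-started from the neighbouring sample in both sweep
directions, which follows stable branches through bistable windows). Events
are then classified from structural changes between adjacent samples:

- saddle_node      equilibrium count changes by two
- snic             saddle-node whose adjacent cycle period diverges
- hopf             a non-saddle equilibrium's complex pair crosses the axis
                   (flagged subcritical when a stable cycle coexists with the
                   stable equilibrium next to the crossing)
- saddle_loop      the cycle disappears while the saddle persists
- fold_of_cycles   the cycle disappears with an unchanged, stable equilibrium
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .cycles import LimitCycle, detect_limit_cycle
from .equilibria import find_equilibria

__all__ = ["BifurcationDiagram", "BifurcationEvent", "SweepSample",
           "sweep_bifurcation"]

PERIOD_DIVERGENCE_FACTOR = 10.0


@dataclass
class SweepSample:
    value: float
    equilibria: list
    cycle: LimitCycle | None
    indeterminate: bool = False


@dataclass
class BifurcationEvent:
    type: str
    interval: tuple
    info: dict = field(default_factory=dict)


@dataclass
class BifurcationDiagram:
    parameter: str
    samples: list

    events: list = field(default_factory=list)

    def events_of(self, kind: str):
        return [e for e in self.events if e.type == kind]


def _model_at(model, param, value):
    """Return (model, I_stim) realizing the given parameter value."""
    if param == "I_stim":
        return model, float(value)
    if param == getattr(model, "slow_name", None):
        return model.with_slow(float(value)), 0.0
    m = copy.copy(model)
    m.params = model.params.with_(**{param: float(value)})
    return m, 0.0


def _cycle_pass(model, param, values, T, dt, rel_tol):
    out = []
    warm = None
    for val in values:
        m, I = _model_at(model, param, val)
        cyc = detect_limit_cycle(m, I, T=T, dt=dt, start=warm,
                                 rel_tol=rel_tol)
        if cyc is None and warm is not None:
            # a cold start can still find a cycle the warm start left
            cyc = detect_limit_cycle(m, I, T=T, dt=dt, rel_tol=rel_tol)
        warm = cyc.end_state if cyc is not None else None
        out.append(cyc)
    return out


def sweep_bifurcation(model, parameter: str, values=None, prange=None,
                      resolution: int = 61, T: float = 1.0,
                      dt: float | None = None,
                      cycle_rel_tol: float = 0.02) -> BifurcationDiagram:
    """Sweep ``parameter`` (I_stim, the slow variable, or any model scalar)."""
    if values is None:
        if resolution < 50:
            raise ValueError("resolution must be >= 50")
        values = np.linspace(prange[0], prange[1], resolution)
    values = np.asarray(values, dtype=float)

    asc = _cycle_pass(model, parameter, values, T, dt, cycle_rel_tol)
    desc = _cycle_pass(model, parameter, values[::-1], T, dt,
                       cycle_rel_tol)[::-1]

    samples = []
    for i, val in enumerate(values):
        m, I = _model_at(model, parameter, val)
        eqs = find_equilibria(m, I)
        cands = [c for c in (asc[i], desc[i]) if c is not None]
        settled = [c for c in cands if c.settled]
        cyc = settled[0] if settled else None
        indet = bool(cands) and not settled
        samples.append(SweepSample(float(val), eqs, cyc, indet))

    diagram = BifurcationDiagram(parameter, samples)
    diagram.events = _detect_events(samples)
    return diagram


def _nearest_nonsaddle(eqs, v_ref):
    cands = [e for e in eqs if not e.is_saddle]
    if not cands:
        return None
    return min(cands, key=lambda e: abs(e.v - v_ref))


def _detect_events(samples) -> list:
    periods = [s.cycle.period for s in samples if s.cycle is not None]
    # the far-field reference is the fastest cycle seen: the one farthest
    # from any period-lengthening bifurcation
    far_period = float(np.min(periods)) if periods else np.inf
    events = []
    for a, b in zip(samples, samples[1:]):
        interval = (a.value, b.value)
        na, nb = len(a.equilibria), len(b.equilibria)
        # --- saddle-node / SNIC
        if abs(na - nb) == 2:
            near_cycles = [s.cycle for s in (a, b) if s.cycle is not None]
            diverged = any(c.period > PERIOD_DIVERGENCE_FACTOR * far_period
                           for c in near_cycles)
            kind = "snic" if diverged else "saddle_node"
            events.append(BifurcationEvent(kind, interval, {
                "counts": (na, nb),
                "period_ratio": (max(c.period for c in near_cycles)
                                 / far_period) if near_cycles else None,
            }))
        # --- Hopf: stability flip of a tracked non-saddle equilibrium
        for ea in a.equilibria:
            if ea.is_saddle:
                continue
            eb = _nearest_nonsaddle(b.equilibria, ea.v)
            if eb is None:
                continue
            if ea.stable != eb.stable:
                complex_pair = (
                    any(abs(np.imag(x)) > 0 for x in ea.eigenvalues)
                    or any(abs(np.imag(x)) > 0 for x in eb.eigenvalues))
                if not complex_pair:
                    continue
                stable_side = a if ea.stable else b
                subcritical = stable_side.cycle is not None
                events.append(BifurcationEvent("hopf", interval, {
                    "subcritical": subcritical, "v": ea.v}))
                break
        # --- cycle disappearance: saddle-loop vs fold of cycles
        ca, cb = a.cycle, b.cycle
        if (ca is None) != (cb is None):
            have, lack = (a, b) if ca is not None else (b, a)
            saddle_persists = (any(e.is_saddle for e in have.equilibria)
                               and any(e.is_saddle for e in lack.equilibria))
            if saddle_persists:
                events.append(BifurcationEvent("saddle_loop", interval, {
                    "period_ratio": have.cycle.period / far_period}))
            elif (len(have.equilibria) == len(lack.equilibria)
                  and all(not e.is_saddle for e in have.equilibria)
                  and any(e.stable for e in have.equilibria)
                  and any(e.stable for e in lack.equilibria)):
                events.append(BifurcationEvent("fold_of_cycles", interval, {
                    "period_ratio": have.cycle.period / far_period}))
    return events
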