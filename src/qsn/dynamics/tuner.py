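"""Seeded stochastic mode tuner.

Finds model parameters that realize a target neuronal class by simulated
annealing on a geometry objective (required equilibrium counts and
stabilities, N-shaped v-nullcline, curve-ordering heuristics, slow-nullcline
placement), followed by dynamical verification with the classify/sweep
operations. The search heuristics mirror how the analog circuit is tuned by
hand: steepen the rising phase (raise the fast sigmoid amplitude), steepen
the falling phases (raise the opposing-curve amplitude), keep the opposing
curve's midpoint below the fast sigmoid's, and place the slow nullcline
between the fast subsystem's limit cycle and its resting equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..common import SpikeTrain, StimulusProtocol
from .bursts import segment_bursts
from .equilibria import find_equilibria
from .firing import classify_excitability, fi_curve

__all__ = ["tune_mode", "TuneResult"]


@dataclass
class TuneResult:
    success: bool
    params: object
    penalty: float
    report: dict
    log: list = field(default_factory=list)


def _nshape_score(model, I=0.0, npts=400):
    """0 when the v-nullcline derivative changes sign exactly twice."""
    lo, hi = model.v_range
    vs = np.linspace(lo, hi, npts)
    w = np.asarray(model.vnull(vs, I))
    d = np.diff(w)
    sign_changes = int(np.count_nonzero(np.sign(d[:-1]) != np.sign(d[1:])))
    return abs(sign_changes - 2)


def _label_pattern(eqs):
    return tuple("stable" if e.stable else ("saddle" if e.is_saddle
                                            else "unstable") for e in eqs)


def _geometry_penalty_class1(model):
    pen = 5.0 * _nshape_score(model)
    eqs = find_equilibria(model)
    pat = _label_pattern(eqs)
    if pat != ("stable", "saddle", "unstable"):
        pen += 10.0 + 5.0 * abs(len(eqs) - 3)
    return pen


def _geometry_penalty_class2(model):
    pen = 5.0 * _nshape_score(model)
    eqs = find_equilibria(model)
    if len(eqs) != 1 or not eqs[0].stable:
        pen += 10.0 + 5.0 * abs(len(eqs) - 1)
        return pen
    # the rest state should sit close to instability so a modest stimulus
    # can carry it through the Hopf point
    tr = float(np.trace(model.jac(eqs[0].v, eqs[0].w)))
    rate = max(abs(x) for x in eqs[0].eigenvalues)
    margin = -tr / rate  # >0 stable; small = near instability
    if margin > 0.8:
        pen += margin - 0.8
    return pen


def _geometry_penalty_square_wave(builder, params, q_probe):
    """Fast-subsystem structure over a probe range of the slow variable:
    want a window with 3 equilibria (rest + saddle) whose q-nullcline lies
    between the resting branch and the spiking branch."""
    from ..analog import AnalogFastSubsystem, sigmoid_current
    fast0 = builder(params)
    pen = 5.0 * _nshape_score(fast0)
    counts = []
    window = []
    for q in q_probe:
        eqs = find_equilibria(fast0.with_slow(q))
        counts.append(len(eqs))
        if len(eqs) == 3 and _label_pattern(eqs) == (
                "stable", "saddle", "unstable"):
            window.append((q, eqs))
    if not window:
        return pen + 10.0 + 5.0 * min(abs(c - 3) for c in counts)
    # q-nullcline placement: at the resting v, f_q must pull q below the
    # window (silence ends); at spiking v, push it above (bursts end)
    q_lo, q_hi = window[0][0], window[-1][0]
    eqs = window[len(window) // 2][1]
    p = fast0.params
    fq_rest = sigmoid_current(p.fq, p.consts, eqs[0].v)
    fq_spike = sigmoid_current(p.fq, p.consts, fast0.v_range[1])
    if not fq_rest < q_lo:
        pen += 1.0 + abs(fq_rest - q_lo) / max(q_hi - q_lo, 1e-15)
    if not fq_spike > q_hi:
        pen += 1.0 + abs(fq_spike - q_hi) / max(q_hi - q_lo, 1e-15)
    return pen


def _apply(base, names, x):
    return base.with_(**dict(zip(names, x)))


def verify_class1(model, I_grid, T):
    fi = fi_curve(model, I_grid, T=T)
    try:
        label, rep = classify_excitability(fi)
    except RuntimeError:
        return False, {"error": "no spiking in range"}
    return label == "class1", rep


def verify_class2(model, I_grid, T):
    fi = fi_curve(model, I_grid, T=T)
    try:
        label, rep = classify_excitability(fi)
    except RuntimeError:
        return False, {"error": "no spiking in range"}
    return label == "class2", rep


def verify_square_wave(params, T, dt, threshold):
    """Autonomous alternation between spiking and silence, with the slow
    variable rising inside bursts and falling in the gaps."""
    from ..analog import AnalogSNState, integrate_analog
    traj = integrate_analog(params, AnalogSNState(-0.1, 0.0, 0.0),
                            StimulusProtocol.none(), dt=dt, T=T)
    half = traj.t >= 0.5 * T
    train = traj.spike_train(threshold)
    spk = train.times[train.times >= 0.5 * T]
    seq = segment_bursts(SpikeTrain(spk))
    if len(seq) < 3:
        return False, {"bursts": len(seq)}
    q = traj["q"]
    dq = np.gradient(q, traj.dt)
    inside = np.zeros(traj.t.size, dtype=bool)
    for b in seq.bursts:
        inside |= (traj.t >= b.start) & (traj.t <= b.end)
    silent = half & ~inside
    inside &= half
    up = float(np.mean(dq[inside] > 0)) if inside.any() else 0.0
    down = float(np.mean(dq[silent] < 0)) if silent.any() else 0.0
    ok = up >= 0.9 and down >= 0.9 and len(seq) >= 3
    return ok, {"bursts": len(seq), "frac_dq_up_in_burst": up,
                "frac_dq_down_in_silence": down,
                "counts": seq.counts}


def tune_mode(family: str, target: str, search: dict, seed: int
              ) -> TuneResult:
    """Stochastic search for a parameter set realizing ``target``.

    ``search`` keys:
      base        starting parameter object (AnalogSNParams/ULPSNParams/
                  DSSNParams)
      builder     callable params -> planar model adapter
      bounds      {scalar name: (lo, hi, 'log'|'lin')}
      budget      max objective evaluations (default 300)
      verify      optional callable params -> (ok, report); when omitted a
                  geometry-only success criterion is used
      q_probe     slow-variable probe grid (square_wave only)
    """
    rng = np.random.default_rng(seed)
    base = search["base"]
    builder = search["builder"]
    bounds = search["bounds"]
    budget = int(search.get("budget", 300))
    verify = search.get("verify")
    names = list(bounds)

    def clip(x):
        return [min(max(xi, bounds[k][0]), bounds[k][1])
                for k, xi in zip(names, x)]

    if target not in ("class1", "class2", "rs", "elliptic", "square_wave"):
        raise ValueError(f"unknown target {target!r}")

    def penalty(x):
        try:
            params = _apply(base, names, x)
        except ValueError:
            return 1e3  # invalid parameter combination
        if target == "square_wave":
            return _geometry_penalty_square_wave(
                builder, params, search["q_probe"])
        model = builder(params)
        if target in ("class1", "rs"):
            return _geometry_penalty_class1(model)
        return _geometry_penalty_class2(model)

    x = clip([getattr_nested(base, k) for k in names])
    best_x, best_pen = list(x), penalty(x)
    cur_x, cur_pen = list(best_x), best_pen
    log = [(0, best_pen)]
    temp0 = max(best_pen, 1.0)
    for it in range(1, budget):
        temp = temp0 * (0.01 ** (it / budget))
        k = int(rng.integers(len(names)))
        lo, hi, scale = bounds[names[k]]
        prop = list(cur_x)
        if scale == "log" and lo > 0:
            prop[k] = float(np.exp(np.log(cur_x[k])
                                   + 0.25 * rng.standard_normal()))
        else:
            prop[k] = float(cur_x[k] + 0.1 * (hi - lo)
                            * rng.standard_normal())
        prop = clip(prop)
        pen = penalty(prop)
        if pen < cur_pen or rng.random() < math.exp(
                min((cur_pen - pen) / max(temp, 1e-12), 0.0)):
            cur_x, cur_pen = prop, pen
        if pen < best_pen:
            best_x, best_pen = list(prop), pen
            log.append((it, pen))
        if best_pen == 0.0:
            break

    params = _apply(base, names, best_x)
    report = {"target": target, "family": family, "seed": seed,
              "evaluations": len(log), "geometry_penalty": best_pen}
    success = best_pen == 0.0
    if success and verify is not None:
        ok, vrep = verify(params)
        report["verification"] = vrep
        success = ok
    return TuneResult(success, params, best_pen, report, log)


def getattr_nested(params, name):
    """Read a tuner scalar back out of a parameter object via with_ naming."""
    try:
        return float(getattr(params, name))
    except AttributeError:
        pass
    if name.startswith(("M_", "delta_")):
        which, curve = name.split("_")
        spec = getattr(params, "f" + curve, None) \
            or getattr(params, "curve_" + curve)
        return float(getattr(spec, "M" if which == "M" else "delta"))
    if name == "S":
        return float(params.g.S)
    if name == "theta_v":
        return float(params.g.theta_v)
    if name.endswith(("_v", "_n")):
        return float(getattr(getattr(params, "curve_" + name[-1]),
                             name[:-2]))
    raise KeyError(name)
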