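"""f-I curves, Hodgkin excitability classification, graded responses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..common import StimulusProtocol, spike_times
from .equilibria import find_equilibria

__all__ = ["FICurve", "fi_curve", "classify_excitability",
           "graded_response_test", "graded_spread", "dominant_frequency"]

TRANSIENT_FRACTION = 0.5  # first half of every steady-state run is discarded


@dataclass
class FICurve:
    I: np.ndarray
    f: np.ndarray  # sustained rate in Hz, from the last half of each run
    direction: str

    def onset_current(self):
        nz = np.nonzero(self.f > 0)[0]
        return float(self.I[nz[0]]) if nz.size else None

    def min_nonzero_rate(self):
        nz = self.f[self.f > 0]
        return float(nz.min()) if nz.size else None

    def plateau_rate(self):
        return float(self.f.max())


def _rest_state(model, I):
    eqs = [e for e in find_equilibria(model, I) if e.stable]
    if eqs:
        return (eqs[0].v, eqs[0].w)
    lo, hi = model.v_range
    vmid = 0.5 * (lo + hi)
    return (vmid, float(model.wnull(vmid)))


def fi_curve(model, I_values, T: float = 1.0, dt: float | None = None,
             direction: str = "up") -> FICurve:
    """Sustained firing rate vs stimulus, swept with state continuation.

    The state is carried from one stimulus level to the next (warm start),
    so a down sweep follows the spiking branch through a bistable window and
    the up/down pair exposes onset hysteresis.
    """
    I_values = np.sort(np.asarray(I_values, dtype=float))
    order = I_values if direction == "up" else I_values[::-1]
    state = _rest_state(model, order[0])
    rates = {}
    for I in order:
        traj = model.simulate(state[0], state[1],
                              StimulusProtocol.constant(I), T, dt=dt)
        state = (float(traj.states[-1, 0]), float(traj.states[-1, 1]))
        t0 = traj.t[-1] * TRANSIENT_FRACTION
        spk = spike_times(traj.t, traj.v, model.spike_threshold)
        spk = spk[spk >= t0]
        rates[float(I)] = (spk.size - 1) / (spk[-1] - spk[0]) \
            if spk.size >= 2 else 0.0
    f = np.array([rates[float(I)] for I in I_values])
    return FICurve(I_values, f, direction)


def classify_excitability(fi_up: FICurve, fi_down: FICurve | None = None,
                          onset_fraction: float = 0.1):
    """Hodgkin Class I vs Class II from the shape of the f-I curve.

    Class I: the sustained rate can be made arbitrarily small near onset
    (here: the minimum nonzero rate is below ``onset_fraction`` of the
    plateau rate). Class II: spiking starts/stops at a nonzero rate.
    Returns (label, report); the report includes onset hysteresis when a
    down sweep is supplied.
    """
    if not np.any(fi_up.f > 0):
        raise RuntimeError("range below threshold: no spiking anywhere")
    plateau = fi_up.plateau_rate()
    min_rate = fi_up.min_nonzero_rate()
    if fi_down is not None and np.any(fi_down.f > 0):
        min_rate = min(min_rate, fi_down.min_nonzero_rate())
    label = "class1" if min_rate < onset_fraction * plateau else "class2"
    report = {"min_nonzero_rate": min_rate, "plateau_rate": plateau,
              "onset_ratio": min_rate / plateau,
              "onset_current_up": fi_up.onset_current()}
    if fi_down is not None:
        nz = np.nonzero(fi_down.f > 0)[0]
        off = float(fi_down.I[nz[0]]) if nz.size else None
        report["onset_current_down"] = off
        if off is not None and report["onset_current_up"] is not None:
            report["hysteresis"] = report["onset_current_up"] - off
    return label, report


def graded_response_test(model, amplitudes, width: float,
                         I_base: float = 0.0, T_after: float | None = None,
                         dt: float | None = None):
    """Peak membrane excursion after a brief pulse, per pulse amplitude."""
    amplitudes = list(amplitudes)
    if any(b < a for a, b in zip(amplitudes, amplitudes[1:])):
        raise ValueError("amplitudes must be sorted ascending")
    v0, w0 = _rest_state(model, I_base)
    dt_eff = model.dt if dt is None else dt
    T_after = 200.0 * width if T_after is None else T_after
    T = width + T_after
    out = []
    for amp in amplitudes:
        stim = StimulusProtocol(((0.0, width, I_base + amp),
                                 (width, T, I_base)))
        traj = model.simulate(v0, w0, stim, T, dt=dt_eff)
        out.append((float(amp), float(traj.v.max())))
    return out


def graded_spread(results, spike_threshold: float) -> float:
    """(max - min)/median of the suprathreshold peaks; 0 if fewer than two."""
    peaks = np.array([pk for _, pk in results if pk > spike_threshold])
    if peaks.size < 2:
        return 0.0
    med = float(np.median(peaks))
    return float((peaks.max() - peaks.min()) / abs(med)) if med != 0 else 0.0


def dominant_frequency(traj, t0: float = 0.0) -> float:
    """Fundamental frequency of v(t) for t >= t0 via FFT peak with
    parabolic interpolation (cross-check for ISI-based rates)."""
    mask = traj.t >= t0
    v = traj.v[mask]
    v = v - v.mean()
    w = np.hanning(v.size)
    spec = np.abs(np.fft.rfft(v * w))
    freqs = np.fft.rfftfreq(v.size, traj.dt)
    k = int(np.argmax(spec[1:]) + 1)
    if 1 <= k < spec.size - 1:
        a, b, c = spec[k - 1], spec[k], spec[k + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    return float((k + shift) * (freqs[1] - freqs[0]))
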