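"""Burst segmentation and the slow-nullcline-position regime sweep."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..analog import AnalogSNState, integrate_analog
from ..common import SpikeTrain, StimulusProtocol

__all__ = ["Burst", "BurstSequence", "segment_bursts",
           "spikes_per_burst_sweep", "RegimePoint"]

GAP_FACTOR = 3.0  # an ISI > GAP_FACTOR * median ISI opens a new burst
MAX_PERIOD = 6    # longest spike-count periodicity searched for


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    count: int


@dataclass
class BurstSequence:
    bursts: list
    gaps: list  # interburst gap durations, len = len(bursts) - 1

    @property
    def counts(self):
        return [b.count for b in self.bursts]

    def __len__(self):
        return len(self.bursts)


def segment_bursts(train: SpikeTrain, gap_factor: float = GAP_FACTOR
                   ) -> BurstSequence:
    """Split a spike train into bursts at ISIs > gap_factor * median ISI."""
    t = np.asarray(train.times, dtype=float)
    if t.size == 0:
        return BurstSequence([], [])
    if t.size == 1:
        return BurstSequence([Burst(t[0], t[0], 1)], [])
    isis = np.diff(t)
    cut = gap_factor * float(np.median(isis))
    breaks = np.nonzero(isis > cut)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    bursts = [Burst(float(t[a]), float(t[b]), int(b - a + 1))
              for a, b in zip(starts, ends)]
    gaps = [bursts[i + 1].start - bursts[i].end
            for i in range(len(bursts) - 1)]
    return BurstSequence(bursts, gaps)


def classify_count_sequence(counts, min_chaotic: int = 40):
    """'tonic' (single burst), 'periodic-k', or 'aperiodic' (chaos candidate)."""
    counts = list(counts)
    if len(counts) <= 1:
        return "tonic"
    tail = counts[-min(len(counts), 24):]
    for k in range(1, MAX_PERIOD + 1):
        if len(tail) >= 2 * k and all(
                tail[i] == tail[i + k] for i in range(len(tail) - k)):
            return f"periodic-{k}"
    if len(counts) >= min_chaotic:
        return "aperiodic"
    return "indeterminate"


@dataclass
class RegimePoint:
    value: float
    counts: list
    label: str


def _burst_counts(p, s0, T, dt, threshold, gap_factor):
    traj = integrate_analog(p, s0, StimulusProtocol.none(), dt=dt, T=T)
    t0 = T * 0.5
    train = traj.spike_train(threshold)
    spk = train.times[train.times >= t0]
    seq = segment_bursts(SpikeTrain(spk), gap_factor)
    counts = seq.counts
    if len(counts) > 2:
        counts = counts[1:-1]  # clip possibly partial edge bursts
    end = AnalogSNState(*traj.states[-1])
    return counts, end, traj


def spikes_per_burst_sweep(params, M_q_values, T: float, dt: float,
                           spike_threshold: float,
                           gap_factor: float = GAP_FACTOR,
                           min_chaotic_bursts: int = 40,
                           perturbation: float = 1e-9,
                           lone_spike_isi: float | None = None,
                           s0: AnalogSNState | None = None):
    """Sweep the slow-current amplitude M_q of the three-variable model and
    label each sample tonic / periodic-k / chaotic.

    Chaos is certified only when the spike-count-per-burst sequence is
    aperiodic over >= ``min_chaotic_bursts`` bursts AND two runs whose
    initial v differ by ``perturbation`` decorrelate (their count sequences
    diverge).

    Single-spike bursting produces uniform ISIs that gap segmentation
    cannot split; when a run yields one "burst" whose median ISI exceeds
    ``lone_spike_isi``, every spike is counted as its own burst.
    """
    out = []
    state = s0 if s0 is not None else AnalogSNState(-0.1, 0.0, 0.0)
    for val in np.asarray(M_q_values, dtype=float):
        p = params.with_(M_q=float(val))
        counts, end, traj = _burst_counts(p, state, T, dt, spike_threshold,
                                          gap_factor)
        state = end  # warm start the next sample
        if (lone_spike_isi is not None and len(counts) == 1
                and counts[0] > 1):
            spk = traj.spike_train(spike_threshold)
            isis = spk.isis()
            if isis.size and float(np.median(isis)) > lone_spike_isi:
                counts = [1] * counts[0]
        label = classify_count_sequence(counts, min_chaotic_bursts)
        if label == "aperiodic":
            s_pert = AnalogSNState(end.v + perturbation, end.n, end.q)
            c1, _, _ = _burst_counts(p, end, T, dt, spike_threshold,
                                     gap_factor)
            c2, _, _ = _burst_counts(p, s_pert, T, dt, spike_threshold,
                                     gap_factor)
            m = min(len(c1), len(c2))
            decorrelated = m > 0 and c1[:m] != c2[:m]
            label = "chaotic" if decorrelated else "indeterminate"
        out.append(RegimePoint(float(val), counts, label))
    return out
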