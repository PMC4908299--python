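"""Shared domain types: thermal constants, stimulus protocols, trajectories.

All quantities are SI internally (volts, amps, seconds, farads). The digital
model is dimensionless except for time, which is in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThermalConstants",
    "StimulusProtocol",
    "Trajectory",
    "SpikeTrain",
    "spike_times",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when a trajectory exceeds the configured divergence bound."""

    def __init__(self, t_blow: float):
        self.t_blow = t_blow
        super().__init__(f"numerical blow-up at t = {t_blow:.6g} s")


@dataclass(frozen=True)
class ThermalConstants:
    """Subthreshold MOSFET constants.

    U_T is the thermal voltage (~26 mV at room temperature); kappa the
    capacitive-coupling ratio (~0.7 for typical processes).
    """

    U_T: float = 0.026
    kappa: float = 0.7

    def __post_init__(self):
        if not (self.U_T > 0):
            raise ValueError("U_T must be positive")
        if not (0 < self.kappa <= 1):
            raise ValueError("kappa must be in (0, 1]")

    @property
    def kou(self) -> float:
        """kappa / U_T, the exponential slope factor in 1/V."""
        return self.kappa / self.U_T


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant stimulus current: ordered (t0, t1, amplitude).

    The current is zero outside all segments. Segments must be ordered and
    non-overlapping.
    """

    segments: tuple = ()

    def __post_init__(self):
        segs = tuple((float(a), float(b), float(c)) for a, b, c in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = -math.inf
        for t0, t1, _amp in segs:
            if t1 < t0:
                raise ValueError(f"segment end {t1} before start {t0}")
            if t0 < prev_end:
                raise ValueError("stimulus segments overlap or are unordered")
            prev_end = t1

    @classmethod
    def constant(cls, amplitude: float, t1: float = 1e9) -> "StimulusProtocol":
        return cls(((0.0, t1, amplitude),))

    @classmethod
    def pulse(cls, t0: float, width: float, amplitude: float) -> "StimulusProtocol":
        return cls(((t0, t0 + width, amplitude),))

    @classmethod
    def none(cls) -> "StimulusProtocol":
        return cls(())

    def amplitude(self, t: float) -> float:
        for t0, t1, amp in self.segments:
            if t0 <= t < t1:
                return amp
        return 0.0

    def arrays(self):
        """(t0[], t1[], amp[]) float64 arrays for the compiled integrators."""
        if not self.segments:
            z = np.zeros(0)
            return z, z.copy(), z.copy()
        a = np.asarray(self.segments, dtype=float)
        return (np.ascontiguousarray(a[:, 0]), np.ascontiguousarray(a[:, 1]),
                np.ascontiguousarray(a[:, 2]))


@dataclass
class Trajectory:
    """Uniformly sampled state trace: t plus one column per state variable."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), n_vars)
    columns: tuple
    dt: float
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def v(self) -> np.ndarray:
        return self["v"]

    def to_csv(self, path) -> None:
        header = "t," + ",".join(self.columns)
        data = np.column_stack([self.t, self.states])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.17g")

    def spike_train(self, threshold: float) -> "SpikeTrain":
        return SpikeTrain(spike_times(self.t, self.v, threshold))


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times in seconds."""

    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    def __len__(self):
        return self.times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def rate(self, t0: float | None = None) -> float:
        """Mean firing rate (Hz) from spikes at times >= t0; 0 if < 2 spikes."""
        t = self.times if t0 is None else self.times[self.times >= t0]
        if t.size < 2:
            return 0.0
        return (t.size - 1) / (t[-1] - t[0])


def spike_times(t: np.ndarray, v: np.ndarray, threshold: float) -> np.ndarray:
    """Upward threshold crossings, linearly interpolated between samples."""
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.zeros(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])
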