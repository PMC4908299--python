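"""Silicon synapse kinetics, synaptic accumulation, and plasticity rules.

The kinetic synapse charges toward 1 while the presynaptic membrane is
suprathreshold and decays otherwise:

    dI_s/dt = alpha (1 - I_s)   if v_pre >= 0
            = -beta I_s         if v_pre <  0

Postsynaptic drive is accumulated as I_stim_j = I_ext_j + c sum_i W_ji I_s_i.
Spike-timing-dependent weight changes follow the exponential-difference rule

    dW = A_+ exp(-|dt|/tau_+) - A_- exp(-|dt|/tau_-)

which is Mexican-hat shaped (potentiation at small |dt|, depression beyond)
when A_+ > A_- and tau_+ < tau_-. Hopfield-style correlation learning over
+-1 patterns is provided as the non-plastic storage alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = ["SynapseParams", "SynapseState", "STDPParams", "WeightMatrix",
           "synapse_step", "accumulate", "stdp_delta", "stdp_zero_crossing",
           "nearest_pair_deltas", "correlation_weights", "stdp_training",
           "StdpNonTermination"]


@dataclass(frozen=True)
class SynapseParams:
    alpha: float  # rise rate, 1/s
    beta: float   # decay rate, 1/s

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass(frozen=True)
class SynapseState:
    I_s: float = 0.0


@dataclass(frozen=True)
class STDPParams:
    A_plus: float
    A_minus: float
    tau_plus: float
    tau_minus: float

    def __post_init__(self):
        if min(self.A_plus, self.A_minus, self.tau_plus, self.tau_minus) <= 0:
            raise ValueError("all STDP parameters must be positive")
        if not (self.A_plus > self.A_minus and self.tau_plus < self.tau_minus):
            warnings.warn("parameters do not give a Mexican-hat curve "
                          "(need A_plus > A_minus and tau_plus < tau_minus)",
                          stacklevel=2)


@dataclass
class WeightMatrix:
    """All-to-all weights, W[j, i] = weight from presynaptic i to post j."""

    W: np.ndarray
    c: float = 1.0  # accumulator scaling, stored alongside

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if np.any(np.abs(self.W) > 1.0 + 1e-12):
            raise ValueError("weights must lie in [-1, 1]")
        if np.any(np.diag(self.W) != 0.0):
            raise ValueError("self-connections must be zero")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.W, delimiter=",", header="W", comments="",
                   fmt="%.17g")

    @classmethod
    def from_csv(cls, path, c: float = 1.0) -> "WeightMatrix":
        return cls(np.loadtxt(path, delimiter=",", skiprows=1), c)


def synapse_step(s: SynapseState, p: SynapseParams, v_pre: float,
                 dt: float) -> SynapseState:
    """Forward-Euler update of the kinetic synapse, clipped to [0, 1]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt * max(p.alpha, p.beta) >= 1.0:
        raise ValueError("unstable step: require dt*max(alpha, beta) < 1")
    if v_pre >= 0.0:
        val = s.I_s + dt * p.alpha * (1.0 - s.I_s)
    else:
        val = s.I_s - dt * p.beta * s.I_s
    return SynapseState(min(max(val, 0.0), 1.0))


def accumulate(W: WeightMatrix, I_s_vec, I_ext_vec) -> np.ndarray:
    """I_stim_j = I_ext_j + c * sum_i W_ji I_s_i."""
    I_s = np.asarray(I_s_vec, dtype=float)
    I_ext = np.asarray(I_ext_vec, dtype=float)
    if I_s.shape != (W.n,) or I_ext.shape != (W.n,):
        raise ValueError("dimension mismatch")
    return I_ext + W.c * (W.W @ I_s)


def stdp_delta(p: STDPParams, delta_t: float) -> float:
    """Weight change for a spike-pair time difference; even in delta_t."""
    a = abs(delta_t)
    return (p.A_plus * math.exp(-a / p.tau_plus)
            - p.A_minus * math.exp(-a / p.tau_minus))


def stdp_zero_crossing(p: STDPParams) -> float:
    """|dt| where the Mexican-hat curve changes sign:
    t* = ln(A_+/A_-) / (1/tau_+ - 1/tau_-)."""
    return math.log(p.A_plus / p.A_minus) / (1.0 / p.tau_plus
                                             - 1.0 / p.tau_minus)


def nearest_pair_deltas(train_j, train_i) -> np.ndarray:
    """Signed dt_ji = t_j - t_i to the nearest spike of i, per spike of j."""
    tj = np.asarray(getattr(train_j, "times", train_j), dtype=float)
    ti = np.asarray(getattr(train_i, "times", train_i), dtype=float)
    if tj.size == 0 or ti.size == 0:
        return np.zeros(0)
    pos = np.searchsorted(ti, tj)
    left = np.clip(pos - 1, 0, ti.size - 1)
    right = np.clip(pos, 0, ti.size - 1)
    d_left = tj - ti[left]
    d_right = tj - ti[right]
    return np.where(np.abs(d_left) <= np.abs(d_right), d_left, d_right)


def correlation_weights(patterns) -> WeightMatrix:
    """W_ij = (1/P) sum_u x_i^u x_j^u off-diagonal, 0 on the diagonal.

    The canonical stored count is P = 4, for which entries fall in
    {-1, -0.5, 0, 0.5, 1}; other counts use the same 1/P scaling.
    """
    X = np.asarray([getattr(p, "values", p) for p in patterns], dtype=float)
    if X.ndim != 2:
        raise ValueError("patterns must share a common length")
    if not np.all(np.abs(X) == 1.0):
        raise ValueError("pattern entries must be +-1")
    P = X.shape[0]
    W = (X.T @ X) / P
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W)


class StdpNonTermination(RuntimeError):
    def __init__(self, budget, max_abs_w):
        self.max_abs_w = max_abs_w
        super().__init__(
            f"no weight reached +-1 within {budget} presentations "
            f"(max |W| = {max_abs_w:.3f})")


def default_schedule(n_patterns: int, reps: int = 8):
    """Yield (pattern index, inverted?) cyclically: (1),(1bar) x reps,
    (2),(2bar) x reps, ... restarting after the last pattern."""
    while True:
        for u in range(n_patterns):
            for _ in range(reps):
                yield (u, False)
                yield (u, True)


def stdp_training(runner, patterns, p: STDPParams, seed: int,
                  schedule=None, max_presentations: int = 2000,
                  c: float = 1.0):
    """Train all-to-all weights by presenting patterns through ``runner``.

    ``runner(W, pattern, seed) -> list of spike-time arrays`` simulates one
    presentation on the current weights. After each presentation every
    ordered pair (j, i) receives sum_k dW(nearest dt) over postsynaptic
    spikes k, weights are clipped to [-1, 1], and training stops as soon as
    any |W_ji| reaches 1.

    Returns (WeightMatrix, log) where the log records per-presentation
    max |W| summaries.
    """
    n = len(patterns[0].values) if hasattr(patterns[0], "values") \
        else len(patterns[0])
    W = np.zeros((n, n))
    sched = schedule if schedule is not None else default_schedule(
        len(patterns))
    rng = np.random.default_rng(seed)
    log = []
    for pres, (u, inverted) in enumerate(sched):
        if pres >= max_presentations:
            raise StdpNonTermination(max_presentations,
                                     float(np.max(np.abs(W))))
        pat = patterns[u]
        vec = np.asarray(getattr(pat, "values", pat))
        if inverted:
            vec = -vec
        trains = runner(WeightMatrix(W.copy(), c), vec,
                        int(rng.integers(2 ** 31)))
        dW = np.zeros_like(W)
        arrs = [np.asarray(getattr(tr, "times", tr), dtype=float)
                for tr in trains]
        offs = np.zeros(n + 1, dtype=np.int64)
        offs[1:] = np.cumsum([a.size for a in arrs])
        flat = np.concatenate(arrs) if offs[-1] else np.zeros(0)
        _kernels.stdp_pair_update(flat, offs, p.A_plus, p.A_minus,
                                  p.tau_plus, p.tau_minus, dW)
        W = np.clip(W + dW, -1.0, 1.0)
        np.fill_diagonal(W, 0.0)
        m = float(np.max(np.abs(W)))
        log.append({"presentation": pres, "pattern": u,
                    "inverted": inverted, "max_abs_w": m})
        if m >= 1.0:
            return WeightMatrix(W, c), log
    raise StdpNonTermination(max_presentations, float(np.max(np.abs(W))))
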