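"""All-to-all spiking associative memory on digital silicon neurons.

256 DSSN cells are coupled through kinetic synapses and a weighted
accumulator. Retrieval protocol: a brief positive pulse is applied to the
neurons whose input pixel is +1 (phase seeding), then a sustained stimulus
makes every neuron spike repetitively; the stored pattern closest to the
input is expressed as an anti-phase clustering of the spike phases.

Readouts are circular order parameters over the instantaneous spike phases
theta_j(t): the overlap index M_u = |mean_j x_j^u e^{i theta_j}| approaches
1 when the phase clustering matches stored pattern u, and the phase
synchronization index PSI = |mean_j e^{i theta_j}| measures global
coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .common import SpikeTrain
from .dssn import DSSNParams, NETWORK_DT
from .synapse import WeightMatrix

__all__ = ["RetrievalConfig", "RetrievalResult", "simulate_assoc_network",
           "spike_phases", "overlap_index", "psi", "error_sweep",
           "make_presentation_runner", "SilentNetworkError"]


class SilentNetworkError(RuntimeError):
    pass


@dataclass
class RetrievalConfig:
    """Protocol and coupling settings for one retrieval run."""

    params: DSSNParams
    mode: str = "class2"
    dt: float = NETWORK_DT
    T_total: float = 3.0
    I_ext: float = 0.1            # sustained drive to every neuron
    pulse_amp: float = 0.2        # extra drive to +1 pixels, phase seeding
    pulse_duration: float = 0.075
    alpha: float = 500.0          # synapse rise rate, 1/s
    beta: float = 50.0            # synapse decay rate, 1/s
    c: float = 0.002              # accumulator scaling
    theta_M: float = 0.8          # success threshold on the correct M_u
    theta_other: float = 0.5      # ceiling for all other overlaps
    v_init: float | None = None   # default: the rest state under I_ext, so
    n_init: float | None = None   # unpulsed neurons stay quiescent
    metric_stride: int = 20       # steps between metric samples
    min_defined_fraction: float = 0.2  # metric samples need this many phases
    metric_end_margin: float = 0.15  # s; phases need a next spike, so
    # samples this close to the end of the run are bracket-starved

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 < self.theta_M < 1.0:
            raise ValueError("theta_M must be in (0, 1)")


@dataclass
class RetrievalResult:
    t: np.ndarray            # metric sample times
    M: np.ndarray            # shape (n_patterns, len(t))
    psi: np.ndarray
    success: bool
    retrieved: int | None    # index into the stored patterns, or None
    anti_pattern: bool = False
    details: dict = field(default_factory=dict)


def spike_phases(trains, t: float):
    """Instantaneous phases theta_j(t) = 2*pi*(t - t_prev)/(t_next - t_prev).

    Returns (theta, mask); mask is False where t is not bracketed by two
    spikes of neuron j (those entries are excluded from the metrics).
    """
    n = len(trains)
    theta = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    for j, tr in enumerate(trains):
        ts = np.asarray(getattr(tr, "times", tr))
        if ts.size < 2:
            continue
        k = np.searchsorted(ts, t, side="right")
        if k == 0 or k >= ts.size:
            continue
        theta[j] = 2.0 * np.pi * (t - ts[k - 1]) / (ts[k] - ts[k - 1])
        mask[j] = True
    return theta, mask


def overlap_index(theta, pattern, mask=None) -> float:
    """M_u = |(1/N') sum_j x_j^u e^{i theta_j}| over unmasked neurons."""
    x = np.asarray(getattr(pattern, "values", pattern), dtype=float)
    if mask is None:
        mask = np.ones(x.size, dtype=bool)
    npr = int(np.count_nonzero(mask))
    if npr == 0:
        raise ValueError("no neuron has a defined phase")
    z = np.sum(x[mask] * np.exp(1j * np.asarray(theta)[mask])) / npr
    return float(np.abs(z))


def psi(theta, mask=None) -> float:
    """Kuramoto order parameter |(1/N') sum_j e^{i theta_j}|."""
    theta = np.asarray(theta)
    if mask is None:
        mask = np.ones(theta.size, dtype=bool)
    npr = int(np.count_nonzero(mask))
    if npr == 0:
        raise ValueError("no neuron has a defined phase")
    return float(np.abs(np.sum(np.exp(1j * theta[mask])) / npr))


def _rest_state(cfg: RetrievalConfig):
    """Quiescent state of one neuron under the sustained stimulus."""
    from .dssn import DSSNPlanar
    from .dynamics import find_equilibria
    if cfg.v_init is not None and cfg.n_init is not None:
        return cfg.v_init, cfg.n_init
    eqs = [e for e in find_equilibria(DSSNPlanar(cfg.params), cfg.I_ext)
           if e.stable]
    if not eqs:
        raise ValueError("no stable rest state under I_ext; "
                         "set v_init/n_init explicitly")
    return eqs[0].v, eqs[0].w


def _run_kernel(W: WeightMatrix, cfg: RetrievalConfig, pulse_mask,
                max_rate: float = 400.0):
    N = W.n
    nsteps = int(round(cfg.T_total / cfg.dt))
    maxspk = int(cfg.T_total * max_rate) + 16
    spike_t = np.zeros((N, maxspk))
    spike_cnt = np.zeros(N, dtype=np.int64)
    v0, n0 = _rest_state(cfg)
    i_blow = _kernels.run_assoc_network(
        cfg.params.as_array(), np.ascontiguousarray(W.W), cfg.c,
        np.full(N, cfg.I_ext), pulse_mask.astype(np.int64), cfg.pulse_amp,
        int(round(cfg.pulse_duration / cfg.dt)),
        np.full(N, float(v0)), np.full(N, float(n0)),
        cfg.alpha, cfg.beta, cfg.dt, nsteps, spike_t, spike_cnt, 16.0)
    if i_blow >= 0:
        raise RuntimeError(f"numerical blow-up at t={i_blow * cfg.dt:.4f} s")
    return [SpikeTrain(spike_t[j, :spike_cnt[j]]) for j in range(N)]


def simulate_assoc_network(W: WeightMatrix, patterns, input_pattern,
                           cfg: RetrievalConfig):
    """One retrieval run. Returns (spike trains, RetrievalResult).

    Success requires exactly the correct overlap to stay above theta_M over
    the final half of the run while every other overlap stays below
    theta_other. A clustering that matches a stored pattern with inverted
    sign structure (the +1 cluster of u aligned with the input's -1 cluster)
    is reported as anti_pattern, not success.
    """
    inp = np.asarray(getattr(input_pattern, "values", input_pattern))
    trains = _run_kernel(W, cfg, (inp == 1))
    t_sustained = cfg.pulse_duration
    if not any(np.any(tr.times > t_sustained) for tr in trains):
        raise SilentNetworkError("no spikes during the sustained phase")

    nsteps = int(round(cfg.T_total / cfg.dt))
    last = nsteps - int(round(cfg.metric_end_margin / cfg.dt))
    samples = np.arange(cfg.metric_stride, max(last, cfg.metric_stride + 1),
                        cfg.metric_stride) * cfg.dt
    P = len(patterns)
    N = inp.size
    M = np.full((P, samples.size), np.nan)
    psis = np.full(samples.size, np.nan)
    align = np.full((P, samples.size), np.nan)
    for k, t in enumerate(samples):
        theta, mask = spike_phases(trains, t)
        npr = int(np.count_nonzero(mask))
        if npr < cfg.min_defined_fraction * N:
            continue  # too few bracketed neurons for a meaningful sample
        for u, pat in enumerate(patterns):
            x = np.asarray(getattr(pat, "values", pat), dtype=float)
            z = np.sum(x[mask] * np.exp(1j * theta[mask]))
            M[u, k] = np.abs(z) / npr
            align[u, k] = float(np.sum(x[mask])) / npr
        psis[k] = np.abs(np.sum(np.exp(1j * theta[mask]))) / npr

    final = samples >= 0.5 * cfg.T_total
    valid = final & ~np.isnan(psis)
    success, retrieved, anti = False, None, False
    if valid.any():
        held = [u for u in range(P)
                if np.nanmin(M[u, valid]) > cfg.theta_M]
        if len(held) == 1:
            u = held[0]
            others_ok = all(np.nanmax(M[w, valid]) < cfg.theta_other
                            for w in range(P) if w != u)
            if others_ok:
                retrieved = u
                # active-set sign structure: positive mean alignment means
                # the +1 pixels of u carry the activity; negative means the
                # inverse pattern was expressed
                if float(np.nanmean(align[u, valid])) >= 0.0:
                    success = True
                else:
                    anti = True
    result = RetrievalResult(samples, M, psis, success, retrieved, anti)
    return trains, result


def error_sweep(stored, cfg: RetrievalConfig, error_levels,
                trials_per_level: int, seed: int,
                W: WeightMatrix | None = None) -> pd.DataFrame:
    """Success rate vs error level: per trial, flip a seeded fraction of a
    stored pattern's pixels and test whether exactly that pattern is
    retrieved."""
    from .patterns import flip_pixels
    from .synapse import correlation_weights
    if W is None:
        W = correlation_weights(stored)
        W.c = cfg.c
    ss = np.random.SeedSequence(seed)
    rows = []
    for level in error_levels:
        if not 0.0 <= level < 1.0 + 1e-12:
            raise ValueError("error levels must lie in [0, 1)")
        successes = 0
        for trial in range(trials_per_level):
            u = trial % len(stored)
            sub = np.random.SeedSequence(
                entropy=ss.entropy,
                spawn_key=(int(round(level * 1000)), trial))
            inp = flip_pixels(stored[u], level,
                              int(sub.generate_state(1)[0] % (2 ** 31)))
            _, res = simulate_assoc_network(W, stored, inp, cfg)
            successes += int(res.success and res.retrieved == u)
        rows.append({"error_level": float(level), "trials": trials_per_level,
                     "successes": successes,
                     "rate": successes / trials_per_level})
    return pd.DataFrame(rows)


def make_presentation_runner(cfg: RetrievalConfig, T_present: float = 0.5):
    """Runner for STDP training: one pattern presentation on the current
    weights, returning per-neuron spike-time arrays."""

    def runner(W: WeightMatrix, pattern_vec, seed: int):
        run_cfg = RetrievalConfig(**{**cfg.__dict__})
        run_cfg.T_total = T_present
        inp = np.asarray(getattr(pattern_vec, "values", pattern_vec))
        trains = _run_kernel(W, run_cfg, (inp == 1))
        return [tr.times for tr in trains]

    return runner
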