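"""Canned experiment assemblies: retrieval configs, STDP storage, sweeps.

These tie the preset parameter sets to the network protocols used in the
associative-memory studies, so scripts and tests run the same conditions.
"""

from __future__ import annotations

import numpy as np

from .network import RetrievalConfig, error_sweep, make_presentation_runner
from .presets_io import load_preset
from .synapse import STDPParams, WeightMatrix, correlation_weights, \
    stdp_training

__all__ = ["retrieval_config", "train_stdp_weights", "sweep_both_classes",
           "success_auc", "DEFAULT_ERROR_LEVELS", "DEFAULT_STDP"]

# error levels of the sweep protocol: 5..50% in 5% steps
DEFAULT_ERROR_LEVELS = [round(0.05 * k, 2) for k in range(1, 11)]

# Mexican-hat rule sized so that in-group (near-zero lag) pairs potentiate
# and cross-group (roughly half-period lag, ~25 ms nearest-pair) pairs
# depress by about the same magnitude, giving Hopfield-like weights with
# saturation after roughly one presentation cycle of 4 patterns
DEFAULT_STDP = STDPParams(A_plus=1e-3, A_minus=6.75e-4,
                          tau_plus=0.004, tau_minus=0.035)


def retrieval_config(mode: str = "class2", **overrides) -> RetrievalConfig:
    """Retrieval protocol for the class1/class2 network presets."""
    pre = load_preset(f"dssn_{mode}")
    net = dict(pre.network)
    net.update(overrides)
    return RetrievalConfig(params=pre.params, mode=mode,
                           I_ext=net["I_ext"], pulse_amp=net["pulse_amp"],
                           pulse_duration=net["pulse_duration"],
                           alpha=net["alpha"], beta=net["beta"],
                           c=net["c"], T_total=net["T_total"],
                           v_init=net.get("v_init"),
                           n_init=net.get("n_init"))


def train_stdp_weights(stored, cfg: RetrievalConfig, seed: int,
                       stdp: STDPParams = DEFAULT_STDP,
                       I_train: float | None = None,
                       T_present: float = 0.5,
                       max_presentations: int = 600):
    """Store patterns by spike-timing-dependent learning.

    Each presentation drives the whole network above the spiking onset
    (I_train, default just above the Hopf point) with the phase-seed pulse
    applied to the pattern's +1 pixels, so the two pixel groups spike with
    a half-cycle offset; the Mexican-hat rule then potentiates within-group
    pairs and depresses cross-group pairs. Presentations follow the
    pattern/anti-pattern block schedule and stop at the first weight
    saturation.
    """
    from .dssn import DSSNPlanar
    from .dynamics import find_equilibria
    train_cfg = RetrievalConfig(**{**cfg.__dict__})
    train_cfg.I_ext = I_train if I_train is not None else cfg.I_ext + 0.05
    train_cfg.pulse_amp = 1.6  # calibrated for a ~half-cycle group offset
    train_cfg.c = 0.0  # plasticity shapes W; coupling off while measuring
    # everyone starts from the zero-input rest; the sustained drive is
    # above the spiking onset so the whole network fires during training
    rest = [e for e in find_equilibria(DSSNPlanar(cfg.params), 0.0)
            if e.stable]
    if rest:
        train_cfg.v_init, train_cfg.n_init = rest[0].v, rest[0].w
    runner = make_presentation_runner(train_cfg, T_present=T_present)
    W, log = stdp_training(runner, stored, stdp, seed=seed,
                           max_presentations=max_presentations)
    W.c = cfg.c
    return W, log


def success_auc(table) -> float:
    """Area under the success-rate-vs-error-level curve (trapezoid)."""
    return float(np.trapezoid(table["rate"], table["error_level"]))


def sweep_both_classes(stored, error_levels, trials_per_level, seed,
                       **overrides):
    """Correlation-learning error sweep in class1 and class2 modes."""
    out = {}
    for mode in ("class1", "class2"):
        cfg = retrieval_config(mode, **overrides)
        W = correlation_weights(stored)
        W.c = cfg.c
        out[mode] = error_sweep(stored, cfg, error_levels,
                                trials_per_level, seed, W=W)
    return out
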