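# qsn — qualitative-modeling-based silicon neurons

Software implementations of three silicon-neuron dynamical systems and the
analysis machinery needed to configure and study them:

- a **three-variable analog model** built from subthreshold-MOSFET V–I
  curves (differential-pair sigmoids and a transconductance tanh) with two
  Tau-cell-integrated recovery currents — capable of Class I and Class II
  excitability and square-wave bursting;
- a **two-variable ultralow-power model** whose recovery variable enters
  through an invertible sigmoid `r(n)`, with an exactly equivalent
  transformed system in `(v, ñ = r(n))`;
- a **digital spiking silicon neuron (DSSN)**: a piecewise-quadratic planar
  model solved by forward Euler, optionally in emulated two's-complement
  fixed-point arithmetic (every multiply/add quantized);

plus a **dynamics toolkit** (equilibria and stability, bifurcation sweeps
with SNIC / saddle-loop / subcritical-Hopf / fold-of-cycles detection, f–I
curves and Hodgkin classification, burst segmentation, chaos certification,
a seeded mode tuner) and a **256-neuron all-to-all associative memory**
with kinetic synapses, correlation and spike-timing-dependent storage, and
circular order-parameter readouts (overlap index M_u and phase
synchronization index PSI).

The membrane models follow the qualitative-modeling idea: reproduce the
*dynamical structure* of a neuronal class (the arrangement of nullclines,
equilibria, and bifurcations) with circuit-native functions instead of
polynomials. For example the analog membrane equation is

    C_v dv/dt = −g(v) + f_m(v) − n − q + I_a + I_stim,
    f_x(v) = M_x / (1 + e^{−(κ/U_T)(v−δ_x)}),
    g(v)   = S (1 − e^{−a})/(1 + e^{−a}),  a = (κ/U_T)(v−θ_v)/(1+1/κ),

whose v-nullcline is N-shaped for suitable `M_m, S, θ_v < δ_m`, and the
DSSN is `dv/dt = (φ/τ)(f(v) − n + I_0 + I_stim)`, `dn/dt = (g(v) − n)/τ`
with piecewise-quadratic `f, g`. See `docs/methods.md` for the full model
descriptions, parameter conventions, and design choices.

## Worked example

Classify the shipped Class II preset and inspect its bifurcation
structure:

```python
import numpy as np
from qsn.presets_io import load_preset
from qsn.dynamics import (find_equilibria, fi_curve, classify_excitability,
                          sweep_bifurcation)

pre = load_preset("dssn_class2")
m = pre.planar()

print([(round(e.v, 3), e.label) for e in find_equilibria(m)])
# [(-0.3, 'stable_focus')]

up = fi_curve(m, pre.protocol["fi_grid"], T=3.0)
label, rep = classify_excitability(up)
print(label, round(rep["min_nonzero_rate"], 2), "Hz minimum")
# class2 16.75 Hz minimum

bd = sweep_bifurcation(m, "I_stim", prange=(0.02, 0.22), resolution=51,
                       T=3.0)
print([(e.type, np.round(e.interval, 3).tolist()) for e in bd.events])
# [('fold_of_cycles', [0.104, 0.108]), ('hopf', [0.124, 0.128])]
```

The single stable focus, the fold of limit cycles below a subcritical Hopf
point, and the ~16.8 Hz nonzero minimum rate are the Class II signature:
spiking starts and stops at a finite frequency, with a bistable window
between 0.108 and 0.124 where rest and spiking coexist.

Retrieve a stored pattern on the associative memory:

```python
from qsn.experiments import retrieval_config
from qsn.network import simulate_assoc_network
from qsn.patterns import generate_patterns, flip_pixels
from qsn.synapse import correlation_weights

stored = generate_patterns(256, 4, seed=2024)
W = correlation_weights(stored)
cfg = retrieval_config("class2")
W.c = cfg.c
noisy = flip_pixels(stored[0], 0.10, seed=99)   # 26 of 256 pixels flipped
trains, res = simulate_assoc_network(W, stored, noisy, cfg)
print(res.success, res.retrieved)
# True 0
```

The correct overlap index rises above 0.97 and holds for the rest of the
run while the other three stay below 0.15, with PSI near 1 — the network
recovers the stored pattern from the corrupted input.

A `qsn` command-line tool wraps the same library:
`qsn simulate`, `qsn nullclines`, `qsn bifurcate`, `qsn ficurve`,
`qsn tune`, `qsn assocmem`, `qsn selftest`.

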