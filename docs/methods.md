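# Methods

This note records the models this package implements, the choices made
where the design was genuinely open, the parameters that matter, and what
the shipped tests do and do not establish.

## The three neuron models

**Three-variable analog model** (`qsn.analog`). The membrane equation
balances a steep differential-pair sigmoid `f_m(v)` against a shallower
odd-symmetric transconductance curve `g(v)` and two recovery currents:

    C_v dv/dt = -g(v) + f_m(v) - n - q + I_a + I_stim
        dn/dt = (f_n(v) - n) / tau_n
        dq/dt = (f_q(v) - q) / tau_q

with `f_x(v) = M_x / (1 + exp(-(kappa/U_T)(v - delta_x)))` and
`g(v) = S tanh(a/2)`, `a = (kappa/U_T)(v - theta_v)/(1 + 1/kappa)`. The
`(1 + 1/kappa)` factor makes `g` wider than `f_m`, which is what lets their
difference form an N-shaped v-nullcline. `U_T = 26 mV` and `kappa = 0.7`
are the subthreshold-MOSFET thermal constants. `(v, n)` is the fast
spike-generation subsystem; `q` enters the membrane equation exactly like a
negative stimulus current, so all fast-subsystem analysis treats it as a
parameter. The v-nullcline is implemented as
`n = f_m - g - q + I_a + I_stim`; at `q = 0` this reduces to the
q-absorbed two-variable form. First-order recovery integration corresponds
to the Tau-cell current-mode integrator, whose ideal law
`dI_out/dt = (I_in - I_out)/(C U_T / I_tau)` is provided (and tested
against its exact exponential solution).

**Two-variable ultralow-power model** (`qsn.ulp`). Both state variables are
capacitor voltages; the recovery current enters through a strictly
increasing sigmoid `r(n)`, and the substitution `ntilde = r(n)` produces a
planar system whose nullclines are directly measurable:

    C_v dv/dt      = f_v(v) - g_v(v) + I_av - ntilde + I_stim
    C_n dntilde/dt = r'(n) (f_n(v) - g_n(v) + I_an - ntilde)

`r` is logistic, so `r'(r^-1(ntilde)) = (kappa/U_T) ntilde (P - ntilde)/P`
in closed form, with `P` the plateau `I_0P exp((kappa/U_T) theta_r)`; the
inverse is the logit, not a numerical solve. The raw and transformed
integration routes are both implemented and must agree (tested to
1e-6 of the plateau over 100 ms). `r` as printed upstream carries `v` in
its exponent although it is declared a function of `n`; it is implemented
as a function of `n`, which the transform requires. Capacitances default
to 1.5 pF and 2.0 pF. A structural constraint worth recording: the model is
globally well behaved only if the ntilde-nullcline stays below `P`
(`I_an + max f_n < P`), otherwise `n` runs away; the shipped preset
respects this with ~10% margin.

**Digital model (DSSN)** (`qsn.dssn`). Dimensionless piecewise-quadratic
planar model, `dv/dt = (phi/tau)(f(v) - n + I_0 + I_stim)`,
`dn/dt = (g(v) - n)/tau`, where `f` branches at `v = 0` and `g` at
`v = r_g`, each branch `a(v-b)^2 + c`. Branch continuity is enforced at
construction (residual <= 1e-9). Integration is forward Euler; in
fixed-point mode every multiply/add result is quantized to a two's
complement `Qm.n` format (truncation = floor; saturation by default), with
constant-times-variable products quantized once after the multiply, the way
a shift-add datapath would. The default format is 18 total / 10 fractional
bits — a typical FPGA word size, chosen here as a stand-in since no
hardware word length is claimed. Spikes are upward crossings of `v = 0`,
linearly interpolated.

## Mode presets

Parameter values realizing the neuronal classes are not published for any
of these circuits, so the presets shipped under `qsn/presets/` are this
package's own, produced from the design heuristics (steepen the rising
phase by raising `M_m`; steepen the falling phases by raising `S`; keep
`theta_v` below `delta_m`; place the slow nullcline between the resting
equilibrium and the limit cycle) plus seeded random search where geometry
alone was not decisive, and then verified with the toolkit's classify and
sweep operations. Each file records the search seed, the objective, and the
characterization numbers frozen on first measurement; tests assert against
those frozen numbers.

- `dssn_class1`: rest / saddle / unstable-focus structure; spiking begins
  through a saddle-node on invariant circle at `I ~= 0.2064`, with the
  measured period exponent -0.51 (theory: -1/2).
- `dssn_class2`: single stable focus near criticality; a fold of limit
  cycles (~0.106) and a subcritical Hopf (~0.126) bracket a bistable
  window; minimum sustained rate ~16.8 Hz; graded pulse responses with
  ~3x the Class I spread.
- `analog_square_wave`: the fast subsystem has a window of the slow
  current `q` (0.925–1.025 nA) with three equilibria in which a stable
  cycle coexists with rest, dying via a saddle loop ~15% into the window
  (period diverging logarithmically). `f_q` is centred at `delta_q = 0` so
  the burst trajectory charges `q` and the resting branch discharges it;
  `tau_q = 0.3 s` gives ~4 spikes per burst at `M_q = 4.5 nA`.
- `analog_class1`: the same curve family with `f_q` saturated well below
  the working range, pinning `q` at an effectively constant bias; SNIC
  onset under current sweep.
- `ulp_class2`: single near-critical stable focus destabilized by a Hopf
  near 0.7 nA, with graded peaks.

Regular spiking and elliptic bursting remain available as tuner targets
(`tune_mode`) but no preset is shipped for them, and no Class I preset is
shipped for the ultralow-power model: in that curve family the third
equilibrium could not be destabilized without violating the plateau
constraint above (the required ordering `s_n > s_v > (C_v/C_n) r'` closes
only in a narrow corner that the search did not reach). The mode tuner
itself is simulated annealing over box bounds on log- or linear-scaled
parameters with a geometry objective (equilibrium counts and labels,
N-shape, slow-nullcline placement) followed by dynamical verification; all
randomness is seeded.

## Dynamics toolkit conventions

Equilibria are roots of `vnull(v) - wnull(v)` bracketed on a 2001-point
grid and polished by Brent's method; stability labels come from the
analytic Jacobians (verified against centered differences). Continuation is
sweep-and-detect, not pseudo-arclength: limit cycles are found by forward
simulation warm-started from the neighbouring sample in both sweep
directions (which follows stable branches through bistable windows), and a
cycle is accepted when the last interspike intervals agree within 2%.
Events are classified from structural changes between adjacent samples;
a saddle-node is promoted to SNIC when the adjacent cycle period exceeds
10x the fastest cycle in the sweep, a Hopf is flagged subcritical when a
stable cycle coexists with the stable equilibrium beside the crossing, and
a cycle death is a saddle loop or a fold of cycles according to whether the
saddle persists. Steady-state measurements discard the first half of every
run. Burst segmentation cuts at interspike intervals exceeding 3x the
median; single-spike bursting produces uniform ISIs that gap segmentation
cannot split, so a run yielding one "burst" with median ISI above a
preset-recorded floor (50 ms) is counted as one-spike bursts. Chaos is only
certified when the spike-count sequence is aperiodic over at least 40
bursts *and* two runs differing by 1e-9 in initial `v` produce diverging
count sequences.

Integration defaults: fixed-step RK4 at 10 us for the analog model (1–2 us
for the fast sub-nanoamp presets), RK4 at 2 us for the ultralow-power
model, forward Euler at 375 us for the digital model and the network.
Divergence is declared at |v| > 10 V (16 in dimensionless units).

## Synapse, plasticity, and the associative memory

The kinetic synapse `dI_s/dt = alpha(1-I_s)` for `v >= 0`, `-beta I_s`
otherwise, is advanced by Euler at the network step and clipped to [0, 1].
Accumulation is `I_stim_j = I_ext_j + c sum_i W_ji I_s_i`. The
spike-timing rule `dW = A_+ e^{-|dt|/tau_+} - A_- e^{-|dt|/tau_-}` is
applied per postsynaptic spike using the nearest presynaptic spike
(signed `dt = t_j - t_i`; the rule is even in `dt`, so the pairing
direction is immaterial); weights are clipped to [-1, 1] and training
stops at the first saturated weight. Correlation storage uses
`W_ij = (1/P) sum_u x_i x_j` off-diagonal (1/4 for the canonical four
patterns).

The 256-neuron all-to-all network co-simulates digital neurons, synapses,
and the accumulator at dt = 375 us in double precision (the fixed-point
emulation is exercised in single-cell studies; the network reference runs
in floating point). Retrieval protocol: all neurons start at the rest state
under the sustained drive; a pulse is added to the +1-pixel neurons for
0.12 s; then the sustained stimulus alone continues. In the Class II
preset the drive (0.112) sits inside the bistable window, so each neuron
can persist either resting or spiking: recurrent excitation keeps (and
recruits) the neurons of the stored pattern closest to the input, and
recurrent inhibition silences the rest. A slow synapse decay
(beta = 10/s, roughly the interspike interval) is essential here — it
makes the recurrent inhibition quasi-DC; with fast decay the synchronized
volley of the active group resonantly rings the resting foci (which are
near-critical spirals) past threshold and the whole network ignites. The
retrieved state is therefore activity-coded: the active group is
internally synchronized (PSI near 1) and the complementary group is
silent, which maximizes the overlap index over the phase-defined neurons.

The overlap index and synchronization index are realized as circular order
parameters, `M_u = |mean_j x_j^u e^{i theta_j}|` and
`PSI = |mean_j e^{i theta_j}|`, over the neurons whose phase is defined at
the sample time (`theta_j` interpolates the position of `t` inside neuron
j's interspike interval). Samples where fewer than 20% of neurons have a
defined phase, or that lie within 0.15 s of the end of the run (where the
"next spike" needed by the phase definition is censored), are excluded;
without the end-margin the last few samples are dominated by a biased,
perfectly synchronized surviving subset and can spuriously reach 1.
Success means exactly the correct `M_u` stays above 0.8 over the final
half of the run while every other overlap stays below 0.5; an inverse
retrieval (the active set carrying the pattern's -1 pixels) is detected by
the sign of the mean pixel value over the active set and reported
separately, not counted as success.

In the Class I mode the drive (0.212) sits just above the SNIC point, so
silencing works (inhibition pushes a neuron below the saddle-node, where a
genuine rest state exists) but there is no bistability and the
near-onset rate depends steeply on input, dispersing the active group's
phases; retrieval is correspondingly much weaker than in Class II mode,
which is the expected ordering.

STDP storage presents patterns with the whole network driven above the
spiking onset (0.162) and a calibrated strong pulse (amplitude 1.6) that
offsets the two pixel groups by roughly half a cycle; with
`A_+ = 1e-3, A_- = 6.75e-4, tau_+ = 4 ms, tau_- = 35 ms` the in-group
(near-zero-lag) potentiation and cross-group (~25 ms nearest-pair lag)
depression have comparable magnitude, so the accumulated weights are
Hopfield-like and saturation arrives after a few presentation cycles of
the pattern/anti-pattern block schedule. Coupling is off during training
presentations (the groups hold their seeded offset because the neurons are
identical); plasticity alone shapes `W`.

## Synthetic patterns

The stored patterns of the original experiments exist only as figures, so
`generate_patterns` draws seeded random 16x16 ±1 patterns,
rejection-sampled to pairwise overlap at most 0.25 (four random patterns
of 256 pixels overlap by ~6% typically; the bound only rejects outliers).
Random patterns lack the spatial structure of glyph-like images, but for
an all-to-all network only the overlap statistics matter, and random
patterns with bounded overlap are the standard benchmark condition for
Hopfield-type storage at this loading (4/256 ~= 0.016). Success rates
measured here therefore characterize the mechanism, not any particular
pictograms.

## Problem sizes and numerical choices

Characterization and test runs use: f–I points simulated for 3–8 s with the
first half discarded; bifurcation sweeps of >= 50 samples at 3 s each; the
burst-regime sweep 14 s per slow-amplitude sample at dt = 2 us; retrieval
trials of 3–4 s at dt = 375 us with 10 trials per error level and 10
levels per class. The SNIC scaling exponent is fitted over stimulus
offsets 1e-5..1e-3 above a bifurcation point located by bisection on the
equilibrium count (locating it from the spiking onset instead biases the
fit badly, since the detection-limited onset overestimates the critical
current). The saddle-loop law is fitted as period vs log-distance to the
cycle-death point found by warm continuation at 1.25 pA resolution.

## Known limitations

- The design target that `dq/dt > 0` in >= 90% of in-burst samples is not
  met by the shipped square-wave preset (measured ~0.34; silence fraction
  ~0.94 passes). The burst limit cycle of this sigmoid/tanh
  curve family necessarily swings through deeply hyperpolarized voltages
  on every spike, below any monotone `f_q`'s midpoint, and the resting
  point sits *inside* the cycle's voltage range, so no placement of the
  q-nullcline can make the in-burst samples sign-definite while silence
  still discharges q. The slow current does charge monotonically on a
  cycle-averaged basis — burst alternation, the regime cascade, and the
  window hysteresis all behave as intended.
- Event detection is grid-based; a bifurcation between two samples is
  reported as an interval, and events closer together than the sample
  spacing can merge or shadow each other.
- Chaos certification by count-sequence decorrelation is a practical
  criterion, not a Lyapunov computation; regimes labelled `indeterminate`
  (aperiodic but not decorrelating within the run) occur near
  period-adding boundaries.
- The network runs in double precision; fixed-point effects on retrieval
  are not characterized.
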