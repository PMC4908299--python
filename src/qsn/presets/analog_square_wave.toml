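# Square-wave bursting mode of the three-variable analog silicon neuron.
# Found by seeded random search over the curve geometry with local
# annealing refinement (seed below): the fast (v, n) subsystem
# has a window of the slow current q with three equilibria where a stable
# limit cycle coexists with rest (cycle dies via a saddle-loop ~15% into the
# window); f_q is placed between the resting branch and the spiking region
# so that q alternately charges during bursts and discharges in silence.
# M_q is the burst-regime dial: ~<3.55 tonic, ~3.6 chaotic, then periodic
# bursting whose spikes-per-burst falls from ~7 to single-spike near 6.65.

[meta]
model = "analog"
mode = "square_wave"
seed = 7
objective = "STU window + in-window cycle + q-nullcline separation"

[params]
C_v = 2.0797e-12
I_a = 2.7959e-10
tau_n = 3.4810e-4
tau_q = 0.3
M_m = 5.2697e-9
delta_m = 0.0
M_n = 4.2337e-9
delta_n = 0.027005
M_q = 4.5e-9
delta_q = 0.0
S = 1.9674e-9
theta_v = -0.047759
U_T = 0.026
kappa = 0.7

[protocol]
dt = 1e-6
v_range = [-0.4, 0.45]
spike_threshold = 0.0
burst_T = 4.0
sweep_T = 14.0
q_init = 9.3e-10
mq_sweep = [3.53e-9, 3.5385e-9, 4.5e-9, 5.0e-9, 6.0e-9, 6.65e-9]
lone_spike_isi = 0.05

[analysis]
q_window = [9.25e-10, 1.025e-9]
q_homoclinic = 9.4e-10
spikes_per_burst_default = 4
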