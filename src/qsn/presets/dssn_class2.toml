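# Class II (subcritical Hopf) digital silicon neuron.
# Single stable focus at rest; a fold of limit cycles near I ~= 0.106 and a
# subcritical Hopf near I ~= 0.126 bracket a bistable window; spiking starts
# and stops at ~16.8 Hz (nonzero minimum frequency) and pulse responses are
# graded. The bistable window is also what the associative-memory network
# exploits: neurons inside it can be held either resting or spiking by the
# recurrent input.

[meta]
model = "dssn"
mode = "class2"
seed = 7
objective = "class2 geometry (single near-critical stable focus), verified by sweep + f-I"

[params]
phi = 0.5
tau = 0.01
I_0 = -0.69
a_fn = 4.0
b_fn = -0.5
c_fn = -1.0
a_fp = -4.0
b_fp = 0.5
c_fp = 1.0
a_gn = 3.0
b_gn = -1.0
c_gn = -3.0
a_gp = -3.0
b_gp = 1.0
c_gp = 3.0
r_g = 0.0

[protocol]
dt = 5e-5
v_range = [-1.2, 1.4]
spike_threshold = 0.0
fi_grid = [0.0, 0.03, 0.06, 0.09, 0.112, 0.13, 0.15, 0.167, 0.183, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45]
fi_T = 3.0
graded_width = 0.005
graded_amps = [1.0, 1.5, 2.0, 2.5, 3.0]
sweep_range = [0.02, 0.22]

[network]
I_ext = 0.112
pulse_amp = 0.4
pulse_duration = 0.12
alpha = 500.0
beta = 10.0
c = 0.002
T_total = 3.0

[analysis]
rest_v = -0.3
I_fold = 0.106
I_hopf = 0.126
min_rate = 16.75
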