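# Class I (saddle-node-on-invariant-circle) digital silicon neuron.
# Constructed from the Class I design geometry (rest on the falling branch
# of the N-shaped v-nullcline, saddle and unstable focus on the rising
# branch, n-nullcline flat below r_g and steep above) and verified with
# classify_excitability and the bifurcation sweep: SNIC at
# I_stim ~= 0.20643 with period ~ (I - I_c)^(-1/2).

[meta]
model = "dssn"
mode = "class1"
seed = 7
objective = "class1 geometry, verified by f-I onset ratio and SNIC scaling"

[params]
phi = 0.5
tau = 0.01
I_0 = -0.135
a_fn = 4.0
b_fn = -0.5
c_fn = -1.0
a_fp = -4.0
b_fp = 0.5
c_fp = 1.0
a_gn = 0.5
b_gn = -1.5
c_gn = -1.5
a_gp = 6.0
b_gp = -0.3
c_gp = -0.78
r_g = -0.3

[protocol]
dt = 5e-5
v_range = [-1.2, 1.4]
spike_threshold = 0.0
# f-I sweep bracketing the onset, with near-onset refinement points
fi_grid_coarse = [0.0, 0.1, 0.19]
fi_onset_offsets = [1e-4, 1e-3, 5e-3]
fi_grid_upper = [0.23, 0.26, 0.30, 0.34, 0.38, 0.42, 0.45]
fi_T = 8.0
graded_width = 0.005
graded_amps = [1.0, 1.5, 2.0, 2.5, 3.0]

[network]
# sustained drive just above the SNIC point: recurrent inhibition can push
# a neuron below it (silencing), excitation raises its rate; no bistability
I_ext = 0.212
pulse_amp = 0.4
pulse_duration = 0.12
alpha = 500.0
beta = 10.0
c = 0.002
T_total = 4.0
v_init = -0.6
n_init = -1.095

[analysis]
# frozen characterization (first run), asserted by tests within tolerances
I_snic = 0.20642784
rest_v = -0.6
saddle_v = -0.15
unstable_v = 0.124
snic_period_slope = -0.51
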