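# Class I mode of the three-variable analog silicon neuron.
# The slow current is pinned essentially constant (f_q saturated well below
# the working voltage range), so the cell reduces to its fast subsystem with
# a constant inhibitory bias; rest/saddle/unstable structure disappears via
# a saddle-node on invariant circle as I_stim increases, with the firing
# rate rising continuously from zero.

[meta]
model = "analog"
mode = "class1"
seed = 7
objective = "class1 geometry (STU at rest, SNIC onset)"

[params]
C_v = 2.0e-12
I_a = 1.0e-10
tau_n = 3.0e-4
tau_q = 0.01
M_m = 4.0e-9
delta_m = 0.0
M_n = 4.0e-9
delta_n = 0.04
M_q = 7.5e-10
delta_q = -0.3
S = 1.0e-9
theta_v = -0.03
U_T = 0.026
kappa = 0.7

[protocol]
dt = 2e-6
v_range = [-0.35, 0.42]
spike_threshold = 0.0
fi_T = 2.0

[analysis]
q_rest = 7.5e-10
q_window = [6.3e-10, 9.2e-10]
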