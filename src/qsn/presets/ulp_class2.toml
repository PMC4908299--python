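# Class II mode of the two-variable ultralow-power silicon nerve membrane.
# Single stable focus close to instability; increasing I_stim destabilizes
# it through a Hopf bifurcation, and pulse responses are graded. The g_n
# cascode branch is parked at its weak setting (R20 = 0.5, theta = 0), i.e.
# effectively off, so the ntilde-nullcline is the f_n sigmoid plus I_an.

[meta]
model = "ulp"
mode = "class2"
seed = 5
objective = "class2 geometry (single near-critical stable focus + Hopf)"

[params]
C_v = 1.5e-12
C_n = 2.0e-12
I_0P = 1e-12
I_av = 3.052e-9
I_an = 2.05e-10
M_v = 3.046e-9
delta_v = 0.525
Rv20 = 1.0
Rv21 = 1.0
theta_gv = 0.279
M_n = 4.695e-9
delta_n = 0.498
Rn20 = 0.5
Rn21 = 1.0
theta_gn = 0.0
theta_r = 0.319
U_T = 0.026
kappa = 0.7

[protocol]
dt = 2e-6
v_range = [0.05, 0.95]
spike_threshold = 0.5
fi_T = 0.3
graded_width = 0.0005

[analysis]
I_hopf_below = 7.5e-10
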