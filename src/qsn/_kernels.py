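"""Numba-compiled inner loops.

Everything here works on plain floats / contiguous float64 arrays so the
same code paths run compiled (numba) or interpreted (if numba is absent).
Parameter vectors use fixed layouts defined by the owning model modules.
"""

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

_EXP_CLIP = 700.0


@njit(cache=True)
def sigmoid_cur(M, delta, kou, v):
    """M / (1 + exp(-kou*(v - delta))), overflow-safe. kou = kappa/U_T."""
    t = -kou * (v - delta)
    if t > _EXP_CLIP:
        t = _EXP_CLIP
    elif t < -_EXP_CLIP:
        t = -_EXP_CLIP
    return M / (1.0 + math.exp(t))


@njit(cache=True)
def tanh_cur(S, theta, kou, kappa, v):
    # S*(1-e^-a)/(1+e^-a) with a = kou*(v-theta)/(1+1/kappa); equals S*tanh(a/2)
    a = kou * (v - theta) / (1.0 + 1.0 / kappa)
    return S * math.tanh(0.5 * a)


@njit(cache=True)
def stim_at(t, seg_t0, seg_t1, seg_amp):
    for k in range(seg_t0.size):
        if seg_t0[k] <= t < seg_t1[k]:
            return seg_amp[k]
    return 0.0


# ---------------------------------------------------------------- analog SN
# p layout: 0 C_v, 1 I_a, 2 tau_n, 3 tau_q, 4 M_m, 5 d_m, 6 M_n, 7 d_n,
#           8 M_q, 9 d_q, 10 S, 11 theta_v, 12 U_T, 13 kappa

@njit(cache=True)
def analog_rhs(p, v, n, q, I):
    kou = p[13] / p[12]
    fm = sigmoid_cur(p[4], p[5], kou, v)
    fn = sigmoid_cur(p[6], p[7], kou, v)
    fq = sigmoid_cur(p[8], p[9], kou, v)
    g = tanh_cur(p[10], p[11], kou, p[13], v)
    dv = (-g + fm - n - q + p[1] + I) / p[0]
    dn = (fn - n) / p[2]
    dq = (fq - q) / p[3]
    return dv, dn, dq


@njit(cache=True)
def integrate_analog(p, v0, n0, q0, seg_t0, seg_t1, seg_amp, dt, nsteps, vmax):
    """Fixed-step RK4 of the 3-variable model. Returns (out, i_blow).

    out has shape (nsteps+1, 3); i_blow is the first step index where
    |v| exceeded vmax, or -1.
    """
    out = np.empty((nsteps + 1, 3))
    v, n, q = v0, n0, q0
    out[0, 0] = v
    out[0, 1] = n
    out[0, 2] = q
    for i in range(nsteps):
        t = i * dt
        I1 = stim_at(t, seg_t0, seg_t1, seg_amp)
        Ih = stim_at(t + 0.5 * dt, seg_t0, seg_t1, seg_amp)
        I2 = stim_at(t + dt, seg_t0, seg_t1, seg_amp)
        k1v, k1n, k1q = analog_rhs(p, v, n, q, I1)
        k2v, k2n, k2q = analog_rhs(p, v + 0.5 * dt * k1v, n + 0.5 * dt * k1n,
                                   q + 0.5 * dt * k1q, Ih)
        k3v, k3n, k3q = analog_rhs(p, v + 0.5 * dt * k2v, n + 0.5 * dt * k2n,
                                   q + 0.5 * dt * k2q, Ih)
        k4v, k4n, k4q = analog_rhs(p, v + dt * k3v, n + dt * k3n,
                                   q + dt * k3q, I2)
        v += dt * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
        n += dt * (k1n + 2.0 * k2n + 2.0 * k3n + k4n) / 6.0
        q += dt * (k1q + 2.0 * k2q + 2.0 * k3q + k4q) / 6.0
        out[i + 1, 0] = v
        out[i + 1, 1] = n
        out[i + 1, 2] = q
        if abs(v) > vmax or not math.isfinite(v):
            return out, i + 1
    return out, -1


@njit(cache=True)
def integrate_analog_fast(p, q, v0, n0, seg_t0, seg_t1, seg_amp, dt, nsteps,
                          vmax):
    """RK4 of the fast (v, n) subsystem with q frozen as a parameter."""
    out = np.empty((nsteps + 1, 2))
    v, n = v0, n0
    out[0, 0] = v
    out[0, 1] = n
    for i in range(nsteps):
        t = i * dt
        I1 = stim_at(t, seg_t0, seg_t1, seg_amp)
        Ih = stim_at(t + 0.5 * dt, seg_t0, seg_t1, seg_amp)
        I2 = stim_at(t + dt, seg_t0, seg_t1, seg_amp)
        k1v, k1n, _ = analog_rhs(p, v, n, q, I1)
        k2v, k2n, _ = analog_rhs(p, v + 0.5 * dt * k1v, n + 0.5 * dt * k1n,
                                 q, Ih)
        k3v, k3n, _ = analog_rhs(p, v + 0.5 * dt * k2v, n + 0.5 * dt * k2n,
                                 q, Ih)
        k4v, k4n, _ = analog_rhs(p, v + dt * k3v, n + dt * k3n, q, I2)
        v += dt * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
        n += dt * (k1n + 2.0 * k2n + 2.0 * k3n + k4n) / 6.0
        out[i + 1, 0] = v
        out[i + 1, 1] = n
        if abs(v) > vmax or not math.isfinite(v):
            return out, i + 1
    return out, -1


# ------------------------------------------------------------------ ULP SN
# p layout: 0 C_v, 1 C_n, 2 I_av, 3 I_an, 4 I_0P,
#           5 M_v, 6 d_v, 7 Rv20, 8 Rv21, 9 th_v,
#           10 M_n, 11 d_n, 12 Rn20, 13 Rn21, 14 th_n,
#           15 theta_r, 16 U_T, 17 kappa

@njit(cache=True)
def ulp_g_cur(I0P, R20, R21, theta, kou, v):
    a = kou * theta
    if a > _EXP_CLIP:
        a = _EXP_CLIP
    A = I0P * R20 * math.exp(a)
    t = -kou * (v - theta)
    if t > _EXP_CLIP:
        t = _EXP_CLIP
    elif t < -_EXP_CLIP:
        t = -_EXP_CLIP
    return A / (1.0 + R21 * math.exp(t))


@njit(cache=True)
def ulp_r_cur(I0P, theta_r, kou, n):
    a = kou * theta_r
    if a > _EXP_CLIP:
        a = _EXP_CLIP
    P = I0P * math.exp(a)
    t = -kou * (n - theta_r)
    if t > _EXP_CLIP:
        t = _EXP_CLIP
    elif t < -_EXP_CLIP:
        t = -_EXP_CLIP
    return P / (1.0 + math.exp(t))


@njit(cache=True)
def ulp_rhs(p, v, n, I):
    kou = p[17] / p[16]
    fv = sigmoid_cur(p[5], p[6], kou, v)
    gv = ulp_g_cur(p[4], p[7], p[8], p[9], kou, v)
    fn = sigmoid_cur(p[10], p[11], kou, v)
    gn = ulp_g_cur(p[4], p[12], p[13], p[14], kou, v)
    r = ulp_r_cur(p[4], p[15], kou, n)
    dv = (fv - gv + p[2] - r + I) / p[0]
    dn = (fn - gn + p[3] - r) / p[1]
    return dv, dn


@njit(cache=True)
def ulp_rhs_tilde(p, v, nt, I):
    """Transformed system in (v, ntilde) with ntilde = r(n).

    r'(r^-1(nt)) has the closed form kou*nt*(P-nt)/P for the logistic r.
    """
    kou = p[17] / p[16]
    a = kou * p[15]
    if a > _EXP_CLIP:
        a = _EXP_CLIP
    P = p[4] * math.exp(a)
    fv = sigmoid_cur(p[5], p[6], kou, v)
    gv = ulp_g_cur(p[4], p[7], p[8], p[9], kou, v)
    fn = sigmoid_cur(p[10], p[11], kou, v)
    gn = ulp_g_cur(p[4], p[12], p[13], p[14], kou, v)
    rp = kou * nt * (P - nt) / P
    dv = (fv - gv + p[2] - nt + I) / p[0]
    dnt = rp * (fn - gn + p[3] - nt) / p[1]
    return dv, dnt


@njit(cache=True)
def integrate_ulp(p, v0, n0, seg_t0, seg_t1, seg_amp, dt, nsteps, vmax,
                  transformed):
    out = np.empty((nsteps + 1, 2))
    v, n = v0, n0
    out[0, 0] = v
    out[0, 1] = n
    for i in range(nsteps):
        t = i * dt
        I1 = stim_at(t, seg_t0, seg_t1, seg_amp)
        Ih = stim_at(t + 0.5 * dt, seg_t0, seg_t1, seg_amp)
        I2 = stim_at(t + dt, seg_t0, seg_t1, seg_amp)
        if transformed:
            k1v, k1n = ulp_rhs_tilde(p, v, n, I1)
            k2v, k2n = ulp_rhs_tilde(p, v + 0.5 * dt * k1v,
                                     n + 0.5 * dt * k1n, Ih)
            k3v, k3n = ulp_rhs_tilde(p, v + 0.5 * dt * k2v,
                                     n + 0.5 * dt * k2n, Ih)
            k4v, k4n = ulp_rhs_tilde(p, v + dt * k3v, n + dt * k3n, I2)
        else:
            k1v, k1n = ulp_rhs(p, v, n, I1)
            k2v, k2n = ulp_rhs(p, v + 0.5 * dt * k1v, n + 0.5 * dt * k1n, Ih)
            k3v, k3n = ulp_rhs(p, v + 0.5 * dt * k2v, n + 0.5 * dt * k2n, Ih)
            k4v, k4n = ulp_rhs(p, v + dt * k3v, n + dt * k3n, I2)
        v += dt * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
        n += dt * (k1n + 2.0 * k2n + 2.0 * k3n + k4n) / 6.0
        out[i + 1, 0] = v
        out[i + 1, 1] = n
        if abs(v) > vmax or not math.isfinite(v):
            return out, i + 1
    return out, -1


# -------------------------------------------------------------------- DSSN
# p layout: 0 phi, 1 tau, 2 I0, 3 afn, 4 bfn, 5 cfn, 6 afp, 7 bfp, 8 cfp,
#           9 agn, 10 bgn, 11 cgn, 12 agp, 13 bgp, 14 cgp, 15 rg

@njit(cache=True)
def dssn_f(p, v):
    if v < 0.0:
        t = v - p[4]
        return p[3] * t * t + p[5]
    t = v - p[7]
    return p[6] * t * t + p[8]


@njit(cache=True)
def dssn_g(p, v):
    if v < p[15]:
        t = v - p[10]
        return p[9] * t * t + p[11]
    t = v - p[13]
    return p[12] * t * t + p[14]


@njit(cache=True)
def dssn_rhs(p, v, n, I):
    dv = p[0] / p[1] * (dssn_f(p, v) - n + p[2] + I)
    dn = (dssn_g(p, v) - n) / p[1]
    return dv, dn


@njit(cache=True)
def fx_quant(x, scale, lo, hi, nearest):
    """Two's-complement fixed-point quantization with saturation.

    scale = 2**frac_bits; lo/hi are the representable extremes.
    Truncation is floor (two's-complement bit truncation), not round-to-zero.
    """
    y = x * scale
    if nearest:
        y = math.floor(y + 0.5)
    else:
        y = math.floor(y)
    y = y / scale
    if y < lo:
        return lo
    if y > hi:
        return hi
    return y


@njit(cache=True)
def dssn_euler_fx(p, v, n, I, dt, scale, lo, hi, nearest):
    """One fixed-point Euler step; every multiply/add result is quantized.

    Constant folding mirrors a shift-add datapath: kv = phi*dt/tau and
    kn = dt/tau are precomputed constants, themselves quantized.
    """
    kv = fx_quant(p[0] * dt / p[1], scale, lo, hi, nearest)
    kn = fx_quant(dt / p[1], scale, lo, hi, nearest)
    # f(v)
    if v < 0.0:
        t = fx_quant(v - fx_quant(p[4], scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
        t2 = fx_quant(t * t, scale, lo, hi, nearest)
        f = fx_quant(fx_quant(fx_quant(p[3], scale, lo, hi, nearest) * t2,
                              scale, lo, hi, nearest)
                     + fx_quant(p[5], scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
    else:
        t = fx_quant(v - fx_quant(p[7], scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
        t2 = fx_quant(t * t, scale, lo, hi, nearest)
        f = fx_quant(fx_quant(fx_quant(p[6], scale, lo, hi, nearest) * t2,
                              scale, lo, hi, nearest)
                     + fx_quant(p[8], scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
    # g(v)
    if v < p[15]:
        t = fx_quant(v - fx_quant(p[10], scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
        t2 = fx_quant(t * t, scale, lo, hi, nearest)
        g = fx_quant(fx_quant(fx_quant(p[9], scale, lo, hi, nearest) * t2,
                              scale, lo, hi, nearest)
                     + fx_quant(p[11], scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
    else:
        t = fx_quant(v - fx_quant(p[13], scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
        t2 = fx_quant(t * t, scale, lo, hi, nearest)
        g = fx_quant(fx_quant(fx_quant(p[12], scale, lo, hi, nearest) * t2,
                              scale, lo, hi, nearest)
                     + fx_quant(p[14], scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
    u = fx_quant(f - n, scale, lo, hi, nearest)
    u = fx_quant(u + fx_quant(p[2] + I, scale, lo, hi, nearest),
                 scale, lo, hi, nearest)
    v_new = fx_quant(v + fx_quant(kv * u, scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
    w = fx_quant(g - n, scale, lo, hi, nearest)
    n_new = fx_quant(n + fx_quant(kn * w, scale, lo, hi, nearest),
                     scale, lo, hi, nearest)
    return v_new, n_new


@njit(cache=True)
def integrate_dssn(p, v0, n0, seg_t0, seg_t1, seg_amp, dt, nsteps, vmax,
                   use_fx, scale, lo, hi, nearest):
    """Forward Euler, double precision or emulated fixed point."""
    out = np.empty((nsteps + 1, 2))
    v, n = v0, n0
    if use_fx:
        v = fx_quant(v, scale, lo, hi, nearest)
        n = fx_quant(n, scale, lo, hi, nearest)
    out[0, 0] = v
    out[0, 1] = n
    for i in range(nsteps):
        I = stim_at(i * dt, seg_t0, seg_t1, seg_amp)
        if use_fx:
            v, n = dssn_euler_fx(p, v, n, I, dt, scale, lo, hi, nearest)
        else:
            dv, dn = dssn_rhs(p, v, n, I)
            v = v + dt * dv
            n = n + dt * dn
        out[i + 1, 0] = v
        out[i + 1, 1] = n
        if abs(v) > vmax or not math.isfinite(v):
            return out, i + 1
    return out, -1


# ------------------------------------------------------------------ STDP
@njit(cache=True)
def stdp_pair_update(times, offs, Ap, Am, tp, tm, dW):
    """Accumulate the exponential-difference rule over nearest-neighbour
    spike pairs for every ordered (post j, pre i) pair.

    ``times`` concatenates all per-neuron sorted spike trains; neuron k owns
    times[offs[k]:offs[k+1]]. On ties the earlier presynaptic spike wins,
    matching nearest_pair_deltas.
    """
    N = offs.size - 1
    for j in range(N):
        j0, j1 = offs[j], offs[j + 1]
        if j1 == j0:
            continue
        for i in range(N):
            if i == j:
                continue
            i0, i1 = offs[i], offs[i + 1]
            if i1 == i0:
                continue
            s = 0.0
            for a in range(j0, j1):
                t = times[a]
                lo = i0
                hi = i1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if times[mid] < t:
                        lo = mid + 1
                    else:
                        hi = mid
                best = 1e300
                if lo < i1:
                    best = t - times[lo]
                if lo > i0:
                    d = t - times[lo - 1]
                    if abs(d) <= abs(best):
                        best = d
                ad = abs(best)
                s += Ap * math.exp(-ad / tp) - Am * math.exp(-ad / tm)
            dW[j, i] += s


# --------------------------------------------------------------- network
@njit(cache=True)
def run_assoc_network(p, W, c, Iext, pulse_mask, pulse_amp, pulse_steps,
                      v0, n0, alpha, beta, dt, nsteps,
                      spike_t, spike_cnt, vmax):
    """Co-simulate N DSSN neurons + kinetic synapses + accumulator.

    All neurons share the DSSN parameter vector p. The drive to neuron j is
    Iext[j] + c * sum_i W[j,i]*Is[i], plus pulse_amp during the first
    pulse_steps where pulse_mask is 1 (the seeding input that starts the
    +1-pixel neurons spiking).

    Spike times (upward v crossings of 0, linearly interpolated) are written
    into spike_t[j, :]; spike_cnt[j] holds per-neuron counts. Returns the
    step index of numerical blow-up or -1.
    """
    N = v0.size
    v = v0.copy()
    n = n0.copy()
    Is = np.zeros(N)
    maxspk = spike_t.shape[1]
    for i in range(nsteps):
        syn = c * np.dot(W, Is)
        for j in range(N):
            I = Iext[j] + syn[j]
            if i < pulse_steps and pulse_mask[j] == 1:
                I += pulse_amp
            dv, dn = dssn_rhs(p, v[j], n[j], I)
            v_new = v[j] + dt * dv
            n_new = n[j] + dt * dn
            if v[j] < 0.0 and v_new >= 0.0:
                k = spike_cnt[j]
                if k < maxspk:
                    frac = -v[j] / (v_new - v[j])
                    spike_t[j, k] = (i + frac) * dt
                    spike_cnt[j] = k + 1
            # synapse driven by the presynaptic membrane sign
            if v_new >= 0.0:
                Is[j] = Is[j] + dt * alpha * (1.0 - Is[j])
            else:
                Is[j] = Is[j] - dt * beta * Is[j]
            if Is[j] < 0.0:
                Is[j] = 0.0
            elif Is[j] > 1.0:
                Is[j] = 1.0
            if abs(v_new) > vmax or not math.isfinite(v_new):
                return i
            v[j] = v_new
            n[j] = n_new
    return -1
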