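"""Numba integration kernel for the recurrent inhibitory MSN network.

Fixed-step scheme: channel gates relax by exponential Euler against their
tabulated voltage-dependent steady states; the membrane potential advances
by RK4 within each step with gates and the recurrent synaptic conductance
held constant; the per-presynaptic-cell synaptic gating variable s follows
its exact exponential solution each step (opening toward a/(a+B) while the
presynaptic membrane is above 0 mV, decaying at rate B otherwise).  The
total inhibitory conductance onto each cell, sum_j G_syn[j->i] * s_j, is
refreshed by a sparse gather every ``syn_every`` steps (s varies on the
~12 ms IPSP timescale, far slower than the voltage step).

Spikes are upward crossings of 0 mV subject to a refractory lockout.
Status codes: 0 ok; >0 the 1-based step at which |V| exceeded 200 mV;
-2 spike buffer overflow (recording stopped, integration completed).
"""

import numpy as np
from numba import njit

__all__ = ["run_network"]


@njit(cache=True, inline="always")
def _interp(row, x):
    n = row.shape[0]
    if x <= 0.0:
        return row[0]
    if x >= n - 1:
        return row[n - 1]
    i = int(x)
    f = x - i
    return row[i] * (1.0 - f) + row[i + 1] * f


@njit(cache=True, inline="always")
def _dv(v, h, nn, b, a, g_ex, g_syn, P, tab, vmin, inv_dv):
    x = (v - vmin) * inv_dv
    minf = _interp(tab[0], x)
    kinf = _interp(tab[1], x)
    i_na = P[0] * minf * minf * minf * h * (v - P[1])
    i_k = P[2] * nn * nn * nn * nn * (v - P[3])
    i_kir = P[4] * kinf * (v - P[3])
    i_kas = P[5] * a * b * (v - P[3])
    i_l = P[6] * (v - P[7])
    i_ex = g_ex * (v - P[9])
    i_syn = g_syn * (v - P[8])
    return -(i_na + i_k + i_kir + i_kas + i_l + i_ex + i_syn)


@njit(cache=True)
def run_network(
    indptr, indices, weights,
    g_ex, s_dec0, s_dec1, s_inf,
    tab, vmin, inv_dv, P,
    dt, n_steps, syn_every, lockout_steps, record_start_step,
    V0, H0, N0, B0, A0, S0,
    max_spikes, vrec_idx, vrec_stride,
):
    nc = V0.shape[0]
    V = V0.copy()
    H = H0.copy()
    N = N0.copy()
    B = B0.copy()
    A = A0.copy()
    S = S0.copy()
    G = np.zeros(nc)
    last_spike = np.full(nc, -2 * lockout_steps, np.int64)

    sp_cell = np.empty(max_spikes, np.int64)
    sp_time = np.empty(max_spikes, np.float64)
    nsp = 0
    status = 0

    n_rec_t = (n_steps + vrec_stride - 1) // vrec_stride if vrec_idx.size else 1
    vrec = np.zeros((vrec_idx.shape[0], n_rec_t))

    half = 0.5 * dt
    sixth = dt / 6.0

    for step in range(n_steps):
        if step % syn_every == 0:
            for i in range(nc):
                acc = 0.0
                for k in range(indptr[i], indptr[i + 1]):
                    acc += weights[k] * S[indices[k]]
                G[i] = acc
        for i in range(nc):
            v = V[i]
            # synaptic gating of cell i as a presynaptic source
            if v > 0.0:
                S[i] = s_inf[i] + (S[i] - s_inf[i]) * s_dec1[i]
            else:
                S[i] = S[i] * s_dec0[i]
            # gate relaxation at the step-start voltage
            x = (v - vmin) * inv_dv
            hinf = _interp(tab[2], x)
            H[i] = hinf + (H[i] - hinf) * _interp(tab[3], x)
            ninf = _interp(tab[4], x)
            N[i] = ninf + (N[i] - ninf) * _interp(tab[5], x)
            binf = _interp(tab[6], x)
            B[i] = binf + (B[i] - binf) * _interp(tab[7], x)
            ainf = _interp(tab[8], x)
            A[i] = ainf + (A[i] - ainf) * _interp(tab[9], x)

            h = H[i]
            nn = N[i]
            b = B[i]
            a = A[i]
            ge = g_ex[i]
            gs = G[i]
            k1 = _dv(v, h, nn, b, a, ge, gs, P, tab, vmin, inv_dv)
            k2 = _dv(v + half * k1, h, nn, b, a, ge, gs, P, tab, vmin, inv_dv)
            k3 = _dv(v + half * k2, h, nn, b, a, ge, gs, P, tab, vmin, inv_dv)
            k4 = _dv(v + dt * k3, h, nn, b, a, ge, gs, P, tab, vmin, inv_dv)
            vn = v + sixth * (k1 + 2.0 * (k2 + k3) + k4)
            if np.abs(vn) > 200.0:
                status = step + 1
                return status, nsp, sp_cell, sp_time, V, H, N, B, A, vrec
            if v <= 0.0 and vn > 0.0 and step - last_spike[i] >= lockout_steps:
                last_spike[i] = step
                if step >= record_start_step:
                    if nsp < max_spikes:
                        sp_cell[nsp] = i
                        sp_time[nsp] = (step + 1) * dt
                        nsp += 1
                    else:
                        status = -2
            V[i] = vn
        if vrec_idx.size and step % vrec_stride == 0:
            j = step // vrec_stride
            for r in range(vrec_idx.shape[0]):
                vrec[r, j] = V[vrec_idx[r]]
    return status, nsp, sp_cell, sp_time, V, H, N, B, A, vrec
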