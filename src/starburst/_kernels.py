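"""Numba-compiled inner loops (bipolar RF recursion, branched-cable stepping).

These are private; the public API lives in :mod:`starburst.rf` and
:mod:`starburst.cable`.  Both kernels are strictly sequential in time, which
is why they are compiled rather than vectorized.
"""

import numba as nb
import numpy as np


@nb.njit(cache=True)
def bc_recursion(area_c, area_s, rise_c, decay_c, rise_s,
                 strength_s, reversal_s, amplitude, r_in):
    """Per-step center/surround/adaptation recursion for n cells in parallel.

    area_c, area_s : (T, n) stimulated-mass fractions per component.
    r_in : (n,) input-resistance term, 0.1 x total center mass in the arena.
    Returns (rf_center, adaptation, rf_surround, rf_full), each (T, n).

    Rise/decay constants are dimensionless per-step divisors; values below
    one are clipped to one to keep the update a stable low-pass.
    """
    T, n = area_c.shape
    rc = np.empty((T, n))
    ad = np.empty((T, n))
    rs = np.empty((T, n))
    full = np.empty((T, n))
    tr_c = max(rise_c, 1.0)
    td_c = max(decay_c, 1.0)
    tr_s = max(rise_s, 1.0)
    for i in range(n):
        rc_p = 0.0
        ad_p = 1.0
        rs_p = 0.0
        for t in range(T):
            rci = ((area_c[t, i] - rc_p) / tr_c + rc_p) * ad_p
            adi = ad_p - rci / td_c
            if adi < 0.0:
                adi = 0.0
            rsi = rs_p + (area_s[t, i] * strength_s - rs_p) / tr_s
            denom = rci + rsi + r_in[i]
            f = amplitude * (rci + rsi * reversal_s) / denom if denom > 0.0 else 0.0
            rc[t, i] = rci
            ad[t, i] = adi
            rs[t, i] = rsi
            full[t, i] = f
            rc_p, ad_p, rs_p = rci, adi, rsi
    return rc, ad, rs, full


@nb.njit(cache=True)
def cable_step(parent, g_ax, base_diag, c_over_dt, g_leak, e_rev,
               syn_comp, g_syn, dt_syn, e_syn,
               g_ca_max, m_tau, v_half, slope, e_ca,
               i_inj, t_inj_on, t_inj_off,
               ca_tau, ca_rest, ca_scale,
               dt, n_steps, rec_idx, rec_every, v0):
    """Backward-Euler integration of a branched passive cable with N-type
    calcium channels, synaptic conductances and a per-compartment calcium
    pool, solved per step by Hines (tree-ordered Gaussian) elimination.

    parent      : (n,) parent compartment index, parent[i] < i, root = -1.
    g_ax        : (n,) axial conductance to parent, uS (g_ax[0] unused).
    base_diag   : (n,) c/dt + leak + axial terms, uS.
    syn_comp    : (ns,) compartment index per synapse.
    g_syn       : (ns, Ts) conductance waveform per synapse, uS, sampled
                  every dt_syn ms (linearly interpolated onto solver steps).
    g_ca_max    : (n,) maximal CaN conductance per compartment, uS.
    i_inj       : (n,) current step amplitude, nA, on during [t_on, t_off).
    ca_scale    : (n,) nM of calcium per nA*ms of inward calcium current.
    Returns (v_rec, ca_rec) sampled every ``rec_every`` solver steps.
    """
    n = parent.shape[0]
    ns = syn_comp.shape[0]
    n_rec = rec_idx.shape[0]
    n_out = n_steps // rec_every + 1
    v_rec = np.empty((n_rec, n_out))
    ca_rec = np.empty((n_rec, n_out))

    v = np.full(n, v0)
    m = np.zeros(n)
    ca = np.full(n, ca_rest)
    d = np.empty(n)
    rhs = np.empty(n)
    a = np.empty(n)

    decay = np.exp(-dt / ca_tau)
    gain = ca_tau * (1.0 - decay)
    Ts = g_syn.shape[1]

    out = 0
    for i in range(n_rec):
        v_rec[i, 0] = v[rec_idx[i]]
        ca_rec[i, 0] = ca[rec_idx[i]]
    out = 1

    for step in range(1, n_steps + 1):
        t = step * dt
        # CaN activation gate (m^2 kinetics, first-order relaxation)
        for i in range(n):
            m_inf = 1.0 / (1.0 + np.exp(-(v[i] - v_half) / slope))
            m[i] += dt * (m_inf - m[i]) / m_tau

        for i in range(n):
            gca = g_ca_max[i] * m[i] * m[i]
            d[i] = base_diag[i] + gca
            rhs[i] = c_over_dt[i] * v[i] + g_leak[i] * e_rev + gca * e_ca
            a[i] = -g_ax[i]
        if t_inj_on <= t < t_inj_off:
            for i in range(n):
                rhs[i] += i_inj[i]
        # synaptic conductances, linearly interpolated from the drive grid
        if ns > 0:
            x = t / dt_syn
            k = int(x)
            if k >= Ts - 1:
                k = Ts - 2
            w = x - k
            if w < 0.0:
                w = 0.0
            if w > 1.0:
                w = 1.0
            for s in range(ns):
                gs = g_syn[s, k] * (1.0 - w) + g_syn[s, k + 1] * w
                c = syn_comp[s]
                d[c] += gs
                rhs[c] += gs * e_syn

        # Hines elimination: children have larger indices than parents
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = a[i] / d[i]
            d[p] -= f * a[i]
            rhs[p] -= f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] - a[i] * v[parent[i]]) / d[i]

        # calcium pool: first-order decay toward rest plus CaN influx
        for i in range(n):
            ica = g_ca_max[i] * m[i] * m[i] * (v[i] - e_ca)  # nA, negative inward
            influx = -ica if ica < 0.0 else 0.0
            drive = ca_scale[i] * influx  # nM/ms
            ca[i] = ca_rest + (ca[i] - ca_rest) * decay + drive * gain

        if step % rec_every == 0 and out < n_out:
            for i in range(n_rec):
                v_rec[i, out] = v[rec_idx[i]]
                ca_rec[i, out] = ca[rec_idx[i]]
            out += 1

    return v_rec, ca_rec
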