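"""Compiled inner loop of the network simulation.

One fixed-step pass over the whole network.  Scheme per step (staggered
exponential Euler, all in mV / ms / nS / pF / pA):

1. deliver spike-queue increments whose delay expires this step;
2. record clamp currents / drive at the recording stride;
3. advance the OU conductances of the E cells (exact discretization);
4. compute gap-junction sums from the current voltages;
5. update gates by exponential Euler at the current voltage, then update V
   by exponential Euler (the membrane equation is linear in V once the
   conductances and peer voltages are frozen);
6. decay synaptic states;
7. detect upward 0 mV crossings (1 ms detection refractory), record the
   linearly interpolated spike time, and enqueue each outgoing edge at
   ``step + 1 + round(delay/dt)`` so no postsynaptic change can precede the
   spike by less than the sampled delay.

Voltage-clamped readout cells are held at ``v_hold`` exactly and never
spike; only their synaptic conductances evolve and are read out.
"""

import math

import numpy as np
from numba import njit

__all__ = ["integrate_network"]


@njit(cache=True, inline="always")
def _linoid(u):
    if abs(u) < 1e-6:
        return 1.0 - u / 2.0 + u * u / 12.0
    return u / math.expm1(u)


@njit(cache=True, inline="always")
def _gate_exp_euler(x, a, b, dt):
    tot = a + b
    xinf = a / tot
    return xinf + (x - xinf) * np.exp(-dt * tot)


@njit(cache=True)
def integrate_network(
    n_steps, dt, record_stride, theta_omega,
    # interneurons (I)
    v_i, m_i, h_i, n_i, a_i, clamped_i, last_spk_i, peak_i,
    cm_i, gna_i, gkv1_i, gkv3_i, gl_i, ena_i, ek_i, el_i, kin_i,
    # stellate cells (E)
    v_e, m_e, h_e, n_e, clamped_e, last_spk_e, peak_e,
    cm_e, gna_e, gk_e, gl_e, ena_e, eke_e, el_e,
    # OU noise on E cells
    gou_e, gou_i, ou_mean_e, ou_sd_e, ou_decay_e, ou_diff_e, ou_rev_e,
    ou_mean_i, ou_sd_i, ou_decay_i, ou_diff_i, ou_rev_i,
    # synapse class parameters
    e_gaba_ii, e_gaba_ie, e_ampa,
    fr_ii, fd_ii, fr_ie, fd_ie, f_ei,
    # outgoing-edge CSR per presynaptic cell
    ii_indptr, ii_post, ii_w, ii_dsteps,
    ie_indptr, ie_post, ie_w, ie_dsteps,
    ei_indptr, ei_post, ei_w, ei_dsteps,
    # gap junctions, directed CSR over I cells
    gap_indptr, gap_nbr, gap_gw,
    # delay ring buffers and synaptic states
    buf_ii, buf_ei, buf_ie,
    sa_ii, sb_ii, sg_ei, sa_ie, sb_ie,
    # voltage clamp and recording
    v_hold, include_drive, readout_i, readout_e,
    rec_i, rec_e, rec_drive,
    # spike output
    spk_t_i, spk_c_i, spk_t_e, spk_c_e,
    runtime_seed,
):
    np.random.seed(runtime_seed)
    nslots = buf_ii.shape[0]
    ncell_i = v_i.shape[0]
    ncell_e = v_e.shape[0]
    nsp_i = 0
    nsp_e = 0
    # error sentinel: (code, population, cell, time); code 0 = ok
    err = np.zeros(4)

    for step in range(n_steps):
        t = step * dt
        slot = step % nslots

        # 1. deliver queued spikes
        for c in range(ncell_i):
            w = buf_ii[slot, c]
            if w != 0.0:
                sa_ii[c] += w
                sb_ii[c] += w
                buf_ii[slot, c] = 0.0
            w = buf_ei[slot, c]
            if w != 0.0:
                sg_ei[c] += w
                buf_ei[slot, c] = 0.0
        for c in range(ncell_e):
            w = buf_ie[slot, c]
            if w != 0.0:
                sa_ie[c] += w
                sb_ie[c] += w
                buf_ie[slot, c] = 0.0

        env = 0.5 * (1.0 - np.cos(theta_omega * t))

        # 2. record clamp currents (synaptic only unless include_drive)
        if step % record_stride == 0:
            r = step // record_stride
            rec_drive[r] = env
            for k in range(readout_i.shape[0]):
                c = readout_i[k]
                cur = (sb_ii[c] - sa_ii[c]) * (e_gaba_ii - v_hold) \
                    + sg_ei[c] * (e_ampa - v_hold)
                if include_drive:
                    cur += peak_i[c] * env * (0.0 - v_hold)
                rec_i[k, r] = cur
            for k in range(readout_e.shape[0]):
                c = readout_e[k]
                cur = (sb_ie[c] - sa_ie[c]) * (e_gaba_ie - v_hold)
                if include_drive:
                    cur += peak_e[c] * env * (0.0 - v_hold)
                rec_e[k, r] = cur

        # 3. OU update (exact) for E cells
        for c in range(ncell_e):
            z1 = np.random.standard_normal()
            z2 = np.random.standard_normal()
            gou_e[c] = ou_mean_e + (gou_e[c] - ou_mean_e) * ou_decay_e \
                + ou_diff_e * z1
            gou_i[c] = ou_mean_i + (gou_i[c] - ou_mean_i) * ou_decay_i \
                + ou_diff_i * z2

        # 4. gap-junction sums at frozen voltages
        gap_sum_g = np.zeros(ncell_i)
        gap_sum_gv = np.zeros(ncell_i)
        for c in range(ncell_i):
            for e in range(gap_indptr[c], gap_indptr[c + 1]):
                g = gap_gw[e]
                gap_sum_g[c] += g
                gap_sum_gv[c] += g * v_i[gap_nbr[e]]

        # 5. integrate I cells
        for c in range(ncell_i):
            if clamped_i[c]:
                continue
            v = v_i[c]
            # gates (exponential Euler at current V)
            # rows of kin_i: m, h, n, a
            # cols: theta, sigma1, sigma2, k1, k2, is_inactivation
            for gidx in range(4):
                th = kin_i[gidx, 0]
                s1 = kin_i[gidx, 1]
                s2 = kin_i[gidx, 2]
                k1 = kin_i[gidx, 3]
                k2 = kin_i[gidx, 4]
                al = k1 * abs(s1) * _linoid((th - v) / s1)
                be = k2 * np.exp(v / s2)
                if kin_i[gidx, 5] != 0.0:  # inactivation: beta opens
                    al, be = be, al
                if gidx == 0:
                    m_i[c] = _gate_exp_euler(m_i[c], al, be, dt)
                elif gidx == 1:
                    h_i[c] = _gate_exp_euler(h_i[c], al, be, dt)
                elif gidx == 2:
                    n_i[c] = _gate_exp_euler(n_i[c], al, be, dt)
                else:
                    a_i[c] = _gate_exp_euler(a_i[c], al, be, dt)
            g_na = gna_i[c] * m_i[c] ** 3 * h_i[c]
            g_k = gkv3_i[c] * n_i[c] ** 4 + gkv1_i[c] * a_i[c] ** 4
            g_drv = peak_i[c] * env
            g_syn_ii = sb_ii[c] - sa_ii[c]
            g_syn_ei = sg_ei[c]
            gtot = g_na + g_k + gl_i[c] + g_drv + g_syn_ii + g_syn_ei \
                + gap_sum_g[c]
            num = g_na * ena_i + g_k * ek_i + gl_i[c] * el_i \
                + g_syn_ii * e_gaba_ii + g_syn_ei * e_ampa + gap_sum_gv[c]
            vinf = num / gtot
            v_new = vinf + (v - vinf) * np.exp(-dt * gtot / cm_i)
            v_i[c] = v_new
            # 7. spike detection + queueing
            if v < 0.0 <= v_new:
                ts = t + dt * (0.0 - v) / (v_new - v)
                if ts - last_spk_i[c] > 1.0:
                    last_spk_i[c] = ts
                    spk_t_i[nsp_i] = ts
                    spk_c_i[nsp_i] = c
                    nsp_i += 1
                    for e in range(ii_indptr[c], ii_indptr[c + 1]):
                        s = (step + 1 + ii_dsteps[e]) % nslots
                        buf_ii[s, ii_post[e]] += ii_w[e]
                    for e in range(ie_indptr[c], ie_indptr[c + 1]):
                        s = (step + 1 + ie_dsteps[e]) % nslots
                        buf_ie[s, ie_post[e]] += ie_w[e]

        # integrate E cells (classic HH rates)
        for c in range(ncell_e):
            if clamped_e[c]:
                continue
            v = v_e[c]
            am = _linoid(-(v + 40.0) / 10.0)
            bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
            m_e[c] = _gate_exp_euler(m_e[c], am, bm, dt)
            ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
            bh = 1.0 / (np.exp(-(v + 35.0) / 10.0) + 1.0)
            h_e[c] = _gate_exp_euler(h_e[c], ah, bh, dt)
            an = 0.1 * _linoid(-(v + 55.0) / 10.0)
            bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
            n_e[c] = _gate_exp_euler(n_e[c], an, bn, dt)
            g_na = gna_e[c] * m_e[c] ** 3 * h_e[c]
            g_k = gk_e[c] * n_e[c] ** 4
            g_drv = peak_e[c] * env
            g_syn = sb_ie[c] - sa_ie[c]
            gtot = g_na + g_k + gl_e[c] + g_drv + g_syn + gou_e[c] + gou_i[c]
            num = g_na * ena_e + g_k * eke_e + gl_e[c] * el_e \
                + g_syn * e_gaba_ie + gou_e[c] * ou_rev_e + gou_i[c] * ou_rev_i
            vinf = num / gtot
            v_new = vinf + (v - vinf) * np.exp(-dt * gtot / cm_e)
            v_e[c] = v_new
            if v < 0.0 <= v_new:
                ts = t + dt * (0.0 - v) / (v_new - v)
                if ts - last_spk_e[c] > 1.0:
                    last_spk_e[c] = ts
                    spk_t_e[nsp_e] = ts
                    spk_c_e[nsp_e] = c
                    nsp_e += 1
                    for e in range(ei_indptr[c], ei_indptr[c + 1]):
                        s = (step + 1 + ei_dsteps[e]) % nslots
                        buf_ei[s, ei_post[e]] += ei_w[e]

        # 6. synaptic decay
        for c in range(ncell_i):
            sa_ii[c] *= fr_ii
            sb_ii[c] *= fd_ii
            sg_ei[c] *= f_ei
        for c in range(ncell_e):
            sa_ie[c] *= fr_ie
            sb_ie[c] *= fd_ie

        # periodic health check
        if step % 2000 == 0:
            for c in range(ncell_i):
                if not np.isfinite(v_i[c]):
                    err[0] = 1.0
                    err[1] = 0.0
                    err[2] = c
                    err[3] = t
                    return nsp_i, nsp_e, err
            for c in range(ncell_e):
                if not np.isfinite(v_e[c]):
                    err[0] = 1.0
                    err[1] = 1.0
                    err[2] = c
                    err[3] = t
                    return nsp_i, nsp_e, err

    return nsp_i, nsp_e, err
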