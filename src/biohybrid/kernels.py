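"""Vectorized network stepper (numba).

Advances an entire homogeneous population of neuron elements on the
fixed dt grid, reproducing the scalar per-step semantics of
:mod:`biohybrid.core` exactly:

  1. deliver recurrent spikes emitted on the previous step (one-step
     routing latency) and the external events scheduled for this step
     (simultaneous events superpose linearly on the multi-synapses);
  2. forward-Euler membrane update (held at reset while refractory),
     clamped to the reversal-potential range;
  3. threshold crossing: reset, refractory, SFA increment, STP update,
     spike queued for delivery on the next step;
  4. exponential decay of all conductances.

Connectivity is passed in CSR form: ``r_indptr[i]:r_indptr[i+1]``
indexes the routing entries of source neuron i (targets, 6-bit weights,
source STP channel, target multi-synapse slot); external channels have
their own CSR with precomputed integer efficacies (weight x 63, no
source STP).  STP modes are encoded 0=static, 1=facilitation,
2=depression, 3=combined.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_chunk", "STP_MODE_CODES"]

STP_MODE_CODES = {"static": 0, "facilitation": 1, "depression": 2, "combined": 3}


@njit(cache=True)
def _pwl_factor(v, pwl_v, pwl_f):
    n = pwl_v.shape[0]
    if v <= pwl_v[0]:
        return pwl_f[0]
    if v >= pwl_v[n - 1]:
        return pwl_f[n - 1]
    for i in range(1, n):
        if v < pwl_v[i]:
            w = (v - pwl_v[i - 1]) / (pwl_v[i] - pwl_v[i - 1])
            return pwl_f[i - 1] + w * (pwl_f[i] - pwl_f[i - 1])
    return pwl_f[n - 1]


@njit(cache=True)
def run_chunk(
    # mutable state
    V, refrac_until, g_sfa, g_syn, stp_u, stp_x, last_spike,
    pend_ids, pend_q, n_pend,
    # neuron parameters
    dt, cap_nf, g_leak, e_leak, threshold, v_reset, t_refrac,
    sfa_inc, sfa_decay, e_sfa, v_lo, v_hi,
    # synapse slot parameters
    syn_e, syn_decay, syn_quant, syn_is_nmda, pwl_v, pwl_f,
    # STP parameters (per channel 0..3)
    stp_mode, stp_uu, stp_facil_tau, stp_rec_tau, quant_levels,
    # recurrent routing CSR
    r_indptr, r_targets, r_tsyn, r_weights, r_stpch,
    # external events and routing CSR
    ev_step, ev_chan, x_indptr, x_targets, x_tsyn, x_eff,
    # chunk extent and spike output
    t0, n_steps, out_step, out_id,
):
    """Advance ``n_steps`` steps from absolute time ``t0`` (ms).

    Returns ``(n_spikes, n_pend)``; spikes are written to
    ``out_step``/``out_id`` as (absolute step offset within chunk,
    neuron id).  ``pend_*`` carry spikes across chunk boundaries.
    """
    n = V.shape[0]
    n_ev = ev_step.shape[0]
    ev_ptr = 0
    n_out = 0
    coef = dt / (1000.0 * cap_nf)
    qlm1 = float(quant_levels - 1)

    for s in range(n_steps):
        t = t0 + s * dt

        # deliver spikes from the previous step (one-dt routing latency)
        for k in range(n_pend):
            i = pend_ids[k]
            for e in range(r_indptr[i], r_indptr[i + 1]):
                eff = r_weights[e] * pend_q[k, r_stpch[e]]
                slot = r_tsyn[e]
                g_syn[r_targets[e], slot] += eff * syn_quant[slot]
        n_pend = 0

        # deliver external events scheduled for this step
        while ev_ptr < n_ev and ev_step[ev_ptr] <= s:
            ch = ev_chan[ev_ptr]
            for e in range(x_indptr[ch], x_indptr[ch + 1]):
                slot = x_tsyn[e]
                g_syn[x_targets[e], slot] += x_eff[e] * syn_quant[slot]
            ev_ptr += 1

        for i in range(n):
            if t < refrac_until[i] - 1e-12:
                V[i] = v_reset
            else:
                v = V[i]
                cur = g_leak * (e_leak - v) + g_sfa[i] * (e_sfa - v)
                for slot in range(5):
                    g = g_syn[i, slot]
                    if g > 0.0:
                        f = _pwl_factor(v, pwl_v, pwl_f) if syn_is_nmda[slot] else 1.0
                        cur += g * f * (syn_e[slot] - v)
                v = v + coef * cur
                if v < v_lo:
                    v = v_lo
                elif v > v_hi:
                    v = v_hi
                if v >= threshold:
                    # spike
                    if n_out < out_step.shape[0]:
                        out_step[n_out] = s
                        out_id[n_out] = i
                        n_out += 1
                    V[i] = v_reset
                    refrac_until[i] = t + t_refrac
                    g_sfa[i] += sfa_inc
                    dtl = t - last_spike[i]
                    for c in range(4):
                        mode = stp_mode[c]
                        uu = stp_uu[c]
                        if mode == 0:
                            u = uu
                            x = 1.0
                        else:
                            fac = math.exp(-dtl / stp_facil_tau[c])
                            rec = math.exp(-dtl / stp_rec_tau[c])
                            u = uu + (stp_u[i, c] - uu) * fac
                            x = 1.0 - (1.0 - stp_x[i, c]) * rec
                            if mode == 1 or mode == 3:
                                u = u + uu * (1.0 - u)
                            if mode == 2 or mode == 3:
                                x = x * (1.0 - u)
                        stp_u[i, c] = u
                        stp_x[i, c] = x
                        pend_q[n_pend, c] = int(math.floor(u * x * qlm1 + 0.5))
                    last_spike[i] = t
                    pend_ids[n_pend] = i
                    n_pend += 1
                else:
                    V[i] = v

            # conductance decay (also during refractoriness)
            for slot in range(5):
                g_syn[i, slot] *= syn_decay[slot]
            g_sfa[i] *= sfa_decay

    return n_out, n_pend
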