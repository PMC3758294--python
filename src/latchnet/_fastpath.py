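"""Numba kernels behind the batch experiment runner.

The model is stepped exactly as in :mod:`latchnet.dynamics`; these kernels
only reorganize the arithmetic for speed:

* clamp phases skip the support/noise update (the output is overridden
  anyway) and run entirely inside one jitted loop;
* plastic free phases keep the per-step ``log`` of the co-activation
  matrix in numpy (SIMD) and jit the rest, driven from a thin Python loop;
* recall phases have frozen weights (``kappa = 0``), so ``w`` and ``beta``
  are computed once and the whole phase runs jitted with pre-drawn noise.

An equivalence test pins these kernels to the reference step function.
Event detection (leaky accumulator with threshold/2 hysteresis) is inlined
so no per-step state leaves the kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "detect_events_jit",
    "run_clamp_phase",
    "plastic_substep",
    "free_substep",
    "run_recall_chunk",
]


@njit(cache=True, inline="always")
def _detector_step(m, A, open_ev, leak, theta, t,
                   ev_step, ev_item, ev_end, n_ev):
    """Advance every item's leaky accumulator by one step and record
    threshold crossings (events) and drops below theta/2 (event ends)."""
    half = 0.5 * theta
    K = m.shape[0]
    for k in range(K):
        A[k] = (1.0 - leak) * A[k] + m[k]
        if open_ev[k] < 0:
            if A[k] >= theta:
                if n_ev < ev_step.shape[0]:
                    ev_step[n_ev] = t
                    ev_item[n_ev] = k
                    ev_end[n_ev] = -1
                    open_ev[k] = n_ev
                n_ev += 1
        else:
            if A[k] < half:
                if open_ev[k] < ev_end.shape[0]:
                    ev_end[open_ev[k]] = t
                open_ev[k] = -1
    return n_ev


@njit(cache=True)
def detect_events_jit(m_ts, leak, theta, t0,
                      A, open_ev, ev_step, ev_item, ev_end, n_ev):
    """Run the detector over a pre-computed overlap time series
    ``m_ts`` of shape ``(n_steps, n_items)``; steps are numbered from
    ``t0``.  Returns the updated event count."""
    T = m_ts.shape[0]
    for t in range(T):
        n_ev = _detector_step(m_ts[t], A, open_ev, leak, theta, t0 + t,
                              ev_step, ev_item, ev_end, n_ev)
    return n_ev


@njit(cache=True, inline="always")
def _overlaps(o, cols, sqrtH, m_buf):
    """Cosine overlap of the output with each stored pattern, using the
    sparse index form (``cols[k, h]`` = flat unit index of item k's active
    unit in hypercolumn h)."""
    n = o.shape[0]
    ss = 0.0
    for j in range(n):
        ss += o[j] * o[j]
    norm = np.sqrt(ss) * sqrtH
    K, H = cols.shape
    for k in range(K):
        d = 0.0
        for h in range(H):
            d += o[cols[k, h]]
        m_buf[k] = d / norm
    return m_buf


@njit(cache=True)
def plastic_substep(z_i, z_j, p_i, p_j, p_ij, o, c_zi, c_zj, c_p, z_floor):
    """Fused z-trace and kappa-gated p-estimate update (one Euler step).

    ``c_zi = dt/tau_zi`` etc.; ``c_p = kappa*dt/tau_p``; ``z_floor`` is
    the spontaneous background rate under which the traces never decay.
    The p update uses the freshly updated traces, matching the reference
    step order.
    """
    n = o.shape[0]
    for j in range(n):
        zi = z_i[j] + c_zi * (o[j] - z_i[j])
        zj = z_j[j] + c_zj * (o[j] - z_j[j])
        if zi < z_floor:
            zi = z_floor
        if zj < z_floor:
            zj = z_floor
        z_i[j] = zi
        z_j[j] = zj
    if c_p != 0.0:
        for j in range(n):
            p_i[j] += c_p * (z_i[j] - p_i[j])
            p_j[j] += c_p * (z_j[j] - p_j[j])
        for i in range(n):
            zi = z_i[i]
            row = p_ij[i]
            for j in range(n):
                row[j] += c_p * (zi * z_j[j] - row[j])


@njit(cache=True)
def run_clamp_phase(n_steps, t0, o_clamp, log_o_clamp,
                    s, a, o, z_i, z_j, p_i, p_j, p_ij,
                    c_zi, c_zj, c_p, p_floor, c_a,
                    cols, sqrtH, A, open_ev, leak, theta,
                    ev_step, ev_item, ev_end, n_ev,
                    record, m_out):
    """Hard-clamp phase: plasticity and adaptation run, the output is
    pinned to ``o_clamp`` and the support to ``log_o_clamp``; no noise is
    drawn.  Detection keeps running on the clamped output."""
    n = o.shape[0]
    K = cols.shape[0]
    m_buf = np.empty(K)
    for t in range(n_steps):
        plastic_substep(z_i, z_j, p_i, p_j, p_ij, o, c_zi, c_zj, c_p,
                        p_floor)
        for j in range(n):
            o[j] = o_clamp[j]
            s[j] = log_o_clamp[j]
            a[j] += c_a * (o[j] - a[j])
        _overlaps(o, cols, sqrtH, m_buf)
        if record:
            for k in range(K):
                m_out[t, k] = m_buf[k]
        n_ev = _detector_step(m_buf, A, open_ev, leak, theta, t0 + t,
                              ev_step, ev_item, ev_end, n_ev)
    return n_ev


@njit(cache=True)
def free_substep(s, a, o, bs, g_a, dt_over_tau_m, noise_row,
                 H, M, c_a, cols, sqrtH, A, open_ev, leak, theta,
                 ev_step, ev_item, ev_end, n_ev, t,
                 record, m_out, t_rec):
    """Support update + softmax + adaptation + detection for one free
    step.  ``bs`` is the precomputed ``beta + synaptic + external`` drive;
    ``noise_row`` is already scaled by sigma."""
    n = s.shape[0]
    for j in range(n):
        d = bs[j] - g_a * a[j] - s[j]
        s[j] += dt_over_tau_m * d + noise_row[j]
        if not np.isfinite(s[j]):
            return -1 - j  # signal: non-finite support at unit j
    for h in range(H):
        base = h * M
        mx = s[base]
        for j in range(1, M):
            if s[base + j] > mx:
                mx = s[base + j]
        tot = 0.0
        for j in range(M):
            e = np.exp(s[base + j] - mx)
            o[base + j] = e
            tot += e
        for j in range(M):
            o[base + j] /= tot
    for j in range(n):
        a[j] += c_a * (o[j] - a[j])
    K = cols.shape[0]
    m_buf = np.empty(K)
    _overlaps(o, cols, sqrtH, m_buf)
    if record:
        for k in range(K):
            m_out[t_rec, k] = m_buf[k]
    n_ev = _detector_step(m_buf, A, open_ev, leak, theta, t,
                          ev_step, ev_item, ev_end, n_ev)
    return n_ev


@njit(cache=True)
def run_plastic_chunk(n_steps, t0, s, a, o, z_i, z_j, p_i, p_j, p_ij,
                      c_zi, c_zj, c_p, z_floor, ext,
                      g_w, g_b, eps, g_a, dt_over_tau_m, noise,
                      H, M, c_a, cols, sqrtH, A, open_ev, leak, theta,
                      ev_step, ev_item, ev_end, n_ev,
                      record, m_out, t_rec0):
    """Plastic free phase: per-step trace/estimate update plus weight
    recomputation folded into the synaptic sum.

    The synaptic drive ``sum_i w_ij o_i`` is expanded as
    ``g_w * (sum_i o_i log p_ij - sum_i o_i log p_i - (sum_i o_i) log
    p_j)`` and evaluated over presynaptic rows with ``o_i > 1e-16`` only:
    suppressed softmax losers sit at ``o ~ e^-80``, so their contribution
    is below double-precision round-off of the total drive.  ``ext`` is a
    constant external drive (the soft-clamp evidence term; zeros
    otherwise); ``noise`` rows are pre-scaled by sigma.
    """
    n = s.shape[0]
    lj = np.empty(n)
    syn = np.empty(n)
    bs = np.empty(n)
    for t in range(n_steps):
        plastic_substep(z_i, z_j, p_i, p_j, p_ij, o, c_zi, c_zj, c_p,
                        z_floor)
        for j in range(n):
            pj = p_j[j]
            if pj < eps:
                pj = eps
            lj[j] = np.log(pj)
            syn[j] = 0.0
        osum = 0.0
        sub = 0.0
        for i in range(n):
            oi = o[i]
            if oi <= 1e-16:
                continue
            osum += oi
            pi = p_i[i]
            if pi < eps:
                pi = eps
            sub += oi * np.log(pi)
            row = p_ij[i]
            for j in range(n):
                pij = row[j]
                if pij < eps:
                    pij = eps
                syn[j] += oi * np.log(pij)
        for j in range(n):
            bs[j] = g_b * lj[j] + g_w * (syn[j] - sub - osum * lj[j]) \
                + ext[j]
        rc = free_substep(s, a, o, bs, g_a, dt_over_tau_m, noise[t],
                          H, M, c_a, cols, sqrtH, A, open_ev, leak,
                          theta, ev_step, ev_item, ev_end, n_ev, t0 + t,
                          record, m_out, t_rec0 + t)
        if rc < 0:
            return rc
        n_ev = rc
    return n_ev


@njit(cache=True)
def run_recall_chunk(n_steps, t0, s, a, o, z_i, z_j, c_zi, c_zj, z_floor,
                     w, beta, g_a, dt_over_tau_m,
                     noise, H, M, c_a, cols, sqrtH, A, open_ev, leak,
                     theta, ev_step, ev_item, ev_end, n_ev,
                     record, m_out, t_rec0):
    """Frozen-weight phase (``kappa = 0``): full internal loop with
    pre-drawn, pre-scaled noise rows.  The z-traces keep evolving (they
    are not kappa-gated) even though they no longer reach the frozen p
    estimates.  Returns the updated event count, or a negative failure
    code (-1 - unit) on non-finite support."""
    n = s.shape[0]
    K = cols.shape[0]
    m_buf = np.empty(K)
    for t in range(n_steps):
        for j in range(n):
            zi = z_i[j] + c_zi * (o[j] - z_i[j])
            zj = z_j[j] + c_zj * (o[j] - z_j[j])
            z_i[j] = zi if zi > z_floor else z_floor
            z_j[j] = zj if zj > z_floor else z_floor
        syn = np.dot(o, w)
        for j in range(n):
            d = beta[j] + syn[j] - g_a * a[j] - s[j]
            s[j] += dt_over_tau_m * d + noise[t, j]
            if not np.isfinite(s[j]):
                return -1 - j
        for h in range(H):
            base = h * M
            mx = s[base]
            for j in range(1, M):
                if s[base + j] > mx:
                    mx = s[base + j]
            tot = 0.0
            for j in range(M):
                e = np.exp(s[base + j] - mx)
                o[base + j] = e
                tot += e
            for j in range(M):
                o[base + j] /= tot
        for j in range(n):
            a[j] += c_a * (o[j] - a[j])
        _overlaps(o, cols, sqrtH, m_buf)
        if record:
            for k in range(K):
                m_out[t_rec0 + t, k] = m_buf[k]
        n_ev = _detector_step(m_buf, A, open_ev, leak, theta, t0 + t,
                              ev_step, ev_item, ev_end, n_ev)
    return n_ev
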