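"""Compiled integration core (numba).

The tissue ODE right-hand side and the fixed-step Heun loop are compiled
with numba for speed; the public, vectorized :func:`discwave.model.derivatives`
is the readable reference implementation of the same equations.

Status codes returned by :func:`run_segment`:
``0`` ok, ``1`` negative state after step rejection, ``2`` divergence.
"""

import numba
import numpy as np

__all__ = ["run_segment"]


@numba.njit(cache=True, fastmath=False)
def _rhs_core(
    c, s, p, h,
    dc, ds, dp, dh,
    indptr, indices, data,
    wsum, inv_area,
    v_ip3r, v_leak, v_serca, k_serca, d1, d5, d2v,
    plc_in, k_deg, v_soce_cell, k_soce, v_pm_out, ca_ext,
    d_c, d_p, beta, tau_h_cell, spike_in,
):
    n = c.shape[0]
    k_serca2 = k_serca * k_serca
    k_soce2 = k_soce * k_soce
    for i in range(n):
        ci = c[i]
        si = s[i]
        pi = p[i]
        hi = h[i]
        gate = (pi / (pi + d1)) * (ci / (ci + d5)) * hi
        open_p = gate * gate * gate
        release = (v_ip3r * open_p + v_leak) * (si - ci)
        serca = v_serca * ci * ci / (k_serca2 + ci * ci)
        soce = v_soce_cell[i] * k_soce2 / (k_soce2 + si * si) * ca_ext
        # junctional exchange (CSR row i)
        acc_c = 0.0
        acc_p = 0.0
        for jj in range(indptr[i], indptr[i + 1]):
            j = indices[jj]
            w = data[jj]
            acc_c += w * c[j]
            acc_p += w * p[j]
        jc = d_c * (acc_c - wsum[i] * ci) * inv_area[i]
        jp = d_p * (acc_p - wsum[i] * pi) * inv_area[i]
        dc[i] = release - serca + soce - v_pm_out * ci + spike_in[i] + jc
        ds[i] = -(release - serca) / beta
        dp[i] = plc_in[i] - k_deg * pi + jp
        dh[i] = (d2v / (d2v + ci) - hi) / tau_h_cell[i]


@numba.njit(cache=True, fastmath=False)
def run_segment(
    c, s, p, h,
    n_steps, t_start, dt,
    indptr, indices, data,
    wsum, inv_area,
    v_ip3r, v_leak, v_serca, k_serca, d1, d5, d2v,
    plc_in, k_deg, v_soce_cell, k_soce, v_pm_out, ca_ext,
    d_c, d_p, beta, tau_h_cell,
    j_spike, spike_dur, spike_until, ev_times, ev_cells, ev_ptr,
):
    """Advance the state by ``n_steps`` Heun steps in place.

    ``ev_times``/``ev_cells`` hold the precomputed stochastic spike events
    (sorted by time); ``ev_ptr`` is the index of the first unconsumed event.
    Returns ``(status, new_ev_ptr)``.
    """
    n = c.shape[0]
    d1c = np.empty(n)
    d1s = np.empty(n)
    d1p = np.empty(n)
    d1h = np.empty(n)
    d2c = np.empty(n)
    d2s = np.empty(n)
    d2p = np.empty(n)
    d2h = np.empty(n)
    c1 = np.empty(n)
    s1 = np.empty(n)
    p1 = np.empty(n)
    h1 = np.empty(n)
    spike_in = np.zeros(n)
    n_events = ev_times.shape[0]

    for k in range(n_steps):
        t = t_start + k * dt
        # activate pending spike events
        while ev_ptr < n_events and ev_times[ev_ptr] <= t + 1e-12:
            i = ev_cells[ev_ptr]
            until = ev_times[ev_ptr] + spike_dur
            if until > spike_until[i]:
                spike_until[i] = until
            ev_ptr += 1
        for i in range(n):
            spike_in[i] = j_spike * ca_ext if spike_until[i] > t else 0.0

        _rhs_core(
            c, s, p, h, d1c, d1s, d1p, d1h, indptr, indices, data, wsum,
            inv_area, v_ip3r, v_leak, v_serca, k_serca, d1, d5, d2v, plc_in,
            k_deg, v_soce_cell, k_soce, v_pm_out, ca_ext, d_c, d_p, beta,
            tau_h_cell, spike_in,
        )
        for i in range(n):
            c1[i] = max(c[i] + dt * d1c[i], 1e-12)
            s1[i] = max(s[i] + dt * d1s[i], 1e-12)
            p1[i] = max(p[i] + dt * d1p[i], 1e-12)
            h1[i] = h[i] + dt * d1h[i]
        _rhs_core(
            c1, s1, p1, h1, d2c, d2s, d2p, d2h, indptr, indices, data, wsum,
            inv_area, v_ip3r, v_leak, v_serca, k_serca, d1, d5, d2v, plc_in,
            k_deg, v_soce_cell, k_soce, v_pm_out, ca_ext, d_c, d_p, beta,
            tau_h_cell, spike_in,
        )
        half = 0.5 * dt
        bad = False
        for i in range(n):
            cn = c[i] + half * (d1c[i] + d2c[i])
            sn = s[i] + half * (d1s[i] + d2s[i])
            pn = p[i] + half * (d1p[i] + d2p[i])
            hn = h[i] + half * (d1h[i] + d2h[i])
            if cn < 0.0 or sn < 0.0 or pn < 0.0 or not np.isfinite(cn):
                bad = True
                break
            c1[i] = cn
            s1[i] = sn
            p1[i] = pn
            h1[i] = hn
        if bad:
            # step rejection: redo the whole step with 8 Euler substeps
            for i in range(n):
                c1[i] = c[i]
                s1[i] = s[i]
                p1[i] = p[i]
                h1[i] = h[i]
            sub = dt / 8.0
            for _ in range(8):
                _rhs_core(
                    c1, s1, p1, h1, d1c, d1s, d1p, d1h, indptr, indices,
                    data, wsum, inv_area, v_ip3r, v_leak, v_serca, k_serca,
                    d1, d5, d2v, plc_in, k_deg, v_soce_cell, k_soce, v_pm_out,
                    ca_ext, d_c, d_p, beta, tau_h_cell, spike_in,
                )
                for i in range(n):
                    c1[i] = c1[i] + sub * d1c[i]
                    s1[i] = s1[i] + sub * d1s[i]
                    p1[i] = p1[i] + sub * d1p[i]
                    h1[i] = h1[i] + sub * d1h[i]
            for i in range(n):
                if (
                    c1[i] < 0.0 or s1[i] < 0.0 or p1[i] < 0.0
                    or not np.isfinite(c1[i])
                ):
                    return 1, ev_ptr
        cmax = 0.0
        for i in range(n):
            c[i] = c1[i]
            s[i] = s1[i]
            p[i] = p1[i]
            h[i] = h1[i]
            if c[i] > cmax:
                cmax = c[i]
            if s[i] > cmax:
                cmax = s[i]
        if cmax > 1e6:
            return 2, ev_ptr
    return 0, ev_ptr
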