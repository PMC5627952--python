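"""Numba-compiled inner loops.

All kernels are pure functions of pre-drawn random numbers so that the
simulation is bit-reproducible for a given seed regardless of compilation.
Time is in seconds for spike/release kernels and in milliseconds inside the
membrane integrators (matching the natural units of the membrane equations:
mV, ms, mS/cm^2, uF/cm^2, uA/cm^2).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def thin_with_refractory(candidates, u, A, B, two_pi_f, refractory):
    """Thin homogeneous Poisson candidates against A + B*sin(2*pi*f*t).

    A candidate inside the dead time of the last accepted spike is deleted
    outright; otherwise it is accepted with probability lambda(t)/(A+B).
    """
    out = np.empty(candidates.size, dtype=np.float64)
    n = 0
    last = -np.inf
    bound = A + B
    for i in range(candidates.size):
        t = candidates[i]
        if t - last < refractory:
            continue
        lam = A + B * np.sin(two_pi_f * t)
        if u[i] * bound < lam:
            out[n] = t
            n += 1
            last = t
    return out[:n]


@njit(cache=True)
def release_zone(spike_times, n_sites, p_v, u, refill, next_avail,
                 counts, avail_frac):
    """Event-driven vesicle release for one active zone.

    next_avail (len n_sites) holds the time at which each site is next
    occupied; a site with next_avail <= t releases with probability p_v and
    is then scheduled to refill after an exponential delay (pre-drawn in
    `refill`). avail_frac records the occupied fraction *before* sampling.
    """
    for i in range(spike_times.size):
        t = spike_times[i]
        n_avail = 0
        n_rel = 0
        for k in range(n_sites):
            if next_avail[k] <= t:
                n_avail += 1
                if u[i, k] < p_v:
                    n_rel += 1
                    next_avail[k] = t + refill[i, k]
        counts[i] = n_rel
        avail_frac[i] = n_avail / n_sites


@njit(cache=True)
def integrate_hh(r_steps, dt, c_m, g_l, g_k, g_na, e_l, e_k, e_na,
                 tau_m, tau_h, tau_n, syn_scale, e_syn,
                 tau_rise, tau_d, v0):
    """Forward-Euler integration of the two-gate HH membrane.

    r_steps: vesicle count assigned to each time step (right-aligned).
    dt in ms.  syn_scale = gbar_synapse[S] * 1e3 / area[cm^2] converts the
    dimensionless conductance g(t) times (v - E_syn)[mV] into uA/cm^2.
    Returns (v, m, h, n, g) traces sampled on the same grid as r_steps.
    Kinetics: gK * n^2 and gNa * m^2 * h with logistic steady states.
    """
    nsteps = r_steps.size
    v = np.empty(nsteps, dtype=np.float64)
    m = np.empty(nsteps, dtype=np.float64)
    h = np.empty(nsteps, dtype=np.float64)
    n = np.empty(nsteps, dtype=np.float64)
    g = np.empty(nsteps, dtype=np.float64)
    vv = v0
    mm = 0.0
    hh = 0.0
    nn = 0.0
    gg = 0.0
    xx = 0.0
    delta = tau_rise == 0.0
    for i in range(nsteps):
        r = r_steps[i]
        if delta:
            xx = r / dt
        elif r > 0.0:
            xx += r / tau_rise
        # membrane currents in uA/cm^2
        i_syn = -syn_scale * gg * (vv - e_syn)
        dv = (-g_l * (vv - e_l)
              - g_k * nn * nn * (vv - e_k)
              - g_na * mm * mm * hh * (vv - e_na)
              + i_syn) / c_m
        m_ss = 1.0 / (1.0 + np.exp(-(vv + 40.0) / 3.0))
        h_ss = 1.0 / (1.0 + np.exp((vv + 45.0) / 3.0))
        n_ss = 1.0 / (1.0 + np.exp(-(vv + 40.0) / 3.0))
        g_new = gg + dt * (-gg / tau_d + xx)
        if not delta:
            xx += dt * (-xx / tau_rise)
        vv += dt * dv
        mm += dt * (m_ss - mm) / tau_m
        hh += dt * (h_ss - hh) / tau_h
        nn += dt * (n_ss - nn) / tau_n
        gg = g_new
        v[i] = vv
        m[i] = mm
        h[i] = hh
        n[i] = nn
        g[i] = gg
    return v, m, h, n, g


@njit(cache=True)
def integrate_lif(r_steps, dt, c_m, g_l, e_l, syn_scale, e_syn,
                  tau_rise, tau_d, v_thresh, v_reset, t_refrac, v0):
    """Forward-Euler LIF with reset clamp; returns (v, g, spike step idx)."""
    nsteps = r_steps.size
    v = np.empty(nsteps, dtype=np.float64)
    g = np.empty(nsteps, dtype=np.float64)
    spikes = np.empty(nsteps, dtype=np.int64)
    n_sp = 0
    vv = v0
    gg = 0.0
    xx = 0.0
    refrac_until = -1.0
    delta = tau_rise == 0.0
    for i in range(nsteps):
        t = i * dt
        r = r_steps[i]
        if delta:
            xx = r / dt
        elif r > 0.0:
            xx += r / tau_rise
        g_new = gg + dt * (-gg / tau_d + xx)
        if not delta:
            xx += dt * (-xx / tau_rise)
        if t < refrac_until:
            vv = v_reset
        else:
            i_syn = -syn_scale * gg * (vv - e_syn)
            vv += dt * (-g_l * (vv - e_l) + i_syn) / c_m
            if vv > v_thresh:
                spikes[n_sp] = i
                n_sp += 1
                vv = v_reset
                refrac_until = t + t_refrac
        gg = g_new
        v[i] = vv
        g[i] = gg
    return v, g, spikes[:n_sp]
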