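"""Numba kernels for the within-patch Gillespie simulation.

State layout (int64, per patch)::

    0  x_A   remaining resource for host A
    1  x_B   remaining resource for host B
    2  A     uninfected host A
    3  B     uninfected host B
    4  G     free generalist phage
    5  S     free specialist phage
    6  I_GA  generalist-infected host A
    7  I_GB  generalist-infected host B
    8  I_SA  specialist-infected host A
    9  y0_A  initial resource-A endowment
    10 y0_B  initial resource-B endowment
    11 cons_A  resource A consumed by divisions (ledger)
    12 cons_B  resource B consumed by divisions (ledger)
    13 dec_A   resource A lost to decay (ledger)
    14 dec_B   resource B lost to decay (ledger)
    15 V     virtual (tracer) phage particles in the patch

Medium layout (int64): ``[M_A, M_B, M_G, M_S, M_V]``.

Parameter layout (float64): ``[Y, v, r_A, r_B, K, d, k, sigma, phi, alpha,
lam_p, lam_h, theta, chi, beta, F_A, F_B, cycle_length]``.

Counter layout (int64): ``[inf_GA, inf_GB, inf_SA, v_created, v_succeeded,
v_decayed, events]``.

The 28 event channels are: host arrival (A, B), host division (A, B), host
detachment (A, B), host decay (A, B), resource decay (A, B), phage arrival
(G, S), phage exit (G, S), phage decay (G, S), infection (G+A, G+B, S+A),
and burst / decay / detachment for each of the three infected classes.
Detaching infected cells lyse immediately, releasing a Poisson burst into
the medium.

Virtual tracer particles (the opportunity-cost probe) are simulated in a
separate layer that draws only from a dedicated RNG stream and never alters
real state, so a probe-carrying run consumes exactly the same draws from the
real stream as a probe-free run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_CHANNELS = 28

# counter indices
CNT_INF_GA = 0
CNT_INF_GB = 1
CNT_INF_SA = 2
CNT_V_CREATED = 3
CNT_V_SUCCEEDED = 4
CNT_V_DECAYED = 5
CNT_EVENTS = 6
N_COUNTERS = 7


@njit(cache=False)
def compute_rates(s, m, P, out):
    """Fill ``out`` with the 28 per-patch channel rates; return their sum."""
    xA = s[0]
    xB = s[1]
    A = s[2]
    B = s[3]
    G = s[4]
    S = s[5]
    IGA = s[6]
    IGB = s[7]
    ISA = s[8]
    v = P[1]
    rA = P[2]
    rB = P[3]
    K = P[4]
    d = P[5]
    k = P[6]
    sig = P[7]
    phi = P[8]
    al = P[9]
    lp = P[10]
    lh = P[11]
    th = P[12]
    beta = P[14]

    ddetA = d * k / (k + xA)
    ddetB = d * k / (k + xB)

    out[0] = v * m[0] if xA >= 1 else 0.0          # host A arrives
    out[1] = v * m[1] if xB >= 1 else 0.0          # host B arrives
    out[2] = rA * A * xA / (K + xA) if xA >= 1 else 0.0   # host A divides
    out[3] = rB * B * xB / (K + xB) if xB >= 1 else 0.0   # host B divides
    out[4] = ddetA * A                              # host A detaches
    out[5] = ddetB * B                              # host B detaches
    out[6] = lh * A                                 # host A dies
    out[7] = lh * B                                 # host B dies
    out[8] = sig * xA                               # resource A decays
    out[9] = sig * xB                               # resource B decays
    out[10] = phi * m[2]                            # generalist arrives
    out[11] = phi * m[3]                            # specialist arrives
    out[12] = al * G                                # generalist exits
    out[13] = al * S                                # specialist exits
    out[14] = lp * G                                # generalist decays
    out[15] = lp * S                                # specialist decays
    out[16] = th * G * A                            # G infects A
    out[17] = th * G * B                            # G infects B
    out[18] = th * S * A                            # S infects A
    out[19] = beta * IGA                            # I_GA bursts in patch
    out[20] = beta * IGB                            # I_GB bursts in patch
    out[21] = beta * ISA                            # I_SA bursts in patch
    out[22] = lh * IGA                              # I_GA dies
    out[23] = lh * IGB                              # I_GB dies
    out[24] = lh * ISA                              # I_SA dies
    out[25] = ddetA * IGA                           # I_GA detaches (lyses out)
    out[26] = ddetB * IGB                           # I_GB detaches (lyses out)
    out[27] = ddetA * ISA                           # I_SA detaches (lyses out)

    total = 0.0
    for i in range(N_CHANNELS):
        total += out[i]
    return total


@njit(cache=False)
def _virtual_window(s, m, P, window, spawning, vrng, counters):
    """Simulate the virtual-tracer layer over a window of real inactivity.

    The real state is constant over the window, so tracer dynamics are a
    time-homogeneous competing-risks process: tracers are spawned at
    specialist–host-B contact rate, arrive from the medium, exit, decay, or
    contact a host-A individual (success, absorbing).
    """
    phi = P[8]
    al = P[9]
    lp = P[10]
    th = P[12]
    t = 0.0
    while True:
        A = s[2]
        B = s[3]
        S = s[5]
        V = s[15]
        r_spawn = th * S * B if spawning else 0.0
        r_arrive = phi * m[4]
        r_exit = al * V
        r_decay = lp * V
        r_success = th * V * A
        total = r_spawn + r_arrive + r_exit + r_decay + r_success
        if total <= 0.0:
            return
        t += vrng.exponential(1.0 / total)
        if t >= window:
            return
        u = vrng.random() * total
        if u < r_spawn:
            s[15] += 1
            counters[CNT_V_CREATED] += 1
        elif u < r_spawn + r_arrive:
            m[4] -= 1
            s[15] += 1
        elif u < r_spawn + r_arrive + r_exit:
            s[15] -= 1
            m[4] += 1
        elif u < r_spawn + r_arrive + r_exit + r_decay:
            s[15] -= 1
            counters[CNT_V_DECAYED] += 1
        else:
            s[15] -= 1
            counters[CNT_V_SUCCEEDED] += 1


@njit(cache=False)
def step_patch_kernel(s, m, P, horizon, rng, counters, probe_on, spawning, vrng):
    """Advance one patch by ``horizon`` hours of Gillespie dynamics.

    Mutates ``s`` (patch), ``m`` (medium) and ``counters`` in place.
    When ``probe_on`` the virtual-tracer layer is interleaved between real
    events, drawing only from ``vrng``.
    """
    FA = P[15]
    FB = P[16]
    rates = np.empty(N_CHANNELS)
    t = 0.0
    while True:
        total = compute_rates(s, m, P, rates)
        if total <= 0.0:
            if probe_on:
                _virtual_window(s, m, P, horizon - t, spawning, vrng, counters)
            return
        tau = rng.exponential(1.0 / total)
        if probe_on:
            window = tau if t + tau < horizon else horizon - t
            _virtual_window(s, m, P, window, spawning, vrng, counters)
        t += tau
        if t >= horizon:
            return
        u = rng.random() * total
        c = 0
        acc = rates[0]
        while u >= acc and c < N_CHANNELS - 1:
            c += 1
            acc += rates[c]
        counters[CNT_EVENTS] += 1
        if c == 0:
            m[0] -= 1
            s[2] += 1
        elif c == 1:
            m[1] -= 1
            s[3] += 1
        elif c == 2:
            s[2] += 1
            s[0] -= 1
            s[11] += 1
        elif c == 3:
            s[3] += 1
            s[1] -= 1
            s[12] += 1
        elif c == 4:
            s[2] -= 1
            m[0] += 1
        elif c == 5:
            s[3] -= 1
            m[1] += 1
        elif c == 6:
            s[2] -= 1
        elif c == 7:
            s[3] -= 1
        elif c == 8:
            s[0] -= 1
            s[13] += 1
        elif c == 9:
            s[1] -= 1
            s[14] += 1
        elif c == 10:
            m[2] -= 1
            s[4] += 1
        elif c == 11:
            m[3] -= 1
            s[5] += 1
        elif c == 12:
            s[4] -= 1
            m[2] += 1
        elif c == 13:
            s[5] -= 1
            m[3] += 1
        elif c == 14:
            s[4] -= 1
        elif c == 15:
            s[5] -= 1
        elif c == 16:
            s[4] -= 1
            s[2] -= 1
            s[6] += 1
            counters[CNT_INF_GA] += 1
        elif c == 17:
            s[4] -= 1
            s[3] -= 1
            s[7] += 1
            counters[CNT_INF_GB] += 1
        elif c == 18:
            s[5] -= 1
            s[2] -= 1
            s[8] += 1
            counters[CNT_INF_SA] += 1
        elif c == 19:
            s[6] -= 1
            s[4] += rng.poisson(FA)
        elif c == 20:
            s[7] -= 1
            s[4] += rng.poisson(FB)
        elif c == 21:
            s[8] -= 1
            s[5] += rng.poisson(FA)
        elif c == 22:
            s[6] -= 1
        elif c == 23:
            s[7] -= 1
        elif c == 24:
            s[8] -= 1
        elif c == 25:
            s[6] -= 1
            m[2] += rng.poisson(FA)
        elif c == 26:
            s[7] -= 1
            m[2] += rng.poisson(FB)
        else:
            s[8] -= 1
            m[3] += rng.poisson(FA)


@njit(cache=False)
def cycle_kernel(patches, order, m, P, dt, rng, counters, probe_on, spawning, vrng):
    """Advance every patch (rows of ``patches``) by one cycle, in the given order."""
    for j in range(order.shape[0]):
        step_patch_kernel(
            patches[order[j]], m, P, dt, rng, counters,
            probe_on, spawning, vrng,
        )
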