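"""Low-level fixed-step integrator for the cable and single-cell model.

The membrane is a two-variable excitable system (normalized potential ``v``
and recovery gate ``h``) coupled to a hybrid calcium-cycling subsystem:
cytosolic calcium ``c`` decays exponentially, the sarcoplasmic-reticulum
load ``s`` refills toward 1, and a sigmoidal fraction of ``s`` is released
instantaneously at each upstroke.  The released amount sets the
repolarization time constant of the ongoing action potential, which is how
calcium alternans drives APD alternans.

Everything here is plain float64 arrays so the whole loop can be jitted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the per-cell parameter matrix (one row per cell)
P_TAU_IN = 0
P_TAU_OUT = 1
P_TAU_OPEN = 2
P_TAU_CLOSE = 3
P_V_GATE = 4
P_GAMMA = 5
P_REL_MAX = 6
P_REL_K = 7
P_TAU_REFILL = 8
P_TAU_CA = 9
P_CA_GAIN = 10
P_K_APD = 11
P_REL_REF = 12
P_H_REC_V = 13
N_PARAMS = 14

V_REST_MV = -85.0
V_AMP_MV = 110.0

RELEASE_TRIGGER_V = 0.5
RELEASE_RESET_V = 0.15
APD_FACTOR_LO = 0.35
APD_FACTOR_HI = 1.30


@njit(cache=True)
def step_cable(v, h, c, s, tc, hrv, trig, params, diffusion, dx, dt, t0, n_steps,
               stim_start, stim_dur, stim_lo, stim_hi, stim_amp,
               rec_vm, rec_ca, rec_start_step, rec_every):
    """Advance the cable ``n_steps`` explicit-Euler steps in place.

    Stimuli are rectangular current pulses ``stim_amp`` (1/ms in v-units)
    applied to cells ``[stim_lo, stim_hi)`` while
    ``stim_start <= t < stim_start + stim_dur``; the schedule must be sorted
    by start time.  Membrane potential (mV) and cytosolic calcium are
    sampled every ``rec_every`` steps starting at ``rec_start_step`` into
    the preallocated ``rec_vm`` / ``rec_ca`` (cell x sample).

    Returns 0 on success, or the 1-based step at which a non-finite
    potential was first seen.
    """
    n = v.shape[0]
    inv_dx2 = 1.0 / (dx * dx) if n > 1 else 0.0
    n_stim = stim_start.shape[0]
    k0 = 0
    dv = np.empty(n)
    for step in range(n_steps):
        t = t0 + step * dt
        if step >= rec_start_step and (step - rec_start_step) % rec_every == 0:
            j = (step - rec_start_step) // rec_every
            if j < rec_vm.shape[1]:
                for i in range(n):
                    rec_vm[i, j] = V_REST_MV + V_AMP_MV * v[i]
                    rec_ca[i, j] = c[i]
        # slide the window of active stimuli
        while k0 < n_stim and t >= stim_start[k0] + stim_dur[k0]:
            k0 += 1
        # release events and reaction terms
        for i in range(n):
            vi = v[i]
            if not trig[i]:
                if vi >= RELEASE_TRIGGER_V:
                    si = s[i]
                    rel = params[i, P_REL_MAX] / (
                        1.0 + (params[i, P_REL_K] / si) ** params[i, P_GAMMA])
                    if rel > 0.95 * si:
                        rel = 0.95 * si
                    s[i] = si - rel
                    c[i] = c[i] + params[i, P_CA_GAIN] * rel
                    # sublinear release -> APD coupling: a beat with the
                    # reference release repolarizes at the baseline rate,
                    # and a premature beat with little SR release produces
                    # a strongly abbreviated action potential
                    f = (rel / params[i, P_REL_REF]) ** params[i, P_K_APD]
                    if f < APD_FACTOR_LO:
                        f = APD_FACTOR_LO
                    elif f > APD_FACTOR_HI:
                        f = APD_FACTOR_HI
                    tc[i] = params[i, P_TAU_CLOSE] * f
                    # post-repolarization refractoriness of this beat scales
                    # with its SR release: the large-release (long) beat
                    # leaves the deepest recovery requirement
                    m = rel / params[i, P_REL_REF]
                    if m > 1.0:
                        m = 1.0
                    m = m * m
                    vg = params[i, P_V_GATE]
                    hrv[i] = vg - (vg - params[i, P_H_REC_V]) * m
                    trig[i] = True
            elif vi < RELEASE_RESET_V:
                trig[i] = False
            # membrane reaction
            dvi = (h[i] * vi * vi * (1.0 - vi) / params[i, P_TAU_IN]
                   - vi / params[i, P_TAU_OUT])
            # gate: drains during the action potential and recovers below
            # the per-cell recovery potential; between the two it is frozen.
            # A recovery potential well below the excitation gate models
            # post-repolarization refractoriness: tissue held semi-
            # depolarized (by a neighboring plateau or a stalled wavefront's
            # foot) cannot restore excitability
            if vi >= params[i, P_V_GATE]:
                h[i] = h[i] - dt * h[i] / tc[i]
            elif vi < hrv[i]:
                h[i] = h[i] + dt * (1.0 - h[i]) / params[i, P_TAU_OPEN]
            # calcium
            c[i] = c[i] - dt * c[i] / params[i, P_TAU_CA]
            s[i] = s[i] + dt * (1.0 - s[i]) / params[i, P_TAU_REFILL]
            dv[i] = dvi
        # stimulus currents
        k = k0
        while k < n_stim and stim_start[k] <= t:
            lo = stim_lo[k]
            hi = stim_hi[k]
            for i in range(lo, hi):
                dv[i] += stim_amp[k]
            k += 1
        # diffusion (no-flux boundaries) and state update
        if n > 1:
            dv[0] += diffusion * (v[1] - v[0]) * inv_dx2
            dv[n - 1] += diffusion * (v[n - 2] - v[n - 1]) * inv_dx2
            for i in range(1, n - 1):
                dv[i] += diffusion * (v[i - 1] - 2.0 * v[i] + v[i + 1]) * inv_dx2
        for i in range(n):
            v[i] = v[i] + dt * dv[i]
        if step % 2000 == 0:
            for i in range(n):
                if not np.isfinite(v[i]):
                    return step + 1
    for i in range(n):
        if not np.isfinite(v[i]):
            return n_steps
    return 0
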