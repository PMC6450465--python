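"""Ventricular myocyte model with infarct border-zone and β-adrenergic phenotypes.

The shipped model (``"ca-ms"``) is a phenomenological action-potential model:
a two-variable excitable membrane (normalized potential plus a recovery gate,
mapped to millivolts as ``Vm = -85 + 110 v``) driven by a hybrid two-variable
calcium-cycling subsystem.  At every upstroke a sigmoidal fraction of the
sarcoplasmic-reticulum (SR) load is released into the cytosol; the release
feeds back onto the repolarization time constant, so a beat with a large
calcium transient has a long action potential.  Alternans arises when the
release function is steep relative to the SR refill rate - the classic
calcium-cycling instability - and is therefore a property of the calcium
subsystem, with the membrane following.

Phenotypes
----------
``NZ`` (non-infarcted) cells have efficient SR refill and a moderate release
slope: they are stable at the cycle lengths studied here and only alternate
at very short cycle lengths.  ``BZ`` (infarct border zone) cells have slowed
reuptake/refill, a steeper release function and a longer baseline APD,
placing them inside the alternans window at a 300 ms cycle length but
outside it at 400 ms.

β-adrenergic stimulation (``bar_level`` in [0, 1]) is modeled as a steady
condition: it accelerates SR refill and cytosolic calcium decay (removing
the alternans instability and shortening the calcium transient), mildly
shortens the baseline APD, and reverses the border-zone remodeling of
repolarization (PKA-dependent restoration of calcium handling), so a fully
stimulated BZ cell repolarizes like an NZ cell.

Other equation sets can be registered under a name via
:func:`register_model` and selected anywhere a ``model`` argument appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .features import measure_aps

REFERENCE_BCL_MS = 300.0  # rate at which each phenotype's release is normalized

ZONES = ("NZ", "BZ")


class IntegrationError(RuntimeError):
    """Raised when the integrator produced a non-finite membrane potential."""


@dataclass(frozen=True)
class Phenotype:
    """Cell phenotype: zone identity plus β-adrenergic stimulation level."""

    zone: str = "NZ"
    bar_level: float = 0.0

    def __post_init__(self):
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}, got {self.zone!r}")
        if not 0.0 <= self.bar_level <= 1.0:
            raise ValueError("bar_level must lie in [0, 1]")


@dataclass
class CellState:
    """Instantaneous model state of one cell."""

    vm: float = K.V_REST_MV      # membrane potential, mV
    h: float = 1.0               # recovery gate (1 = fully excitable)
    cai: float = 0.0             # cytosolic calcium above diastole, uM
    sr_load: float = 1.0         # SR content, fraction of full
    tau_close: float = float("nan")  # per-beat repolarization constant, ms
    release_armed: bool = True


@dataclass
class PacingResult:
    """Summary of a constant-rate pacing run of a single cell."""

    bcl: float
    apd90_per_beat: np.ndarray       # ms, recorded tail beats
    cat_amplitude_per_beat: np.ndarray  # uM
    apd_alternans: float             # |APD90 difference of final beat pair|, ms
    captured: np.ndarray             # per recorded stimulus
    times: np.ndarray | None = None
    vm: np.ndarray | None = None
    cai: np.ndarray | None = None
    erp: float | None = None


class PhenomenologicalModel:
    """Default calcium-driven alternans model (name ``"ca-ms"``).

    Parameter units: time constants in ms; release quantities are fractions
    of a full SR; ``ca_gain`` converts released fraction to uM of cytosolic
    calcium.
    """

    name = "ca-ms"

    # membrane (shared)
    tau_in = 0.3
    tau_out = 6.0
    tau_open = {"NZ": 30.0, "BZ": 30.0}
    v_gate = 0.13
    tau_close_nz = 100.0

    # calcium cycling, per zone
    gamma = {"NZ": 24.0, "BZ": 24.0}
    rel_max = {"NZ": 0.6, "BZ": 0.7}
    rel_k = {"NZ": 0.85, "BZ": 0.90}
    tau_refill = {"NZ": 140.0, "BZ": 250.0}
    tau_ca = {"NZ": 45.0, "BZ": 60.0}
    ca_gain = 2.0
    apd_ca_power = 0.40  # exponent of the sublinear SR-release -> APD coupling

    # phenotype modifiers
    bz_apd_remodeling = 0.10   # fractional APD prolongation of BZ at bar 0
    bar_apd_shortening = 0.02  # fractional APD shortening at bar 1
    bar_refill_speedup = 0.55  # fractional reduction of tau_refill at bar 1
    bar_ca_speedup = 0.30      # fractional reduction of tau_ca at bar 1
    #: recovery potential (normalized v) below which the excitability gate
    #: recovers; NZ recovers as soon as the membrane leaves the excited
    #: range, while remodeled BZ requires full repolarization
    #: (post-repolarization refractoriness), a deficit reversed at bar 1
    h_recovery_v = {"NZ": None, "BZ": 0.03}
    bar_recovery_normalization = 1.0  # fraction of the BZ recovery deficit reversed at bar 1

    # stimulus defaults
    stim_amp = 0.5   # 1/ms, normalized-v units
    stim_dur = 2.0   # ms
    dt = 0.02        # ms

    def params_for(self, phenotype: Phenotype) -> np.ndarray:
        """Flat per-cell parameter row for the kernel."""
        z, b = phenotype.zone, phenotype.bar_level
        row = np.empty(K.N_PARAMS)
        row[K.P_TAU_IN] = self.tau_in
        row[K.P_TAU_OUT] = self.tau_out
        row[K.P_TAU_OPEN] = self.tau_open[z]
        tau_close = self.tau_close_nz * (1.0 - self.bar_apd_shortening * b)
        if z == "BZ":
            tau_close *= 1.0 + self.bz_apd_remodeling * (1.0 - b)
        row[K.P_TAU_CLOSE] = tau_close
        row[K.P_V_GATE] = self.v_gate
        row[K.P_GAMMA] = self.gamma[z]
        row[K.P_REL_MAX] = self.rel_max[z]
        row[K.P_REL_K] = self.rel_k[z]
        row[K.P_TAU_REFILL] = self.tau_refill[z] * (1.0 - self.bar_refill_speedup * b)
        row[K.P_TAU_CA] = self.tau_ca[z] * (1.0 - self.bar_ca_speedup * b)
        row[K.P_CA_GAIN] = self.ca_gain
        row[K.P_K_APD] = self.apd_ca_power
        hv = self.h_recovery_v[z]
        if hv is None:
            row[K.P_H_REC_V] = self.v_gate
        else:
            row[K.P_H_REC_V] = (self.v_gate
                                - (self.v_gate - hv)
                                * (1.0 - self.bar_recovery_normalization * b))
        row[K.P_REL_REF] = self._reference_release(row)
        return row

    @staticmethod
    def _reference_release(row: np.ndarray, bcl: float = REFERENCE_BCL_MS,
                           n_beats: int = 300) -> float:
        """Steady-state release at the reference rate, via the beat map.

        Normalizing each phenotype's release to its own steady state at the
        reference cycle length makes the APD feedback read *deviations* of
        release (the alternating component), not absolute calcium load.
        If the map alternates, the mean of the final pair is used.
        """
        rmax, kk, g = row[K.P_REL_MAX], row[K.P_REL_K], row[K.P_GAMMA]
        tau_r = row[K.P_TAU_REFILL]
        decay = math.exp(-bcl / tau_r)
        s = 1.0
        r_prev = r = 0.0
        for _ in range(n_beats):
            r_prev = r
            r = rmax / (1.0 + (kk / s) ** g)
            r = min(r, 0.95 * s)
            s = 1.0 - (1.0 - (s - r)) * decay
        return 0.5 * (r + r_prev)


_MODELS: dict[str, type] = {}


def register_model(cls) -> type:
    """Register an equation set under ``cls.name`` for lookup by string."""
    _MODELS[cls.name] = cls
    return cls


register_model(PhenomenologicalModel)


def get_model(name: str = "ca-ms"):
    """Instantiate a registered model by name."""
    try:
        return _MODELS[name]()
    except KeyError:
        raise KeyError(
            f"no model named {name!r}; available: {sorted(_MODELS)}") from None


def initial_state_arrays(params: np.ndarray):
    """Resting state arrays (v, h, c, s, tau_close, recovery-v, release flag)."""
    n = params.shape[0]
    return (np.zeros(n), np.ones(n), np.zeros(n), np.ones(n),
            params[:, K.P_TAU_CLOSE].copy(), params[:, K.P_V_GATE].copy(),
            np.zeros(n, dtype=np.bool_))


def derivatives(state: CellState, phenotype: Phenotype, i_stim: float = 0.0,
                model: str = "ca-ms") -> dict[str, float]:
    """Continuous right-hand side at ``state`` (release events excluded).

    SR release is an event tied to the upstroke, so it appears as a jump in
    ``cai``/``sr_load`` during integration, not in this vector field.
    Returns time-derivatives of vm (mV/ms), h, cai (uM/ms) and sr_load.
    """
    if not all(np.isfinite([state.vm, state.h, state.cai, state.sr_load])):
        raise IntegrationError("non-finite state")
    row = get_model(model).params_for(phenotype)
    v = (state.vm - K.V_REST_MV) / K.V_AMP_MV
    tc = state.tau_close if np.isfinite(state.tau_close) else row[K.P_TAU_CLOSE]
    dv = (state.h * v * v * (1.0 - v) / row[K.P_TAU_IN]
          - v / row[K.P_TAU_OUT] + i_stim)
    if v >= row[K.P_V_GATE]:
        dh = -state.h / tc
    elif v < row[K.P_V_GATE] - (row[K.P_V_GATE] - row[K.P_H_REC_V]):
        dh = (1.0 - state.h) / row[K.P_TAU_OPEN]
    else:
        dh = 0.0
    return {
        "vm": dv * K.V_AMP_MV,
        "h": dh,
        "cai": -state.cai / row[K.P_TAU_CA],
        "sr_load": (1.0 - state.sr_load) / row[K.P_TAU_REFILL],
    }


def _run_single(params_row, state, t0, duration, stims, dt, sample_ms,
                record_from=0.0):
    """Integrate one cell; returns (times, vm, ca, final-state tuple)."""
    params = params_row.reshape(1, -1)
    v, h, c, s, tc, hrv, trig = state
    n_steps = int(round(duration / dt))
    rec_every = max(int(round(sample_ms / dt)), 1)
    rec_start = int(round(record_from / dt))
    n_samp = (n_steps - rec_start + rec_every - 1) // rec_every if n_steps > rec_start else 0
    rec_vm = np.empty((1, n_samp))
    rec_ca = np.empty((1, n_samp))
    starts = np.array([st[0] for st in stims], dtype=float)
    order = np.argsort(starts, kind="stable")
    stim_start = starts[order]
    stim_dur = np.array([st[1] for st in stims], dtype=float)[order]
    stim_amp = np.array([st[2] for st in stims], dtype=float)[order]
    stim_lo = np.zeros(len(stims), dtype=np.int64)
    stim_hi = np.ones(len(stims), dtype=np.int64)
    status = K.step_cable(v, h, c, s, tc, hrv, trig, params, 0.0, 1.0, dt, t0,
                          n_steps, stim_start, stim_dur, stim_lo, stim_hi,
                          stim_amp, rec_vm, rec_ca, rec_start, rec_every)
    if status != 0:
        raise IntegrationError(f"non-finite potential at step {status}")
    times = t0 + (rec_start + rec_every * np.arange(n_samp)) * dt
    return times, rec_vm[0], rec_ca[0], (v, h, c, s, tc, hrv, trig)


def pace_single_cell(phenotype: Phenotype, bcl: float, n_beats: int = 500, *,
                     model: str = "ca-ms", n_record_beats: int = 8,
                     dt: float | None = None, sample_ms: float = 0.25,
                     keep_traces: bool = False) -> PacingResult:
    """Pace one cell at a fixed cycle length and measure the final beats.

    APD90 is measured per beat from the recorded tail (last
    ``n_record_beats``); ``apd_alternans`` is the absolute APD90 difference
    of the final beat pair.  Beats whose stimulus does not elicit an
    upstroke are flagged as not captured.
    """
    if bcl <= 0:
        raise ValueError("bcl must be positive")
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    n_record_beats = min(n_record_beats, n_beats)
    mdl = get_model(model)
    dt = mdl.dt if dt is None else dt
    row = mdl.params_for(phenotype)
    state = initial_state_arrays(row.reshape(1, -1))
    stims = [(i * bcl, mdl.stim_dur, mdl.stim_amp) for i in range(n_beats)]
    duration = n_beats * bcl
    record_from = (n_beats - n_record_beats) * bcl
    times, vm, ca, state = _run_single(row, state, 0.0, duration, stims, dt,
                                       sample_ms, record_from)
    meas = measure_aps(vm, times)
    stim_times = np.array([s[0] for s in stims if s[0] >= record_from])
    captured = np.array([
        bool(np.any((meas.activation_times >= st) &
                    (meas.activation_times < st + bcl)))
        for st in stim_times])
    apd = meas.apd90
    # per-beat calcium transient amplitude from the recorded tail
    cat = []
    for st in stim_times:
        sel = (times >= st) & (times < st + bcl)
        cat.append(float(ca[sel].max() - ca[sel].min()) if sel.any() else np.nan)
    good = apd[np.isfinite(apd)]
    alt = abs(good[-1] - good[-2]) if good.size >= 2 else np.nan
    return PacingResult(
        bcl=bcl, apd90_per_beat=apd, cat_amplitude_per_beat=np.array(cat),
        apd_alternans=float(alt), captured=captured,
        times=times if keep_traces else None,
        vm=vm if keep_traces else None,
        cai=ca if keep_traces else None)


ERP_BEYOND_RANGE = float("inf")


def measure_erp(phenotype: Phenotype, bcl: float, *, model: str = "ca-ms",
                n_prepace: int = 50, scan: tuple[float, float] = (60.0, 400.0),
                step: float = 1.0, dt: float | None = None,
                amplitude_fraction: float = 0.8) -> float:
    """Effective refractory period by an S1-S2 scan on a single cell.

    After ``n_prepace`` S1 beats, an S2 is delivered at increasing coupling
    intervals (1 ms grid by default); the ERP is the shortest interval whose
    S2 elicits an action potential with amplitude at least
    ``amplitude_fraction`` of the steady S1 amplitude.  Returns ``inf`` if
    no interval in the scan range captures.
    """
    mdl = get_model(model)
    dt = mdl.dt if dt is None else dt
    row = mdl.params_for(phenotype)
    state = initial_state_arrays(row.reshape(1, -1))
    # pre-pace up to (but not including) the final S1
    stims = [(i * bcl, mdl.stim_dur, mdl.stim_amp) for i in range(n_prepace - 1)]
    t_last_s1 = (n_prepace - 1) * bcl
    times, vm, _, state = _run_single(row, state, 0.0, t_last_s1, stims, dt,
                                      sample_ms=0.5,
                                      record_from=max(0.0, t_last_s1 - 2 * bcl))
    s1_meas = measure_aps(vm, times)
    s1_amp = float(np.nanmean(s1_meas.peaks - s1_meas.takeoff))
    snapshot = tuple(a.copy() for a in state)
    lo, hi = scan
    ci = lo
    while ci <= hi + 1e-9:
        st = tuple(a.copy() for a in snapshot)
        stims2 = [(t_last_s1, mdl.stim_dur, mdl.stim_amp),
                  (t_last_s1 + ci, mdl.stim_dur, mdl.stim_amp)]
        t2, vm2, _, _ = _run_single(row, st, t_last_s1, ci + 300.0, stims2,
                                    dt, sample_ms=0.5)
        m2 = measure_aps(vm2, t2)
        t_s2 = t_last_s1 + ci
        # a captured S2 is a *new* upstroke after the S2 time whose amplitude
        # approaches the steady S1 amplitude; the ongoing S1 plateau does not
        # re-arm the detector and so cannot masquerade as capture
        for k, ta in enumerate(m2.activation_times):
            if ta >= t_s2 - 1.0 and \
                    (m2.peaks[k] - m2.takeoff[k]) >= amplitude_fraction * s1_amp:
                return float(ci)
        ci += step
    return ERP_BEYOND_RANGE


def apd_restitution(phenotype: Phenotype, bcls, *, model: str = "ca-ms",
                    n_beats: int = 120, **kw) -> dict[float, float]:
    """Mean APD90 of the final beat pair at each cycle length."""
    out = {}
    for bcl in bcls:
        res = pace_single_cell(phenotype, bcl, n_beats, model=model, **kw)
        good = res.apd90_per_beat[np.isfinite(res.apd90_per_beat)]
        out[float(bcl)] = float(np.mean(good[-2:])) if good.size >= 2 else np.nan
    return out


def alternans_onset_bcl(phenotype: Phenotype, bcls=None, *, model: str = "ca-ms",
                        n_beats: int = 200, threshold_ms: float = 1.0) -> float:
    """Longest tested cycle length with APD alternans >= ``threshold_ms``.

    Returns ``-inf`` if no tested cycle length alternates.
    """
    if bcls is None:
        bcls = np.arange(120.0, 420.0, 20.0)
    onset = -float("inf")
    for bcl in sorted(bcls):
        res = pace_single_cell(phenotype, float(bcl), n_beats, model=model)
        if np.isfinite(res.apd_alternans) and res.apd_alternans >= threshold_ms \
                and bool(res.captured.all()):
            onset = max(onset, float(bcl))
    return onset
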