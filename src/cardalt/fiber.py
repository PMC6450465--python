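"""1D monodomain cable of NZ/BZ myocytes with S1 pacing and S2 extrastimuli.

The cable is a reaction-diffusion chain with no-flux ends,

    dv/dt = f(v, h; cell) + D (v_{i-1} - 2 v_i + v_{i+1}) / dx^2,

integrated with the same explicit fixed-step kernel as the single cell.
The default geometry is a 240-cell fiber with the border zone occupying
cells 80-159 (``NZ-BZ-NZ``), S1 delivered to the five leftmost cells.
The diffusion coefficient default is calibrated so a plane wave in
non-infarcted tissue travels at ~0.05 cm/ms.

``run_prepace`` conditions the fiber for a number of beats and snapshots the
full state immediately before each of the last two S1 stimuli: S2 protocols
restart from one of those snapshots, which pins the beat parity (the beat
with the long or the short APD during alternans) that the extrastimulus
follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .cellmodel import (IntegrationError, Phenotype, get_model,
                        initial_state_arrays)
from .features import measure_aps

#: chosen so the NZ plane wave travels at ~0.036 cm/ms at dx = 0.01 cm --
#: physiological for ventricular muscle while keeping the electrotonic
#: space constant short enough that border-zone APD alternans stays
#: spatially confined in the default 240-cell geometry (docs/methods.md)
DEFAULT_DIFFUSION = 1.2e-3  # cm^2/ms

COMPOSITIONS = ("NZ-BZ-NZ", "NZ")


@dataclass(frozen=True)
class FiberConfig:
    """Geometry, composition and pacing of one cable experiment."""

    n_cells: int = 240
    composition: str = "NZ-BZ-NZ"
    bz_range: tuple[int, int] = (80, 160)   # [lo, hi), used for NZ-BZ-NZ
    diffusion: float = DEFAULT_DIFFUSION    # cm^2/ms
    dx: float = 0.01                        # cm
    dt: float = 0.02                        # ms
    s1_cells: tuple[int, int] = (0, 5)      # [lo, hi)
    bcl: float = 300.0                      # ms
    n_prepace_beats: int = 500
    bar_level: float = 0.0
    model: str = "ca-ms"

    def __post_init__(self):
        if self.composition not in COMPOSITIONS:
            raise ValueError(f"composition must be one of {COMPOSITIONS}")
        if min(self.diffusion, self.dx, self.dt) <= 0:
            raise ValueError("diffusion, dx and dt must be positive")
        lo, hi = self.s1_cells
        if not (0 <= lo < hi <= self.n_cells):
            raise ValueError("s1_cells out of bounds")
        if self.composition == "NZ-BZ-NZ":
            blo, bhi = self.bz_range
            if not (0 < blo < bhi < self.n_cells):
                raise ValueError("bz_range must lie strictly inside the fiber")

    def phenotypes(self) -> list[Phenotype]:
        ph = [Phenotype("NZ", self.bar_level)] * self.n_cells
        if self.composition == "NZ-BZ-NZ":
            lo, hi = self.bz_range
            ph[lo:hi] = [Phenotype("BZ", self.bar_level)] * (hi - lo)
        return ph

    def bz_cells(self) -> np.ndarray:
        mask = np.zeros(self.n_cells, dtype=bool)
        if self.composition == "NZ-BZ-NZ":
            lo, hi = self.bz_range
            mask[lo:hi] = True
        return mask

    def param_matrix(self) -> np.ndarray:
        mdl = get_model(self.model)
        rows = {}
        out = np.empty((self.n_cells, K.N_PARAMS))
        for i, ph in enumerate(self.phenotypes()):
            if ph not in rows:
                rows[ph] = mdl.params_for(ph)
            out[i] = rows[ph]
        return out


@dataclass
class FiberState:
    """Full cable state at an instant (copies of the integrator arrays)."""

    t: float
    v: np.ndarray
    h: np.ndarray
    c: np.ndarray
    s: np.ndarray
    tau_close: np.ndarray
    h_recovery_v: np.ndarray
    release_flag: np.ndarray

    def copy(self) -> "FiberState":
        return FiberState(self.t, *(a.copy() for a in (
            self.v, self.h, self.c, self.s, self.tau_close,
            self.h_recovery_v, self.release_flag)))

    def arrays(self):
        return (self.v, self.h, self.c, self.s, self.tau_close,
                self.h_recovery_v, self.release_flag)


@dataclass
class FiberRecording:
    """Spatio-temporal record of a cable run.

    ``vm`` is (cell x sample) in mV; ``stim_times`` are the S1 onsets inside
    the recorded window (absolute ms); ``s2_time`` is set by S2 protocols.
    ``activation_times`` holds every detected upstroke per cell;
    ``apd90`` holds one row per cell aligned with ``stim_times`` beats
    (NaN where a beat did not capture or never repolarized in-window).
    """

    config: FiberConfig
    times: np.ndarray
    vm: np.ndarray
    cai: np.ndarray
    stim_times: np.ndarray
    activation_times: list[np.ndarray]
    apd90: np.ndarray
    snapshots: list[FiberState] = field(default_factory=list)
    s2_time: float | None = None
    bz_long_beat: int | None = None

    def apd_alternans_per_cell(self) -> np.ndarray:
        """|APD90 difference| of the final recorded beat pair, per cell."""
        if self.apd90.shape[1] < 2:
            raise ValueError("need at least two recorded beats")
        return np.abs(self.apd90[:, -1] - self.apd90[:, -2])

    def activated_after(self, t: float) -> np.ndarray:
        """Boolean mask of cells with an upstroke strictly after ``t``."""
        return np.array([np.any(a > t) for a in self.activation_times])


def _run_chunk(params, state: FiberState, duration, stims, config: FiberConfig,
               sample_ms=1.0, record=True):
    """Advance ``state`` in place by ``duration``; return (times, vm, cai)."""
    dt = config.dt
    n_steps = int(round(duration / dt))
    rec_every = max(int(round(sample_ms / dt)), 1)
    if record and n_steps > 0:
        n_samp = (n_steps + rec_every - 1) // rec_every
    else:
        n_samp = 0
    rec_vm = np.empty((config.n_cells, n_samp))
    rec_ca = np.empty((config.n_cells, n_samp))
    stims = sorted(stims, key=lambda st: st[0])
    stim_start = np.array([st[0] for st in stims], dtype=float)
    stim_dur = np.array([st[1] for st in stims], dtype=float)
    stim_lo = np.array([st[2] for st in stims], dtype=np.int64)
    stim_hi = np.array([st[3] for st in stims], dtype=np.int64)
    stim_amp = np.array([st[4] for st in stims], dtype=float)
    rec_start = 0 if record else n_steps + 1
    status = K.step_cable(state.v, state.h, state.c, state.s,
                          state.tau_close, state.h_recovery_v,
                          state.release_flag, params,
                          config.diffusion, config.dx, dt, state.t, n_steps,
                          stim_start, stim_dur, stim_lo, stim_hi, stim_amp,
                          rec_vm, rec_ca, rec_start, rec_every)
    if status != 0:
        bad = int(np.argmax(~np.isfinite(state.v)))
        raise IntegrationError(
            f"non-finite membrane potential at cell {bad}, "
            f"t ~ {state.t + status * dt:.2f} ms")
    times = state.t + rec_every * dt * np.arange(n_samp)
    state.t += n_steps * dt
    return times, rec_vm, rec_ca


def _annotate(config, times, vm, stim_times):
    """Per-cell activations and per-beat APD90 aligned to S1 onsets."""
    n_beats = len(stim_times)
    acts = []
    apd = np.full((config.n_cells, n_beats), np.nan)
    for i in range(config.n_cells):
        m = measure_aps(vm[i], times)
        acts.append(m.activation_times)
        for k, st in enumerate(stim_times):
            in_beat = (m.activation_times >= st) & (m.activation_times < st + config.bcl)
            if in_beat.any():
                apd[i, k] = m.apd90[int(np.argmax(in_beat))]
    return acts, apd


def run_prepace(config: FiberConfig, *, n_record_beats: int = 2,
                sample_ms: float = 1.0) -> FiberRecording:
    """Pace the fiber for ``config.n_prepace_beats`` S1 beats.

    Returns the final ``n_record_beats`` beats fully recorded, per-cell
    activation/APD annotations, and state snapshots taken immediately before
    each of the last two S1 stimuli.  For an alternating fiber,
    ``bz_long_beat`` indexes the snapshot whose following beat carries the
    long APD in the (central) zone of interest.
    """
    n_beats = config.n_prepace_beats
    if n_beats < 2:
        raise ValueError("need at least 2 pre-pacing beats")
    n_record_beats = min(max(n_record_beats, 2), n_beats)
    mdl = get_model(config.model)
    params = config.param_matrix()
    state = FiberState(0.0, *initial_state_arrays(params))
    lo, hi = config.s1_cells
    bcl = config.bcl

    def s1(k):
        return (k * bcl, mdl.stim_dur, lo, hi, mdl.stim_amp)

    n_head = n_beats - n_record_beats
    snap_beats = (n_beats - 2, n_beats - 1)
    snapshots = []
    all_t, all_vm, all_ca = [], [], []
    beat = 0
    while beat < n_beats:
        if beat in snap_beats:
            snapshots.append(state.copy())
        nxt = min(b for b in (*snap_beats, n_beats) if b > beat)
        stims = [s1(k) for k in range(beat, nxt)]
        record = beat >= n_head
        t, vm, ca = _run_chunk(params, state, (nxt - beat) * bcl, stims,
                               config, sample_ms, record=record)
        if record:
            all_t.append(t)
            all_vm.append(vm)
            all_ca.append(ca)
        beat = nxt
    times = np.concatenate(all_t)
    vm = np.concatenate(all_vm, axis=1)
    cai = np.concatenate(all_ca, axis=1)
    stim_times = np.array([k * bcl for k in range(n_head, n_beats)])
    acts, apd = _annotate(config, times, vm, stim_times)
    rec = FiberRecording(config=config, times=times, vm=vm, cai=cai,
                         stim_times=stim_times, activation_times=acts,
                         apd90=apd, snapshots=snapshots)
    zone = config.bz_cells()
    if not zone.any():
        zone = np.ones(config.n_cells, dtype=bool)
    sub = apd[zone][:, -2:]
    pair = np.array([np.nan, np.nan])
    for j in range(2):
        col = sub[:, j]
        if np.isfinite(col).any():
            pair[j] = np.nanmean(col)
    if np.all(np.isfinite(pair)):
        rec.bz_long_beat = int(np.argmax(pair))
    return rec


def apply_s2(state: FiberState, config: FiberConfig,
             s2_cells: tuple[int, int], ci: float, *,
             post_ms: float = 400.0, sample_ms: float = 1.0) -> FiberRecording:
    """Deliver the final S1 plus one S2 at coupling interval ``ci``.

    ``state`` must be a snapshot taken immediately before an S1 (as produced
    by :func:`run_prepace`); time is re-zeroed at that S1, so the coupling
    interval is measured from the S1 stimulus of the preceding beat.  The
    recording extends ``post_ms`` past the S2.
    """
    lo2, hi2 = s2_cells
    if not (0 <= lo2 < hi2 <= config.n_cells):
        raise ValueError("s2_cells out of bounds")
    if ci <= 0:
        raise ValueError("coupling interval must be positive")
    mdl = get_model(config.model)
    params = config.param_matrix()
    st = state.copy()
    st.t = 0.0
    lo, hi = config.s1_cells
    stims = [(0.0, mdl.stim_dur, lo, hi, mdl.stim_amp),
             (ci, mdl.stim_dur, lo2, hi2, mdl.stim_amp)]
    times, vm, ca = _run_chunk(params, st, ci + post_ms, stims, config,
                               sample_ms)
    stim_times = np.array([0.0])
    acts, apd = _annotate(config, times, vm, stim_times)
    return FiberRecording(config=config, times=times, vm=vm, cai=ca,
                          stim_times=stim_times, activation_times=acts,
                          apd90=apd, s2_time=ci)


def conduction_velocity(recording: FiberRecording,
                        cells: tuple[int, int] | None = None,
                        beat: int = 0) -> float:
    """Plane-wave speed (cm/ms) from a linear fit of activation time vs x.

    Uses the activation of beat ``beat`` (indexed into ``stim_times``) for
    every cell in ``cells`` ([lo, hi), default: whole fiber minus the
    stimulated segment).  Raises if any cell in range failed to activate.
    """
    cfg = recording.config
    if cells is None:
        cells = (cfg.s1_cells[1], cfg.n_cells)
    lo, hi = cells
    st = recording.stim_times[beat]
    t_next = (recording.stim_times[beat + 1]
              if beat + 1 < len(recording.stim_times) else np.inf)
    t_act = np.full(hi - lo, np.nan)
    for j, i in enumerate(range(lo, hi)):
        a = recording.activation_times[i]
        sel = (a >= st) & (a < t_next)
        if sel.any():
            t_act[j] = a[sel][0]
    if not np.all(np.isfinite(t_act)):
        raise ValueError("propagation did not reach every cell in range")
    x = cfg.dx * np.arange(lo, hi)
    slope = np.polyfit(x, t_act, 1)[0]
    if slope == 0:
        return float("inf")
    return float(abs(1.0 / slope))
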