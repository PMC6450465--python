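"""Synthetic dual-channel mapping movies with known alternans ground truth.

The generator emulates the alternans-mapping recordings the analysis
pipeline consumes: a 32x32-pixel, 1 kHz, 1 s movie per pacing rate, with a
calcium transient per beat whose amplitude alternates as ``a (1 + s)`` /
``a (1 - s)`` around the pixel's mean, where ``s`` is the pixel's signed
alternans field.  The true normalized alternans magnitude of every pixel is
therefore exactly ``|s|``, which makes every stage of the pipeline testable
against programmed truth.  A voltage channel with in-phase APD alternans is
generated alongside (calcium alternans drives APD alternans).

Each beat's transient has compact support: the exponential decay is tapered
smoothly to baseline before the next stimulus, so consecutive beats do not
overlap and measured amplitudes are exactly proportional to the programmed
ones.  Border-zone pixels use a longer decay time constant, emulating the
prolonged CaTD90 of remodeled tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mapping import MappingMovie

DEFAULT_BCL_LADDER = (140.0, 130.0, 120.0, 110.0, 100.0, 95.0, 90.0, 85.0, 80.0)

#: (alternans magnitude scale, decay-tau scale) applied per perfusion
#: condition: norepinephrine attenuates alternans (median 60%) and shortens
#: the calcium transient; metoprolol blocks both effects.
CONDITION_EFFECTS = {
    "control": (1.0, 1.0),
    "NE": (0.4, 0.90),
    "NE+Meto": (0.95, 1.0),
}

TAPER_END_MS = 10.0    # transient reaches baseline this long before the next beat
TAPER_LEN_MS = 10.0


@dataclass(frozen=True)
class TransientTemplate:
    """Shape of one calcium transient.

    ``upstroke_shape`` is the exponent of the half-cosine rise (1 = plain
    half-cosine); higher values sharpen the foot of the upstroke.
    """

    time_to_peak: float = 15.0     # ms
    decay_tau: float = 25.0        # ms
    amplitude: float = 1.0         # a.u.
    baseline: float = 0.0          # a.u.
    upstroke_shape: float = 1.0

    def __post_init__(self):
        if self.time_to_peak <= 0 or self.decay_tau <= 0 or self.amplitude <= 0:
            raise ValueError("time_to_peak, decay_tau and amplitude must be "
                             "positive")

    def catd(self, recovery_level: float = 0.9,
             duration: float | None = None) -> float:
        """Closed-form onset-to-recovery duration (ms); NaN if the taper
        truncates the decay before the level is reached."""
        t = self.time_to_peak + self.decay_tau * math.log(1.0 / (1.0 - recovery_level))
        if duration is not None and t > duration - TAPER_END_MS - TAPER_LEN_MS:
            return float("nan")
        return t


def make_transient(template: TransientTemplate, beat_amplitude: float,
                   duration: float, frame_rate: float) -> np.ndarray:
    """Sample one beat: half-cosine rise, tapered exponential decay.

    Starts at baseline, peaks at ``baseline + beat_amplitude`` at
    ``time_to_peak``, decays with ``decay_tau`` and is tapered to baseline
    over the last stretch of the window.  A zero amplitude gives a flat
    trace at baseline.
    """
    if beat_amplitude < 0:
        raise ValueError("beat amplitude must be non-negative")
    if duration <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame_rate must be positive")
    if duration < template.time_to_peak:
        raise ValueError("duration shorter than time_to_peak")
    n = int(round(duration * frame_rate / 1000.0))
    t = np.arange(n) * (1000.0 / frame_rate)
    return template.baseline + beat_amplitude * _shape(template, t, duration)


def _shape(template: TransientTemplate, t: np.ndarray,
           duration: float) -> np.ndarray:
    """Unit-amplitude transient shape on time grid ``t`` (ms)."""
    tp = template.time_to_peak
    rise = (0.5 - 0.5 * np.cos(np.pi * np.clip(t, 0, tp) / tp)) \
        ** template.upstroke_shape
    decay = np.exp(-np.clip(t - tp, 0, None) / template.decay_tau)
    y = np.where(t < tp, rise, decay)
    t1 = duration - TAPER_END_MS
    t0 = t1 - TAPER_LEN_MS
    taper = np.ones_like(t)
    ramp = (t >= t0) & (t < t1)
    taper[ramp] = 0.5 + 0.5 * np.cos(np.pi * (t[ramp] - t0) / (t1 - t0))
    taper[t >= t1] = 0.0
    return y * taper


@dataclass
class AlternansField:
    """Programmed per-pixel signed alternans plus the BZ geometry."""

    signed_magnitude: np.ndarray
    bz_mask: np.ndarray
    nodal_geometry: np.ndarray | None = None   # nodal column per row, if any

    def __post_init__(self):
        self.signed_magnitude = np.asarray(self.signed_magnitude, dtype=float)
        self.bz_mask = np.asarray(self.bz_mask, dtype=bool)
        if np.any(np.abs(self.signed_magnitude) > 1):
            raise ValueError("|signed_magnitude| must not exceed 1")
        if self.bz_mask.shape != self.signed_magnitude.shape:
            raise ValueError("bz_mask shape mismatch")


@dataclass(frozen=True)
class SyntheticProtocolConfig:
    """Acquisition geometry and pacing ladder of the synthetic protocol."""

    bcl_list: tuple[float, ...] = DEFAULT_BCL_LADDER
    paced_duration_per_bcl: float = 10.0   # s
    recorded_duration: float = 1.0         # s
    frame_rate: float = 1000.0             # Hz
    grid: tuple[int, int] = (32, 32)
    fov: tuple[float, float] = (7.0, 7.0)  # mm
    noise_sd: float = 0.05                 # fraction of mean beat amplitude
    seed: int = 0

    def __post_init__(self):
        if self.recorded_duration > self.paced_duration_per_bcl:
            raise ValueError("cannot record longer than the paced duration")
        frames = self.frame_rate * self.recorded_duration
        if abs(frames - round(frames)) > 1e-9:
            raise ValueError("frame_rate x recorded_duration must be integer")
        if min(self.grid) <= 0 or min(self.fov) <= 0:
            raise ValueError("grid and fov must be positive")


def make_bz_mask(grid: tuple[int, int], fraction: float = 0.4,
                 curved: bool = True) -> np.ndarray:
    """One connected border-zone region covering ``fraction`` of the grid.

    The BZ occupies the left part of the field with a straight or gently
    curved boundary, as when the imaging field spans the infarct border
    zone and the adjacent non-infarcted myocardium.
    """
    rows, cols = grid
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    edge = fraction * cols
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    if curved:
        boundary = edge + 0.15 * cols * np.sin(2 * np.pi * rr / rows)
    else:
        boundary = np.full((rows, 1), edge)
    return cc < boundary


def make_uniform_field(grid: tuple[int, int], s_bz: float, s_nz: float,
                       bz_mask: np.ndarray | None = None) -> AlternansField:
    """Uniform signed alternans per zone (concordant pattern)."""
    bz_mask = make_bz_mask(grid) if bz_mask is None else np.asarray(bz_mask)
    s = np.where(bz_mask, s_bz, s_nz).astype(float)
    return AlternansField(signed_magnitude=s, bz_mask=bz_mask)


def make_discordant_field(grid: tuple[int, int], nodal_line,
                          peak_magnitude: float, width: float = 4.0,
                          bz_mask: np.ndarray | None = None) -> AlternansField:
    """Two zones of opposite alternans phase separated by a nodal line.

    ``nodal_line`` gives the nodal column for each row: a scalar (vertical
    line), a callable ``row -> column``, or an array of per-row columns.
    The signed magnitude is ``peak * tanh(d / width)`` with ``d`` the signed
    column distance from the line, so it tapers continuously through zero.
    """
    rows, cols = grid
    if not 0 < peak_magnitude <= 1:
        raise ValueError("peak_magnitude must lie in (0, 1]")
    if callable(nodal_line):
        nodal = np.array([float(nodal_line(r)) for r in range(rows)])
    else:
        nodal = np.broadcast_to(np.asarray(nodal_line, dtype=float),
                                (rows,)).copy()
    if np.any(nodal < 0) or np.any(nodal > cols - 1):
        raise ValueError("nodal line leaves the grid")
    cc = np.arange(cols)[None, :]
    s = peak_magnitude * np.tanh((cc - nodal[:, None]) / width)
    bz_mask = make_bz_mask(grid) if bz_mask is None else np.asarray(bz_mask)
    return AlternansField(signed_magnitude=s, bz_mask=bz_mask,
                          nodal_geometry=nodal)


def synthesize_movie(config: SyntheticProtocolConfig, field: AlternansField,
                     template: TransientTemplate | None = None, *,
                     bcl: float | None = None, condition: str = "control",
                     bz_decay_factor: float = 1.3, include_voltage: bool = True,
                     parity: int = 0, rng: np.random.Generator | None = None
                     ) -> tuple[MappingMovie, dict]:
    """Render one recording (one pacing rate, one condition) plus its truth.

    Even-indexed beats have amplitude ``a (1 + s)`` and odd beats
    ``a (1 - s)`` (``parity=1`` swaps them), so the true NAM is ``|s|``
    exactly.  Gaussian noise with SD ``noise_sd x a`` is added per frame
    per pixel.  BZ pixels decay ``bz_decay_factor`` slower (prolonged
    CaTD90); the perfusion condition scales alternans magnitude and decay.
    """
    template = template or TransientTemplate()
    bcl = float(config.bcl_list[0] if bcl is None else bcl)
    if field.signed_magnitude.shape != tuple(config.grid):
        raise ValueError("field grid does not match config grid")
    alt_scale, tau_scale = CONDITION_EFFECTS[condition]
    s = field.signed_magnitude * alt_scale
    rows, cols = config.grid
    n_frames = int(round(config.frame_rate * config.recorded_duration))
    dt = 1000.0 / config.frame_rate
    total_ms = n_frames * dt
    pacing = np.arange(0.0, total_ms - 1e-9, bcl)
    rng = np.random.default_rng(config.seed) if rng is None else rng

    taus = np.where(field.bz_mask, template.decay_tau * bz_decay_factor,
                    template.decay_tau) * tau_scale
    ca = np.full((rows, cols, n_frames), template.baseline, dtype=float)
    t_beat = np.arange(int(round(bcl / dt))) * dt
    shapes = {}
    for tau in np.unique(taus):
        shapes[tau] = _shape(replace(template, decay_tau=float(tau)),
                             t_beat, bcl)
    catd_truth = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            tpl = replace(template, decay_tau=float(taus[r, c]))
            catd_truth[r, c] = tpl.catd(duration=bcl)
    for k, t0 in enumerate(pacing):
        amp = template.amplitude * (1 + s if (k + parity) % 2 == 0 else 1 - s)
        i0 = int(round(t0 / dt))
        i1 = min(i0 + t_beat.size, n_frames)
        for tau, shp in shapes.items():
            sel = taus == tau
            ca[sel, i0:i1] += np.outer(amp[sel], shp[: i1 - i0])
    if config.noise_sd > 0:
        ca = ca + rng.normal(0.0, config.noise_sd * template.amplitude,
                             ca.shape)

    voltage = None
    if include_voltage:
        voltage = _voltage_channel(s, pacing, bcl, n_frames, dt, parity)
        if config.noise_sd > 0:
            voltage = voltage + rng.normal(0.0, config.noise_sd,
                                           voltage.shape)

    movie = MappingMovie(calcium=ca, voltage=voltage,
                         frame_rate=config.frame_rate, pacing_times=pacing,
                         bcl=bcl, bz_mask=field.bz_mask,
                         condition_label=condition)
    truth = {
        "signed": s.copy(),
        "nam": np.abs(s),
        "catd90_ms": catd_truth,
        "amplitude": template.amplitude,
        "bcl": bcl,
        "condition": condition,
    }
    return movie, truth


def _voltage_channel(s, pacing, bcl, n_frames, dt, parity) -> np.ndarray:
    """Square-ish action potentials whose APD alternates in phase with s."""
    rows, cols = s.shape
    v = np.zeros((rows, cols, n_frames))
    t_beat = np.arange(int(round(bcl / dt))) * dt
    apd_base = 0.6 * bcl
    for k, t0 in enumerate(pacing):
        sign = 1.0 if (k + parity) % 2 == 0 else -1.0
        apd = apd_base * (1 + 0.3 * sign * s)
        i0 = int(round(t0 / dt))
        i1 = min(i0 + t_beat.size, n_frames)
        tt = t_beat[: i1 - i0][None, None, :]
        up = 1.0 / (1.0 + np.exp(-(tt - 2.0) / 0.5))
        down = 1.0 / (1.0 + np.exp((tt - apd[:, :, None]) / 3.0))
        v[:, :, i0:i1] += up * down
    return v


def make_correlated_hearts(n_hearts: int = 10, slope: float = 0.004,
                           intercept: float = -0.15, noise_sd: float = 0.03,
                           catd_range: tuple[float, float] = (60.0, 110.0),
                           conditions=("control", "NE", "NE+Meto"),
                           seed: int = 0) -> pd.DataFrame:
    """Synthetic heart-level data with a programmed linear CaTD90-NAM link.

    One row per heart x condition: a slow-pacing CaTD90 (ms) and a
    fast-pacing alternans magnitude generated as
    ``clip(intercept + slope * catd90 + noise, 0, 1)``.  Used to exercise
    regression recovery.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for h in range(n_hearts):
        for cond in conditions:
            catd = rng.uniform(*catd_range)
            if cond == "NE":
                catd *= 0.9
            nam = intercept + slope * catd + rng.normal(0.0, noise_sd)
            recs.append({"heart": h, "condition": cond,
                         "catd90_ms": catd, "nam": float(np.clip(nam, 0, 1))})
    return pd.DataFrame(recs)
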