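"""Per-pixel alternans analysis of dual-channel optical-mapping movies.

The central statistic is the normalized alternans magnitude (NAM) of a
pixel: with *A* the mean calcium-transient amplitude of even-indexed beats
and *B* that of odd-indexed beats,

    NAM = |A - B| / (A + B),

a dimensionless measure independent of absolute fluorescence.  The signed
variant ``(A - B)/(A + B)`` carries the alternans phase relative to the
first recorded stimulus; discordant regions differ in its sign and are
separated by nodal lines where it crosses zero.  APD alternans is defined
identically with per-beat action-potential durations in place of
amplitudes.

Beat parity is anchored to the first stimulus of the recording, so phase is
reported relative to that (arbitrary) anchor and is sign-symmetric: shifting
the anchor by one beat negates every signed value and leaves NAM unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal, stats
from skimage import measure as _sk_measure


class InsufficientBeatsError(ValueError):
    """Fewer than two complete beats in the recording."""


class EmptyZoneError(ValueError):
    """A region summary was requested for a zone with no valid pixels."""


@dataclass
class MappingMovie:
    """Dual-channel fluorescence stack with acquisition metadata.

    ``calcium`` (and optionally ``voltage``) are (rows, cols, frames)
    arrays in arbitrary fluorescence units; ``pacing_times`` are stimulus
    onsets in ms within the recorded window.
    """

    calcium: np.ndarray
    frame_rate: float               # Hz
    pacing_times: np.ndarray        # ms
    bcl: float                      # ms
    voltage: np.ndarray | None = None
    bz_mask: np.ndarray | None = None
    condition_label: str = "control"

    def __post_init__(self):
        self.calcium = np.asarray(self.calcium, dtype=float)
        self.pacing_times = np.asarray(self.pacing_times, dtype=float)
        if self.calcium.ndim != 3:
            raise ValueError("calcium stack must be (rows, cols, frames)")
        if np.any(np.diff(self.pacing_times) <= 0):
            raise ValueError("pacing_times must be strictly increasing")
        if self.bz_mask is not None:
            self.bz_mask = np.asarray(self.bz_mask, dtype=bool)
            if self.bz_mask.shape != self.calcium.shape[:2]:
                raise ValueError("bz_mask shape must match the pixel grid")

    @property
    def grid(self) -> tuple[int, int]:
        return self.calcium.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.calcium.shape[2]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.frame_rate


@dataclass
class BeatWindow:
    """Index range of one beat, with pre-stimulus context for the baseline."""

    start: int          # sample index of the stimulus onset
    stop: int           # exclusive end of the pacing interval
    pre_start: int      # start of the pre-stimulus baseline context

    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class AnalysisSettings:
    """Preprocessing and quality-control knobs of the pipeline.

    Defaults: per-pixel linear detrend, 3x3 spatial mean filter, 3-frame
    temporal mean filter, pixels valid when the mean beat amplitude exceeds
    ``snr_k`` times the per-pixel noise estimate, and nodal lines traced
    only where a neighboring pixel reaches ``nodal_nam_floor``.
    """

    detrend: bool = True
    spatial_kernel: int = 3
    temporal_kernel: int = 3
    snr_k: float = 5.0
    nodal_nam_floor: float = 0.05
    recovery_level: float = 0.9
    baseline_pre_ms: float = 10.0

    @classmethod
    def raw(cls) -> "AnalysisSettings":
        """No filtering or detrending; used for exactness checks."""
        return cls(detrend=False, spatial_kernel=1, temporal_kernel=1)


@dataclass
class AlternansMap:
    """Per-pixel alternans statistics of one recording."""

    nam: np.ndarray                 # in [0, 1], NaN on invalid pixels
    signed: np.ndarray              # sign = phase vs even beats
    valid_mask: np.ndarray
    nodal_lines: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        ok = self.valid_mask
        if not np.allclose(self.nam[ok], np.abs(self.signed[ok]),
                           equal_nan=True):
            raise ValueError("nam must equal |signed| on valid pixels")


@dataclass
class RecordingSummary:
    """Zone-level aggregates of one recording (valid pixels only)."""

    mean_nam_total: float
    mean_nam_bz: float
    mean_nam_nz: float
    bz_nz_ratio: float
    catd90_bz: float
    catd90_nz: float
    condition: str = "control"
    bcl: float = float("nan")

    _numeric = ("mean_nam_total", "mean_nam_bz", "mean_nam_nz",
                "bz_nz_ratio", "catd90_bz", "catd90_nz")


def segment_beats(trace: np.ndarray, pacing_times: np.ndarray,
                  frame_rate: float, bcl: float | None = None,
                  pre_ms: float = 10.0) -> list[BeatWindow]:
    """Split a single-pixel trace into per-beat windows.

    One window per pacing interval, aligned to stimulus onset; the final
    beat extends one ``bcl`` (or the median pacing interval) past the last
    stimulus and is dropped if the recording ends first.  Each window keeps
    up to ``pre_ms`` of pre-stimulus context for baseline estimation.
    """
    trace = np.asarray(trace)
    pacing_times = np.asarray(pacing_times, dtype=float)
    if pacing_times.size < 2:
        raise InsufficientBeatsError("need at least 2 pacing times")
    dt = 1000.0 / frame_rate
    if bcl is None:
        bcl = float(np.median(np.diff(pacing_times)))
    pre = int(round(pre_ms / dt))
    bounds = np.concatenate([pacing_times, [pacing_times[-1] + bcl]])
    windows = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        i0 = int(round(t0 / dt))
        i1 = int(round(t1 / dt))
        if i1 > trace.size:
            break
        windows.append(BeatWindow(start=i0, stop=i1,
                                  pre_start=max(i0 - pre, 0)))
    if len(windows) < 2:
        raise InsufficientBeatsError(
            f"only {len(windows)} complete beat(s) in the recording")
    return windows


def beat_amplitude(trace: np.ndarray, window: BeatWindow) -> float:
    """Peak minus pre-upstroke baseline of one beat (clipped at zero).

    The baseline is the minimum over the pre-stimulus context (or the onset
    sample when the stimulus opens the recording), which is robust to slow
    drift.
    """
    seg = trace[window.slice()]
    if seg.size == 0:
        raise ValueError("empty beat window")
    if window.pre_start < window.start:
        baseline = float(np.min(trace[window.pre_start:window.start]))
    else:
        baseline = float(seg[0])
    return max(float(np.max(seg)) - baseline, 0.0)


def nam_pixel(amplitudes) -> tuple[float, float]:
    """Normalized alternans magnitude and its signed (phase) variant.

    *A* is the mean of even-indexed values, *B* of odd-indexed values; with
    an odd count the final value is dropped so both series have equal
    length.  Returns NaN pairs when ``A + B`` is zero (invalid pixel).
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 2:
        raise InsufficientBeatsError("need at least 2 beats")
    if a.size % 2:
        a = a[:-1]
    A = a[0::2].mean()
    B = a[1::2].mean()
    if A + B <= 0:
        return float("nan"), float("nan")
    signed = (A - B) / (A + B)
    return abs(signed), signed


def apd_alternans_pixel(durations) -> tuple[float, float]:
    """APD alternans: the same statistic on per-beat durations."""
    return nam_pixel(durations)


def transient_duration(trace: np.ndarray, window: BeatWindow,
                       frame_rate: float, recovery_level: float = 0.9
                       ) -> tuple[float, bool]:
    """Duration from stimulus onset to fractional recovery of the transient.

    Returns ``(duration_ms, censored)``; ``censored`` is True when the
    trace never recovers to the level inside the window (the value is then
    NaN and the beat is excluded from averaging).  The crossing is linearly
    interpolated between samples.  ``recovery_level=0`` gives the
    onset-to-peak time.
    """
    dt = 1000.0 / frame_rate
    seg = np.asarray(trace[window.slice()], dtype=float)
    if window.pre_start < window.start:
        baseline = float(np.min(trace[window.pre_start:window.start]))
    else:
        baseline = float(seg[0])
    ipk = int(np.argmax(seg))
    peak = seg[ipk]
    if peak <= baseline:
        return float("nan"), True
    level = peak - recovery_level * (peak - baseline)
    if recovery_level == 0:
        return ipk * dt, False
    for j in range(ipk, seg.size - 1):
        if seg[j] >= level > seg[j + 1]:
            frac = (seg[j] - level) / (seg[j] - seg[j + 1])
            return (j + frac) * dt, False
    return float("nan"), True


def _preprocess(stack: np.ndarray, settings: AnalysisSettings) -> np.ndarray:
    out = np.asarray(stack, dtype=float)
    if settings.spatial_kernel > 1:
        out = ndimage.uniform_filter(
            out, size=(settings.spatial_kernel, settings.spatial_kernel, 1),
            mode="nearest")
    if settings.temporal_kernel > 1:
        out = ndimage.uniform_filter(
            out, size=(1, 1, settings.temporal_kernel), mode="nearest")
    if settings.detrend:
        level = out.mean(axis=2, keepdims=True)
        out = signal.detrend(out, axis=2, type="linear") + level
    return out


def _noise_sd(trace: np.ndarray) -> float:
    """Robust white-noise SD from the second difference of the trace."""
    d2 = np.diff(trace, n=2)
    if d2.size == 0:
        return 0.0
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / np.sqrt(6.0))


def alternans_map(movie: MappingMovie,
                  settings: AnalysisSettings | None = None) -> AlternansMap:
    """Per-pixel NAM/phase map with SNR masking and nodal-line extraction.

    Pixels are invalid when the mean beat amplitude does not exceed
    ``snr_k`` times the per-pixel noise estimate (weak-signal scar pixels),
    or when the alternans statistic is undefined.  Nodal lines are
    zero-level contours of the signed map (marching squares), kept only
    where the local neighborhood reaches the NAM floor, so no-alternans
    regions produce no spurious contours.
    """
    settings = settings or AnalysisSettings()
    stack = _preprocess(movie.calcium, settings)
    rows, cols = movie.grid
    nam = np.full((rows, cols), np.nan)
    signed = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            trace = stack[r, c]
            windows = segment_beats(trace, movie.pacing_times,
                                    movie.frame_rate, movie.bcl,
                                    settings.baseline_pre_ms)
            amps = [beat_amplitude(trace, w) for w in windows]
            n, s = nam_pixel(amps)
            if not np.isfinite(n):
                continue
            sd = _noise_sd(trace)
            if np.mean(amps) > settings.snr_k * sd:
                nam[r, c] = n
                signed[r, c] = s
                valid[r, c] = True
    if not valid.any():
        raise EmptyZoneError("no valid pixels in the recording")
    lines = _nodal_lines(nam, signed, valid, settings.nodal_nam_floor)
    return AlternansMap(nam=nam, signed=signed, valid_mask=valid,
                        nodal_lines=lines)


def _nodal_lines(nam, signed, valid, floor) -> list[np.ndarray]:
    field_arr = np.where(valid, signed, 0.0)
    if not (np.any(field_arr > 0) and np.any(field_arr < 0)):
        return []
    near_alternans = ndimage.maximum_filter(np.where(valid, nam, 0.0), size=3)
    lines = []
    for contour in _sk_measure.find_contours(field_arr, 0.0):
        keep = np.array([
            valid[int(round(p[0])), int(round(p[1]))]
            and near_alternans[int(round(p[0])), int(round(p[1]))] >= floor
            for p in contour])
        if keep.any():
            lines.append(contour[keep])
    return lines


def catd_map(movie: MappingMovie,
             settings: AnalysisSettings | None = None) -> np.ndarray:
    """Per-pixel mean calcium-transient duration (ms) at the recovery level.

    Right-censored beats are excluded; a pixel with no measurable beat is
    NaN.
    """
    settings = settings or AnalysisSettings()
    stack = _preprocess(movie.calcium, settings)
    rows, cols = movie.grid
    out = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            trace = stack[r, c]
            windows = segment_beats(trace, movie.pacing_times,
                                    movie.frame_rate, movie.bcl,
                                    settings.baseline_pre_ms)
            durs = [transient_duration(trace, w, movie.frame_rate,
                                       settings.recovery_level)
                    for w in windows]
            vals = [d for d, censored in durs if not censored]
            if vals:
                out[r, c] = float(np.mean(vals))
    return out


def summarize_recording(amap: AlternansMap, catd: np.ndarray | None,
                        bz_mask: np.ndarray, *, condition: str = "control",
                        bcl: float = float("nan")) -> RecordingSummary:
    """Zone means of NAM and CaTD over valid pixels, and the BZ/NZ ratio."""
    bz_mask = np.asarray(bz_mask, dtype=bool)
    ok = amap.valid_mask
    bz_ok = ok & bz_mask
    nz_ok = ok & ~bz_mask
    if not bz_ok.any() or not nz_ok.any():
        raise EmptyZoneError("both zones need at least one valid pixel")
    mean_bz = float(np.nanmean(amap.nam[bz_ok]))
    mean_nz = float(np.nanmean(amap.nam[nz_ok]))
    if mean_nz == 0:
        raise EmptyZoneError("NZ mean alternans is zero; ratio undefined")
    if catd is None:
        catd_bz = catd_nz = float("nan")
    else:
        catd_bz = float(np.nanmean(catd[bz_ok]))
        catd_nz = float(np.nanmean(catd[nz_ok]))
    return RecordingSummary(
        mean_nam_total=float(np.nanmean(amap.nam[ok])),
        mean_nam_bz=mean_bz, mean_nam_nz=mean_nz,
        bz_nz_ratio=mean_bz / mean_nz,
        catd90_bz=catd_bz, catd90_nz=catd_nz,
        condition=condition, bcl=bcl)


def average_repeats(summaries: list[RecordingSummary]) -> RecordingSummary:
    """Element-wise mean of repeat recordings of one condition and rate.

    Three repeats are expected (the mapping protocol records three episodes
    per condition); fewer are averaged with a warning, mismatched labels
    raise.
    """
    if not summaries:
        raise ValueError("no summaries to average")
    labels = {(s.condition, s.bcl) for s in summaries}
    if len(labels) > 1:
        raise ValueError(f"mismatched condition/bcl labels: {labels}")
    if len(summaries) < 3:
        warnings.warn(f"averaging {len(summaries)} repeat(s); 3 expected",
                      stacklevel=2)
    vals = {name: float(np.mean([getattr(s, name) for s in summaries]))
            for name in RecordingSummary._numeric}
    return RecordingSummary(condition=summaries[0].condition,
                            bcl=summaries[0].bcl, **vals)


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    stderr: float
    n: int


def correlate_catd_nam(catd90, nam) -> CorrelationResult:
    """Least-squares regression of alternans magnitude on CaTD90.

    Slow-pacing calcium-transient duration predicting fast-pacing alternans
    is the hallmark of calcium-driven alternans; the p-value is the
    standard t-test on the regression slope, and R^2 the squared
    correlation.
    """
    x = np.asarray(catd90, dtype=float)
    y = np.asarray(nam, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    res = stats.linregress(x, y)
    return CorrelationResult(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r2=float(res.rvalue**2),
                             p_value=float(res.pvalue),
                             stderr=float(res.stderr), n=int(x.size))
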