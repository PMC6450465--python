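"""Action-potential feature extraction from sampled membrane traces.

Activation is an upward crossing of a fixed threshold (default -40 mV);
APD90 runs from activation to the interpolated downward crossing of
``peak - 0.9 * (peak - takeoff)``, where the takeoff potential is the
diastolic minimum over the 10 ms preceding the upstroke (a last-sample
definition would land mid-upstroke and jitter the repolarization level).
All crossings are linearly interpolated between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ACTIVATION_THRESHOLD_MV = -40.0
REARM_THRESHOLD_MV = -60.0


@dataclass
class ApMeasures:
    """Per-trace action-potential annotations."""

    activation_times: np.ndarray  # ms, one per detected upstroke
    apd90: np.ndarray             # ms, NaN where repolarization not seen
    peaks: np.ndarray             # mV, per AP
    takeoff: np.ndarray           # mV, potential just before each upstroke


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    if y1 == y0:
        return t1
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def measure_aps(vm: np.ndarray, times: np.ndarray,
                threshold: float = ACTIVATION_THRESHOLD_MV,
                apd_level: float = 0.9) -> ApMeasures:
    """Detect activations and APDs in a single-cell membrane trace.

    A new activation is only armed after the trace has fallen below the
    re-arm threshold, so a slow repolarization cannot double-count.
    """
    vm = np.asarray(vm, dtype=float)
    times = np.asarray(times, dtype=float)
    acts: list[float] = []
    act_idx: list[int] = []
    armed = vm[0] < threshold
    for i in range(1, vm.size):
        if armed and vm[i - 1] < threshold <= vm[i]:
            acts.append(_interp_crossing(times[i - 1], times[i],
                                         vm[i - 1], vm[i], threshold))
            act_idx.append(i)
            armed = False
        elif not armed and vm[i] < REARM_THRESHOLD_MV:
            armed = True
    n = len(acts)
    apd = np.full(n, np.nan)
    peaks = np.full(n, np.nan)
    takeoff = np.full(n, np.nan)
    for k in range(n):
        i0 = act_idx[k]
        i1 = act_idx[k + 1] - 1 if k + 1 < n else vm.size
        seg = vm[i0:i1]
        if seg.size == 0:
            continue
        peaks[k] = float(np.max(seg))
        dt_samp = times[1] - times[0] if times.size > 1 else 1.0
        w = max(int(round(10.0 / dt_samp)), 1)
        takeoff[k] = float(np.min(vm[max(i0 - w, 0):i0])) if i0 > 0 else float(vm[0])
        level = peaks[k] - apd_level * (peaks[k] - takeoff[k])
        j_peak = i0 + int(np.argmax(seg))
        for j in range(j_peak, min(i1, vm.size - 1)):
            if vm[j] >= level > vm[j + 1]:
                t_cross = _interp_crossing(times[j], times[j + 1],
                                           vm[j], vm[j + 1], level)
                apd[k] = t_cross - acts[k]
                break
    return ApMeasures(activation_times=np.array(acts), apd90=apd,
                      peaks=peaks, takeoff=takeoff)
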