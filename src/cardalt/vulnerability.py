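"""S2 outcome classification, vulnerable-window scans and the fiber table.

Two S1-S2 protocols are implemented on the pre-paced cable:

* **Conduction block** - the S2 is delivered to a short segment of
  non-infarcted tissue just proximal to the border zone, after the beat
  whose BZ action potential is *long* during alternans.  At intermediate
  coupling intervals the S2 wave propagates through recovered NZ tissue but
  dies inside the still-refractory BZ: a conduction block, the classic
  substrate for re-entry.
* **Premature ventricular complex (PVC)** - the S2 is delivered inside the
  border zone after the beat whose BZ action potential is *short*; the
  quantity of interest is the shortest coupling interval from which the
  premature wave propagates out of the segment in both directions.

Outcomes are classified from which cells activate after the S2:
``FULL_PROPAGATION`` iff both fiber-end sentinel groups activate,
``NO_PROPAGATION`` iff no cell outside the stimulated segment activates,
and ``BZ_BLOCK`` otherwise (the wave enters but fails to traverse the BZ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .fiber import FiberConfig, FiberRecording, FiberState, apply_s2, run_prepace

SENTINEL_CELLS = 5          # cells per fiber end used as propagation sentinels
NO_PROPAGATING_CI = float("inf")


class Outcome(str, Enum):
    NO_PROPAGATION = "NO_PROPAGATION"
    BZ_BLOCK = "BZ_BLOCK"
    FULL_PROPAGATION = "FULL_PROPAGATION"


@dataclass
class S2Outcome:
    """Classified result of a single S2 delivery."""

    ci: float
    category: Outcome
    left_sentinel: bool
    right_sentinel: bool
    n_activated_outside: int


@dataclass
class VulnerabilityResult:
    """Outcome of a contiguous coupling-interval scan."""

    scan: list[S2Outcome]
    block_window: tuple[float, float] | None
    min_propagating_ci: float
    ordered: bool           # NO_PROP* -> BZ_BLOCK* -> FULL* with no interleaving
    reached_full: bool      # scan top produced FULL_PROPAGATION

    def categories(self) -> list[Outcome]:
        return [o.category for o in self.scan]


def classify_outcome(recording: FiberRecording,
                     s2_cells: tuple[int, int],
                     segment_margin: int = 3) -> S2Outcome:
    """Classify one S2 recording by post-S2 activation of sentinel cells.

    Cells within ``segment_margin`` of the stimulated segment are counted as
    part of it: a stimulus delivered into relatively refractory tissue can
    excite its immediate neighbors electrotonically without launching a
    wave, and such a graded local response is not propagation.
    """
    if recording.s2_time is None:
        raise ValueError("recording does not contain an S2")
    n = recording.config.n_cells
    lo2, hi2 = s2_cells
    activated = recording.activated_after(recording.s2_time)
    outside = np.ones(n, dtype=bool)
    outside[max(lo2 - segment_margin, 0):hi2 + segment_margin] = False
    # a sentinel group swallowed by the stimulated segment (S2 delivered at a
    # fiber end) carries no information and is vacuously satisfied
    left = bool(activated[:SENTINEL_CELLS][outside[:SENTINEL_CELLS]].all()
                if outside[:SENTINEL_CELLS].any() else True)
    right = bool(activated[n - SENTINEL_CELLS:][outside[n - SENTINEL_CELLS:]].all()
                 if outside[n - SENTINEL_CELLS:].any() else True)
    n_outside = int(np.count_nonzero(activated & outside))
    if n_outside == 0:
        cat = Outcome.NO_PROPAGATION
    elif left and right:
        cat = Outcome.FULL_PROPAGATION
    else:
        cat = Outcome.BZ_BLOCK
    return S2Outcome(ci=float(recording.s2_time), category=cat,
                     left_sentinel=left, right_sentinel=right,
                     n_activated_outside=n_outside)


def _is_ordered(cats: list[Outcome]) -> bool:
    rank = {Outcome.NO_PROPAGATION: 0, Outcome.BZ_BLOCK: 1,
            Outcome.FULL_PROPAGATION: 2}
    r = [rank[c] for c in cats]
    return all(a <= b for a, b in zip(r, r[1:]))


def scan_coupling_intervals(state: FiberState, config: FiberConfig,
                            s2_cells: tuple[int, int],
                            ci_range: tuple[float, float] = (150.0, 250.0),
                            step: float = 1.0, *,
                            stop_after_full: int | None = None,
                            post_ms: float = 400.0) -> VulnerabilityResult:
    """Classify every coupling interval on a contiguous grid.

    The scan is strictly linear in ascending ci (monotonicity of outcomes is
    reported, never assumed).  If ``stop_after_full`` is given, the scan
    ends once that many consecutive FULL_PROPAGATION outcomes have been
    seen, which bounds the cost of wide grids.
    """
    outcomes: list[S2Outcome] = []
    full_streak = 0
    ci = float(ci_range[0])
    while ci <= ci_range[1] + 1e-9:
        rec = apply_s2(state, config, s2_cells, ci, post_ms=post_ms)
        out = classify_outcome(rec, s2_cells)
        outcomes.append(out)
        full_streak = full_streak + 1 if out.category is Outcome.FULL_PROPAGATION else 0
        if stop_after_full is not None and full_streak >= stop_after_full:
            break
        ci += step
    cats = [o.category for o in outcomes]
    blocks = [o.ci for o in outcomes if o.category is Outcome.BZ_BLOCK]
    fulls = [o.ci for o in outcomes if o.category is Outcome.FULL_PROPAGATION]
    reached_full = bool(fulls)
    if not reached_full:
        warnings.warn("scan range ended without full propagation",
                      stacklevel=2)
    return VulnerabilityResult(
        scan=outcomes,
        block_window=(min(blocks), max(blocks)) if blocks else None,
        min_propagating_ci=min(fulls) if fulls else NO_PROPAGATING_CI,
        ordered=_is_ordered(cats),
        reached_full=reached_full)


def scan_block_window(state: FiberState, config: FiberConfig,
                      s2_cells: tuple[int, int] | None = None,
                      ci_range: tuple[float, float] = (150.0, 320.0),
                      step: float = 1.0, **kw) -> VulnerabilityResult:
    """Conduction-block scan: S2 in proximal NZ adjacent to the border zone.

    ``state`` should be the snapshot preceding the *long*-APD border-zone
    beat (``recording.snapshots[recording.bz_long_beat]``).
    """
    if s2_cells is None:
        s2_cells = block_s2_segment(config)
    return scan_coupling_intervals(state, config, s2_cells, ci_range, step,
                                   **kw)


def min_propagating_ci(state: FiberState, config: FiberConfig,
                       s2_cells: tuple[int, int] | None = None,
                       ci_range: tuple[float, float] = (120.0, 320.0),
                       step: float = 1.0, **kw) -> VulnerabilityResult:
    """PVC scan: S2 inside the border zone (fiber middle for NZ-only).

    ``min_propagating_ci`` of the result is the shortest coupling interval
    whose premature wave reaches both fiber ends.
    """
    if s2_cells is None:
        s2_cells = pvc_s2_segment(config)
    return scan_coupling_intervals(state, config, s2_cells, ci_range, step,
                                   **kw)


def block_s2_segment(config: FiberConfig, width: int = 5,
                     offset: int = 50) -> tuple[int, int]:
    """S2 segment in proximal NZ (S1 side of the border zone).

    The default offset places the segment well outside the electrotonic
    neighborhood of the BZ, so its recovery is genuinely that of
    non-infarcted tissue.
    """
    if config.composition == "NZ-BZ-NZ":
        hi = config.bz_range[0] - offset + width
        return (hi - width, hi)
    mid = config.n_cells // 3
    return (mid - width // 2, mid - width // 2 + width)


def pvc_s2_segment(config: FiberConfig, width: int = 5) -> tuple[int, int]:
    """S2 segment centered in the BZ (fiber middle for NZ-only)."""
    if config.composition == "NZ-BZ-NZ":
        mid = (config.bz_range[0] + config.bz_range[1]) // 2
    else:
        mid = config.n_cells // 2
    return (mid - width // 2, mid - width // 2 + width)


#: the five fibers compared in the PVC-vulnerability table:
#: (bcl ms, composition, β-adrenergic level)
TABLE_FIBERS: dict[str, tuple[float, str, float]] = {
    "A": (300.0, "NZ-BZ-NZ", 0.0),
    "B": (300.0, "NZ", 0.0),
    "C": (400.0, "NZ-BZ-NZ", 0.0),
    "D": (400.0, "NZ", 0.0),
    "E": (300.0, "NZ-BZ-NZ", 1.0),
}


def prepace_fiber(fiber_id: str, base: FiberConfig | None = None,
                  **overrides) -> FiberRecording:
    """Pre-pace one of the named table fibers and return its recording."""
    try:
        bcl, comp, bar = TABLE_FIBERS[fiber_id]
    except KeyError:
        raise KeyError(f"unknown fiber id {fiber_id!r}; "
                       f"valid ids: {sorted(TABLE_FIBERS)}") from None
    from dataclasses import replace as _replace
    base = base if base is not None else FiberConfig()
    cfg = _replace(base, bcl=bcl, composition=comp, bar_level=bar, **overrides)
    return run_prepace(cfg)


def pvc_snapshot(recording: FiberRecording) -> FiberState:
    """Snapshot preceding the *short*-APD beat (or the last beat if stable)."""
    if recording.bz_long_beat is None:
        return recording.snapshots[-1]
    return recording.snapshots[1 - recording.bz_long_beat]


def block_snapshot(recording: FiberRecording) -> FiberState:
    """Snapshot preceding the *long*-APD beat (or the last beat if stable)."""
    if recording.bz_long_beat is None:
        return recording.snapshots[-1]
    return recording.snapshots[recording.bz_long_beat]


def table2_harness(base: FiberConfig | None = None,
                   fiber_ids=("A", "B", "C", "D", "E"),
                   ci_range: tuple[float, float] = (120.0, 320.0),
                   step: float = 1.0, *, stop_after_full: int | None = 15,
                   **overrides) -> pd.DataFrame:
    """Run the PVC protocol on the named fibers and tabulate the results.

    Returns one row per fiber: pacing rate, composition, β-adrenergic level
    and the shortest coupling interval with a fully propagating S2.  Fibers
    that fail to pre-pace are reported with an error message instead of a
    value.
    """
    rows = []
    for fid in fiber_ids:
        bcl, comp, bar = TABLE_FIBERS[fid]
        row = {"fiber_id": fid, "bcl_ms": bcl, "composition": comp,
               "bar_level": bar, "min_propagating_ci_ms": np.nan,
               "error": ""}
        try:
            rec = prepace_fiber(fid, base, **overrides)
            res = min_propagating_ci(pvc_snapshot(rec), rec.config,
                                     ci_range=ci_range, step=step,
                                     stop_after_full=stop_after_full)
            row["min_propagating_ci_ms"] = res.min_propagating_ci
        except Exception as exc:  # noqa: BLE001 - partial table contract
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
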