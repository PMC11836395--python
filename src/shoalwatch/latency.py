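"""Novel-object neophobia scoring: darting-event detection and latency to
resume normal swimming.

Darting is a sudden high-velocity excursion: an object whose instantaneous
speed exceeds a body-length-scaled threshold for a minimum number of
consecutive frames emits one dart event at the excursion onset.  Normal
swimming is resumed at the start of the first window of ``window_s`` seconds
in which fewer than ``max_darts_exclusive`` distinct fish dart (the study
rule: less than 2 fish per 10 s); a trial in which no window ever qualifies
is censored at clip duration.  The same rule can be applied to externally
scored event tables (e.g. exports from interactive annotation software).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detect import SizeModel


@dataclass(frozen=True)
class LatencyRule:
    """Resumption rule: a window qualifies iff the number of distinct darting
    fish within it is strictly below ``max_darts_exclusive``."""

    window_s: float = 10.0
    max_darts_exclusive: int = 2
    window_step_s: float = 1.0
    require_consecutive_windows: int = 1

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.max_darts_exclusive < 1:
            raise ValueError("max_darts_exclusive must be >= 1")
        if not 0 < self.window_step_s <= self.window_s:
            raise ValueError("window_step_s must be in (0, window_s]")
        if self.require_consecutive_windows < 1:
            raise ValueError("require_consecutive_windows must be >= 1")


@dataclass(frozen=True)
class DartEvent:
    onset_s: float
    object_id: int
    peak_speed_cmps: float = float("nan")
    n_fish: int = 1  # fish-equivalents of the darting object, >= 1


@dataclass
class LatencyResult:
    latency_s: float
    censored: bool
    clip_duration_s: float
    tank_id: str = ""
    trial: Optional[int] = None

    @property
    def sqrt_latency(self) -> float:
        return float(np.sqrt(self.latency_s))


def detect_darts(
    tracks: np.recarray,
    size: SizeModel,
    fps: float,
    dart_speed_bl_per_s: float = 3.0,
    min_dart_frames: int = 2,
    max_weight: float = 1.5,
) -> list[DartEvent]:
    """Extract dart events from tracklet speeds.

    ``tracks`` is the record array from :func:`shoalwatch.detect.build_tracklets`
    (fields frame, track, speed_cmps, weight).  One event is emitted per
    continuous excursion of at least ``min_dart_frames`` consecutive frames
    above ``dart_speed_bl_per_s * body_length`` cm/s, timed at its onset.

    Steps whose endpoint objects exceed ``max_weight`` fish-equivalents are
    discounted: a centroid step into or out of a merged group blob jumps by
    construction (the blob centroid is not any fish's position), and a dart
    happening inside a blob is unobservable regardless.
    """
    threshold = dart_speed_bl_per_s * size.body_length_cm
    events: list[DartEvent] = []
    if len(tracks) == 0:
        return events
    order = np.lexsort((tracks.frame, tracks.track))
    tr = tracks[order]
    tr = tr[tr.weight <= max_weight]
    if len(tr) == 0:
        return events
    for tid in np.unique(tr.track):
        sel = tr[tr.track == tid]
        frames = sel.frame
        fast = sel.speed_cmps > threshold
        run_start = None
        run_len = 0
        prev_frame = None
        for k in range(len(sel)):
            contiguous = prev_frame is not None and frames[k] == prev_frame + 1
            if fast[k]:
                if run_start is None or not contiguous:
                    if run_start is not None and run_len >= min_dart_frames:
                        events.append(_make_event(sel, run_start, run_len, fps))
                    run_start, run_len = k, 1
                else:
                    run_len += 1
            else:
                if run_start is not None and run_len >= min_dart_frames:
                    events.append(_make_event(sel, run_start, run_len, fps))
                run_start, run_len = None, 0
            prev_frame = frames[k]
        if run_start is not None and run_len >= min_dart_frames:
            events.append(_make_event(sel, run_start, run_len, fps))
    events.sort(key=lambda e: (e.onset_s, e.object_id))
    return events


def _make_event(sel: np.recarray, start: int, length: int, fps: float) -> DartEvent:
    chunk = sel[start : start + length]
    # event time is the onset of the excursion (the earlier frame of its
    # first fast step)
    onset_s = (chunk.frame[0] - 1) / fps
    return DartEvent(
        onset_s=float(onset_s),
        object_id=int(chunk.track[0]),
        peak_speed_cmps=float(chunk.speed_cmps.max()),
        n_fish=max(1, int(round(float(np.median(chunk.weight))))),
    )


def events_from_darting_flags(darting: np.ndarray, fps: float) -> list[DartEvent]:
    """Ground-truth dart events from a (n_frames, n_agents) boolean flag array
    (one event per rising edge), for oracle comparisons."""
    d = np.asarray(darting, dtype=bool)
    prev = np.vstack([np.zeros((1, d.shape[1]), dtype=bool), d[:-1]])
    frames, agents = np.nonzero(d & ~prev)
    return [
        DartEvent(onset_s=float(f / fps), object_id=int(a))
        for f, a in sorted(zip(frames, agents), key=lambda x: (x[0], x[1]))
    ]


def latency_to_resume(
    events: Sequence[DartEvent],
    clip_duration_s: float,
    rule: LatencyRule = LatencyRule(),
    tank_id: str = "",
    trial: Optional[int] = None,
) -> LatencyResult:
    """Scan windows from t=0 and return the start of the first (run of)
    qualifying window(s); censored at clip duration if none qualifies.

    The darting count of a window is the sum of fish-equivalents over the
    distinct objects with at least one event onset in ``[start, start+window)``.
    """
    if clip_duration_s <= 0:
        raise ValueError("clip duration must be positive")
    if any(e.onset_s < 0 for e in events):
        raise ValueError("event times must be non-negative")

    starts = np.arange(0.0, clip_duration_s - rule.window_s + 1e-9, rule.window_step_s)
    if len(starts) == 0:
        starts = np.array([0.0])  # clip shorter than one window: single window
    onsets = np.array([e.onset_s for e in events])
    ids = np.array([e.object_id for e in events])
    weights = np.array([e.n_fish for e in events])

    def window_count(s: float) -> int:
        in_w = (onsets >= s) & (onsets < s + rule.window_s)
        if not in_w.any():
            return 0
        # per distinct object, its fish-equivalents count once
        w = {}
        for oid, nf in zip(ids[in_w], weights[in_w]):
            w[oid] = max(w.get(oid, 0), int(nf))
        return sum(w.values())

    qualifies = np.array([window_count(s) < rule.max_darts_exclusive for s in starts])
    need = rule.require_consecutive_windows
    for k in range(len(starts) - need + 1):
        if qualifies[k : k + need].all():
            return LatencyResult(
                latency_s=float(starts[k]),
                censored=False,
                clip_duration_s=clip_duration_s,
                tank_id=tank_id,
                trial=trial,
            )
    return LatencyResult(
        latency_s=float(clip_duration_s),
        censored=True,
        clip_duration_s=clip_duration_s,
        tank_id=tank_id,
        trial=trial,
    )


def read_events_csv(path: str | Path) -> list[DartEvent]:
    """Load an externally scored event table (columns ``time_s``,
    ``subject_id``; optional ``n_fish``) as dart events, so the resumption
    rule can be applied to human annotations."""
    df = pd.read_csv(path)
    required = {"time_s", "subject_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"events CSV needs columns {sorted(required)}")
    n_fish = df["n_fish"] if "n_fish" in df.columns else pd.Series(1, index=df.index)
    return [
        DartEvent(onset_s=float(t), object_id=int(s), n_fish=max(1, int(n)))
        for t, s, n in zip(df["time_s"], df["subject_id"], n_fish)
    ]


def sqrt_transform_export(results: Sequence[LatencyResult]) -> pd.DataFrame:
    """Trial-level analysis table with a square-root-transformed latency
    column; censored trials keep their flag and are never silently treated
    as observed."""
    rows = []
    for r in results:
        if r.latency_s < 0:
            raise ValueError("latency must be non-negative")
        rows.append(
            {
                "tank_id": r.tank_id,
                "trial": r.trial,
                "latency_s": r.latency_s,
                "censored": r.censored,
                "sqrt_latency": r.sqrt_latency,
            }
        )
    return pd.DataFrame(rows)
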