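"""Per-clip behavioural welfare indicators from labelled detections:
group cohesion (area ratio + tight/loose/dispersed score), activity
(size-weighted centroid displacement) and enrichment occupation.

Cohesion is the ratio between the area of the tank occupied by the main
group and the total monitored tank area, scored categorically: tight below
0.25, dispersed above 0.75, loose in between (boundaries belong to loose).
Activity is the mean Euclidean centroid displacement between consecutive
frames, each displacement weighted by the object's estimated fish count.
Enrichment occupation is the percentage of detected fish pixel area lying
under the enrichment structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detect import LABEL_GROUP, EnrichmentRegion, FrameDetections, FrameLinks, SizeModel


@dataclass(frozen=True)
class CohesionScoreRule:
    """Categorical cohesion cut points: 0=tight, 1=loose, 2=dispersed.

    Tight is ``ratio < tight_upper``, dispersed is ``ratio > dispersed_lower``;
    both boundaries belong to the loose class.
    """

    tight_upper: float = 0.25
    dispersed_lower: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.tight_upper < self.dispersed_lower < 1.0:
            raise ValueError("need 0 < tight_upper < dispersed_lower < 1")


def cohesion_score(ratio: float, rule: CohesionScoreRule = CohesionScoreRule()) -> int:
    """Ordinal cohesion score of an area ratio: 0 tight, 1 loose, 2 dispersed."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"cohesion ratio must be in [0, 1], got {ratio}")
    if ratio < rule.tight_upper:
        return 0
    if ratio > rule.dispersed_lower:
        return 2
    return 1


def group_occupied_area_cm2(
    det: FrameDetections, size: SizeModel, mode: str = "hull"
) -> Optional[float]:
    """Area (cm^2) occupied by the main group in one frame.

    ``hull`` mode: convex hull of member centroids dilated by one body radius
    (a Minkowski sum with a disc), so two members yield a capsule and a lone
    merged blob falls back to its own pixel area.  ``blob`` mode: summed
    member pixel areas.  Returns None when the frame has no main group.
    """
    members = det.members(LABEL_GROUP)
    if len(members) == 0:
        return None
    if mode == "blob":
        return float(det.areas_cm2[members].sum())
    if mode != "hull":
        raise ValueError("mode must be 'hull' or 'blob'")
    if len(members) == 1:
        return float(det.areas_cm2[members[0]])
    from shapely.geometry import MultiPoint

    hull = MultiPoint(det.centroids_cm[members].tolist()).convex_hull
    return float(hull.buffer(size.body_length_cm / 2.0).area)


def cohesion_ratio(
    detections: Sequence[FrameDetections],
    monitored_area_cm2: float,
    size: SizeModel,
    mode: str = "hull",
) -> tuple[float, int]:
    """Mean per-frame group-area / monitored-area ratio over a clip.

    Each frame ratio is multiplied by the growth-correction factor and
    clamped to [0, 1]; the clip value is the mean over frames with a
    non-empty main group.  Returns ``(nan, 0)`` when no frame has one.
    """
    if monitored_area_cm2 <= 0:
        raise ValueError("monitored area must be positive")
    g = size.growth_correction_factor
    ratios = []
    for det in detections:
        area = group_occupied_area_cm2(det, size, mode=mode)
        if area is None:
            continue
        ratios.append(min(max(area / monitored_area_cm2 * g, 0.0), 1.0))
    if not ratios:
        return float("nan"), 0
    return float(np.mean(ratios)), len(ratios)


def activity(
    links: Sequence[FrameLinks],
    fps: float = 10.0,
) -> tuple[float, float, int]:
    """Size-weighted mean centroid displacement, pooled over all frame pairs.

    Returns ``(cm_per_frame, cm_per_s, n_matches)``; the weight of a match is
    the estimated fish count of the moving object, so a merged group of nine
    counts nine times a straggler.  ``(nan, nan, 0)`` when the clip has no
    accepted match.
    """
    num = 0.0
    den = 0.0
    n = 0
    for lk in links:
        if lk.n_matches == 0:
            continue
        num += float((lk.weights * lk.displacements_cm).sum())
        den += float(lk.weights.sum())
        n += lk.n_matches
    if n == 0 or den == 0:
        return float("nan"), float("nan"), 0
    per_frame = num / den
    return per_frame, per_frame * fps, n


def enrichment_occupation(
    foreground_masks: np.ndarray,
    region: EnrichmentRegion,
) -> tuple[float, int]:
    """Mean percentage of detected fish pixel area under the enrichment.

    Per frame: 100 x (fish pixels inside the region) / (all fish pixels);
    the clip value averages frames with any fish detected.  An empty region
    yields 0; no fish in any frame yields ``(nan, 0)``.
    """
    region_mask = region.mask
    vals = []
    for i in range(foreground_masks.shape[0]):
        fg = foreground_masks[i]
        total = int(fg.sum())
        if total == 0:
            continue
        inside = int((fg & region_mask).sum())
        vals.append(100.0 * inside / total)
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


@dataclass
class BehaviourRecord:
    """Per-clip indicator record; NaN metric fields carry a missing flag."""

    clip_id: str = ""
    tank_id: str = ""
    week: Optional[int] = None
    timepoint: str = ""
    cohesion_ratio: float = float("nan")
    cohesion_score: Optional[int] = None
    activity_cm_per_frame: float = float("nan")
    activity_cm_per_s: float = float("nan")
    enrichment_occupation_pct: float = float("nan")
    n_frames_used: int = 0
    missing: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "clip_id": self.clip_id,
            "tank_id": self.tank_id,
            "week": self.week,
            "timepoint": self.timepoint,
            "cohesion_ratio": self.cohesion_ratio,
            "cohesion_score": self.cohesion_score,
            "activity_cm_per_frame": self.activity_cm_per_frame,
            "activity_cm_per_s": self.activity_cm_per_s,
            "enrichment_occupation_pct": self.enrichment_occupation_pct,
            "n_frames_used": self.n_frames_used,
            "missing_cohesion": self.missing.get("cohesion", False),
            "missing_activity": self.missing.get("activity", False),
            "missing_occupation": self.missing.get("occupation", False),
        }


def summarise_clip(
    detections: Sequence[FrameDetections],
    links: Sequence[FrameLinks],
    foreground_masks: np.ndarray,
    region: EnrichmentRegion,
    size: SizeModel,
    monitored_area_cm2: float,
    fps: float,
    rule: CohesionScoreRule = CohesionScoreRule(),
    cohesion_mode: str = "hull",
    clip_id: str = "",
    tank_id: str = "",
    week: Optional[int] = None,
    timepoint: str = "",
) -> BehaviourRecord:
    """Assemble the per-clip behaviour record, flagging missing metrics."""
    ratio, n_coh = cohesion_ratio(detections, monitored_area_cm2, size, mode=cohesion_mode)
    act_frame, act_s, n_act = activity(links, fps=fps)
    occ, n_occ = enrichment_occupation(foreground_masks, region)
    missing = {
        "cohesion": n_coh == 0,
        "activity": n_act == 0,
        "occupation": n_occ == 0,
    }
    return BehaviourRecord(
        clip_id=clip_id,
        tank_id=tank_id,
        week=week,
        timepoint=timepoint,
        cohesion_ratio=ratio,
        cohesion_score=None if n_coh == 0 else cohesion_score(ratio, rule),
        activity_cm_per_frame=act_frame,
        activity_cm_per_s=act_s,
        enrichment_occupation_pct=occ,
        n_frames_used=n_coh,
        missing=missing,
    )


def standardise(values: np.ndarray) -> np.ndarray:
    """Mean-centre and scale to unit SD across clips (for model-ready export);
    NaNs are ignored in the moments and preserved in the output."""
    v = np.asarray(values, dtype=float)
    mu = np.nanmean(v)
    sd = np.nanstd(v)
    if sd == 0 or np.isnan(sd):
        return v - mu
    return (v - mu) / sd
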