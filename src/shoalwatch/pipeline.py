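"""Study-level orchestration: run the full per-clip pipeline (background →
detection → metrics → latency) over a configured multi-week session,
aggregate per-clip records to analysis units, and validate/merge the
morphological and physiological indicator tables for export.

Statistical model fitting (mixed models on the exported tables) is
deliberately out of scope: the exports are tidy long-format CSVs ready for
external statistical software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as swio
from .background import FrameSequence, fit_background, segment_foreground
from .detect import (
    EnrichmentRegion,
    SizeModel,
    assign_groups,
    build_tracklets,
    detect_enrichment_region,
    estimate_fish_size,
    label_objects,
    link_clip,
)
from .latency import (
    LatencyResult,
    LatencyRule,
    detect_darts,
    latency_to_resume,
    sqrt_transform_export,
)
from .metrics import BehaviourRecord, CohesionScoreRule, cohesion_score, summarise_clip
from .sim import SchoolParams, StimulusParams, TankScene, render_frames, simulate_school

TREATMENTS = ("EE", "NE")


@dataclass
class StudyDesign:
    """Tanks with treatments, weeks, daily timepoints and novel-object trials."""

    tanks: dict[str, str]  # tank label -> treatment (EE or NE)
    weeks: Sequence[int] = tuple(range(0, 14))
    timepoints: Sequence[str] = ("00:00", "06:00", "12:00", "18:00")
    trials: Sequence[int] = tuple(range(1, 7))

    def __post_init__(self) -> None:
        for tank, treat in self.tanks.items():
            if treat not in TREATMENTS:
                raise ValueError(f"tank {tank}: treatment must be one of {TREATMENTS}")


@dataclass
class ClipResult:
    record: BehaviourRecord
    latency: Optional[LatencyResult] = None
    size: Optional[SizeModel] = None


@dataclass
class PipelineParams:
    """Per-clip processing parameters (all exposed in the run config)."""

    k_sigma: float = 4.0
    min_spread_floor: float = 1.0
    r_open: int = 1
    min_blob_px: int = 3
    connectivity: int = 8
    linkage_factor: float = 4.0
    outlier_factor: float = 2.5
    gate_factor: float = 2.0
    aspect_ratio: float = 3.0
    cohesion_mode: str = "hull"
    dart_speed_bl_per_s: float = 3.0
    min_dart_frames: int = 2
    latency_rule: LatencyRule = field(default_factory=LatencyRule)
    size_min_frames: int = 100


def process_clip(
    seq: FrameSequence,
    n_fish_nominal: int,
    params: PipelineParams = PipelineParams(),
    enrichment_circle_cm: Optional[tuple[tuple[float, float], float]] = None,
    enrichment_declared: bool = False,
    reference_area_cm2: Optional[float] = None,
    is_trial: bool = False,
) -> ClipResult:
    """Run background modelling, detection and behaviour metrics on one clip;
    dart/latency scoring is added for novel-object trial clips."""
    model = fit_background(seq)
    masks = segment_foreground(
        seq,
        model,
        k_sigma=params.k_sigma,
        min_spread_floor=params.min_spread_floor,
        r_open=params.r_open,
    )
    dets = label_objects(
        masks, seq.px_per_cm, min_blob_px=params.min_blob_px, connectivity=params.connectivity
    )
    size = estimate_fish_size(
        dets,
        n_fish_nominal,
        aspect_ratio=params.aspect_ratio,
        reference_area_cm2=reference_area_cm2,
        min_frames=min(params.size_min_frames, len(dets)),
    )
    dets = assign_groups(
        dets, size, linkage_factor=params.linkage_factor, outlier_factor=params.outlier_factor
    )
    links = link_clip(dets, size, gate_factor=params.gate_factor)
    if enrichment_circle_cm is not None or enrichment_declared:
        region = detect_enrichment_region(
            model.location,
            seq.px_per_cm,
            monitored_mask=seq.monitored_mask,
            circle_cm=enrichment_circle_cm,
            declared_present=enrichment_declared,
        )
    else:
        region = EnrichmentRegion(
            np.zeros(seq.shape, dtype=bool), seq.px_per_cm, source="none"
        )
    record = summarise_clip(
        dets,
        links,
        masks,
        region,
        size,
        seq.monitored_area_cm2,
        seq.fps,
        cohesion_mode=params.cohesion_mode,
        clip_id=seq.clip_id,
        tank_id=seq.tank_id,
        week=seq.week,
        timepoint=seq.timepoint,
    )
    latency = None
    if is_trial:
        tracks = build_tracklets(dets, links, seq.fps)
        events = detect_darts(
            tracks,
            size,
            seq.fps,
            dart_speed_bl_per_s=params.dart_speed_bl_per_s,
            min_dart_frames=params.min_dart_frames,
        )
        latency = latency_to_resume(
            events,
            clip_duration_s=seq.n_frames / seq.fps,
            rule=params.latency_rule,
            tank_id=seq.tank_id,
        )
    return ClipResult(record=record, latency=latency, size=size)


def _sequence_from_clip_config(clip: dict, defaults: dict, base_dir: Path) -> FrameSequence:
    if "frames_dir" in clip:
        frames_dir = base_dir / clip["frames_dir"]
        if not frames_dir.is_dir():
            raise FileNotFoundError(
                f"clip '{clip.get('clip_id', '?')}': frames directory {frames_dir} not found"
            )
        seq = swio.read_frames_png(frames_dir)
    elif "simulate" in clip:
        sim_cfg = clip["simulate"]
        scene = TankScene.from_dict(sim_cfg.get("scene", {}))
        school = SchoolParams(**sim_cfg.get("school", {}))
        stim = (
            StimulusParams(**sim_cfg["stimulus"]) if sim_cfg.get("stimulus") else None
        )
        traj, _ = simulate_school(
            scene,
            school,
            stimulus=stim,
            duration_s=sim_cfg.get("duration_s", 60.0),
            fps=sim_cfg.get("fps", defaults.get("fps", 10.0)),
        )
        seq = render_frames(
            traj,
            scene,
            noise_sd=sim_cfg.get("noise_sd", defaults.get("noise_sd", 2.0)),
            noise_seed=sim_cfg.get("noise_seed", school.seed + 1),
            clip_id=clip.get("clip_id", ""),
        )
    else:
        raise ValueError(
            f"clip '{clip.get('clip_id', '?')}' needs either 'frames_dir' or 'simulate'"
        )
    seq.clip_id = clip.get("clip_id", seq.clip_id)
    seq.tank_id = clip.get("tank_id", seq.tank_id)
    seq.week = clip.get("week", seq.week)
    seq.timepoint = str(clip.get("timepoint", seq.timepoint))
    return seq


BEHAVIOUR_COLUMNS = {
    "clip_id": "clip identifier",
    "tank_id": "tank label",
    "week": "study week (0-based)",
    "timepoint": "daily recording timepoint (HH:MM)",
    "cohesion_ratio": "main-group area / monitored tank area, growth-corrected, in [0,1]",
    "cohesion_score": "ordinal cohesion: 0 tight (<0.25), 1 loose, 2 dispersed (>0.75)",
    "activity_cm_per_frame": "size-weighted mean centroid displacement per frame step (cm)",
    "activity_cm_per_s": "activity scaled to cm per second",
    "enrichment_occupation_pct": "% of detected fish pixel area under the enrichment",
    "n_frames_used": "frames contributing to the cohesion mean",
    "missing_cohesion": "no frame had a detected main group",
    "missing_activity": "no accepted frame-to-frame match",
    "missing_occupation": "no frame had detected fish",
}


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    params: Optional[PipelineParams] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the pipeline for every clip in the run config.

    Writes ``behaviour.csv`` (one row per clip), ``latency.csv`` (novel-object
    trials), a column dictionary and a structured run log; returns the two
    tables.  Deterministic given identical inputs and config.  A missing
    input fails fast, naming the clip, before any output is written.
    """
    base_dir = Path(".")
    if not isinstance(config, dict):
        base_dir = Path(config).parent
        config = swio.load_config(config)
    params = params or PipelineParams()
    defaults = config.get("defaults", {})
    clips = config.get("clips", [])
    if not clips:
        raise ValueError("config contains no clips")

    # fail fast on missing inputs before processing anything
    for clip in clips:
        if "frames_dir" in clip and not (base_dir / clip["frames_dir"]).is_dir():
            raise FileNotFoundError(
                f"clip '{clip.get('clip_id', '?')}': frames directory "
                f"{base_dir / clip['frames_dir']} not found"
            )

    records = []
    latencies: list[LatencyResult] = []
    log: list[dict] = []
    for clip in clips:
        seq = _sequence_from_clip_config(clip, defaults, base_dir)
        enr = clip.get("enrichment")
        circle = None
        declared = False
        if isinstance(enr, dict) and "circle_cm" in enr:
            c = enr["circle_cm"]
            circle = ((float(c["center"][0]), float(c["center"][1])), float(c["diameter"]))
        elif enr == "auto":
            declared = True
        is_trial = clip.get("trial") is not None
        result = process_clip(
            seq,
            n_fish_nominal=int(clip.get("n_fish", defaults.get("n_fish", 1))),
            params=params,
            enrichment_circle_cm=circle,
            enrichment_declared=declared,
            is_trial=is_trial,
        )
        records.append(result.record.to_dict())
        if result.latency is not None:
            result.latency.trial = clip.get("trial")
            latencies.append(result.latency)
        log.append(
            {
                "clip_id": seq.clip_id,
                "n_frames": seq.n_frames,
                "single_fish_area_cm2": result.size.single_fish_area_cm2,
                "body_length_cm": result.size.body_length_cm,
            }
        )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    behaviour = pd.DataFrame(records)
    behaviour.to_csv(out_dir / "behaviour.csv", index=False)
    swio.write_column_dictionary(BEHAVIOUR_COLUMNS, out_dir / "behaviour_columns.json")
    lat_df = sqrt_transform_export(latencies)
    lat_df.to_csv(out_dir / "latency.csv", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump({"clips": log, "params": _params_dict(params)}, fh, indent=2, sort_keys=True)
    return behaviour, lat_df


def _params_dict(p: PipelineParams) -> dict:
    d = dict(vars(p))
    d["latency_rule"] = dict(vars(p.latency_rule))
    return d


def aggregate(
    records: pd.DataFrame,
    design: StudyDesign,
    by_timepoint: bool = False,
    rule: CohesionScoreRule = CohesionScoreRule(),
) -> pd.DataFrame:
    """Aggregate per-clip records to tank x week (x timepoint) means.

    The cohesion score is re-derived from the mean ratio; groups with no
    contributing clip (or all-missing metrics) carry an explicit flag.
    """
    keys = ["tank_id", "week"] + (["timepoint"] if by_timepoint else [])
    rows = []
    groups = records.groupby(keys, dropna=False) if len(records) else None
    index = [
        (t, w) + ((tp,) if by_timepoint else ())
        for t in design.tanks
        for w in design.weeks
        for tp in (design.timepoints if by_timepoint else [None])
    ]
    for key in index:
        try:
            sub = groups.get_group(key if len(key) > 1 else key[0]) if groups else None
        except KeyError:
            sub = None
        row = dict(zip(keys, key))
        row["treatment"] = design.tanks[key[0]]
        if sub is None or len(sub) == 0:
            row.update(
                n_clips=0,
                cohesion_ratio=np.nan,
                cohesion_score=np.nan,
                activity_cm_per_s=np.nan,
                enrichment_occupation_pct=np.nan,
                missing=True,
            )
        else:
            ratio = sub["cohesion_ratio"].mean()
            row.update(
                n_clips=len(sub),
                cohesion_ratio=ratio,
                cohesion_score=(
                    np.nan if np.isnan(ratio) else cohesion_score(float(ratio), rule)
                ),
                activity_cm_per_s=sub["activity_cm_per_s"].mean(),
                enrichment_occupation_pct=sub["enrichment_occupation_pct"].mean(),
                missing=bool(sub["cohesion_ratio"].isna().all()),
            )
        rows.append(row)
    return pd.DataFrame(rows)


class ValidationError(ValueError):
    """Raised with the list of violations found in an indicator table."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


MORPH_SESSIONS = ("week0", "week12_13")


def validate_tables(
    morphology: pd.DataFrame,
    design: StudyDesign,
    cortisol: Optional[pd.DataFrame] = None,
    expression: Optional[pd.DataFrame] = None,
    score_scale: tuple[int, int] = (0, 2),
) -> pd.DataFrame:
    """Validate and merge indicator tables into one long-format export.

    Morphology rows need positive weight/length and ordinal scores within the
    declared scale (the fin-damage scale is configurable: declare (1, 3) or
    (0, 2)); merge keys are (tank, session).  Every violation is reported
    with its row number.
    """
    errors: list[str] = []
    required = {"fish_id", "tank", "session", "weight_g", "length_cm",
                "dorsal_fin_score", "body_condition_score"}
    missing_cols = required - set(morphology.columns)
    if missing_cols:
        raise ValidationError([f"morphology: missing columns {sorted(missing_cols)}"])
    lo, hi = score_scale
    for i, row in morphology.iterrows():
        if row["tank"] not in design.tanks:
            errors.append(f"morphology row {i}: unknown tank '{row['tank']}'")
        if row["session"] not in MORPH_SESSIONS:
            errors.append(
                f"morphology row {i}: session must be one of {MORPH_SESSIONS}"
            )
        if not row["weight_g"] > 0:
            errors.append(f"morphology row {i}: weight_g must be positive")
        if not row["length_cm"] > 0:
            errors.append(f"morphology row {i}: length_cm must be positive")
        for col in ("dorsal_fin_score", "body_condition_score"):
            if not lo <= row[col] <= hi:
                errors.append(
                    f"morphology row {i}: {col}={row[col]} outside scale [{lo}, {hi}]"
                )
    frames = [morphology.assign(table="morphology")]
    for name, df in (("cortisol", cortisol), ("expression", expression)):
        if df is None:
            continue
        for col in ("tank", "session"):
            if col not in df.columns:
                errors.append(f"{name}: missing merge key column '{col}'")
        if {"tank", "session"}.issubset(df.columns):
            for i, row in df.iterrows():
                if row["tank"] not in design.tanks:
                    errors.append(f"{name} row {i}: unknown tank '{row['tank']}'")
            frames.append(df.assign(table=name))
    if errors:
        raise ValidationError(errors)
    merged = pd.concat(frames, ignore_index=True, sort=False)
    merged["treatment"] = merged["tank"].map(design.tanks)
    return merged
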