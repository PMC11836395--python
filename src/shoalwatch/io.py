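"""File I/O: numbered PNG frame sequences, masks, YAML configs, and the
column dictionary accompanying CSV exports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import yaml

from .background import BackgroundModel, FrameSequence

FRAME_PATTERN = "frame_{:06d}.png"


def write_frames_png(seq: FrameSequence, out_dir: str | Path) -> Path:
    """Write a frame sequence as numbered 8-bit grayscale PNGs plus a JSON
    metadata sidecar (fps, pixel scale, labels, simulation parameters)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(seq.n_frames):
        iio.imwrite(out_dir / FRAME_PATTERN.format(i), seq.frames[i].astype(np.uint8))
    if seq.monitored_mask is not None:
        iio.imwrite(
            out_dir / "monitored_mask.png",
            (seq.monitored_mask.astype(np.uint8) * 255),
        )
    meta = {
        "fps": seq.fps,
        "px_per_cm": seq.px_per_cm,
        "n_frames": seq.n_frames,
        "clip_id": seq.clip_id,
        "tank_id": seq.tank_id,
        "week": seq.week,
        "timepoint": seq.timepoint,
        "meta": seq.meta,
    }
    with open(out_dir / "frames_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return out_dir


def read_frames_png(frames_dir: str | Path) -> FrameSequence:
    """Read a numbered PNG sequence written by :func:`write_frames_png`."""
    frames_dir = Path(frames_dir)
    if not frames_dir.is_dir():
        raise FileNotFoundError(f"frames directory not found: {frames_dir}")
    meta_path = frames_dir / "frames_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing frames_meta.json in {frames_dir}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    paths = sorted(frames_dir.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {frames_dir}")
    frames = np.stack([iio.imread(p) for p in paths])
    mask_path = frames_dir / "monitored_mask.png"
    mask = iio.imread(mask_path) > 0 if mask_path.exists() else None
    return FrameSequence(
        frames=frames,
        fps=meta["fps"],
        px_per_cm=meta["px_per_cm"],
        monitored_mask=mask,
        clip_id=meta.get("clip_id", ""),
        tank_id=meta.get("tank_id", ""),
        week=meta.get("week"),
        timepoint=meta.get("timepoint", ""),
        meta=meta.get("meta", {}),
    )


def write_background_model(model: BackgroundModel, path: str | Path) -> None:
    """Save a background model as a 2-plane TIFF (location, spread) plus a
    JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.stack([model.location, model.spread]))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            {"n_frames_used": model.n_frames_used, "polarity": model.polarity},
            fh,
            indent=2,
        )


def read_background_model(path: str | Path) -> BackgroundModel:
    import tifffile

    path = Path(path)
    planes = tifffile.imread(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return BackgroundModel(
        location=planes[0],
        spread=planes[1],
        n_frames_used=meta["n_frames_used"],
        polarity=meta["polarity"],
    )


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), mask.astype(np.uint8) * 255)


def read_mask_png(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)) > 0


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def write_column_dictionary(columns: dict[str, str], path: str | Path) -> None:
    """Machine-readable description of a CSV export's columns."""
    with open(path, "w") as fh:
        json.dump(columns, fh, indent=2, sort_keys=True)
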