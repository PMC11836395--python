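"""Statistical background model of the static tank scene and foreground
segmentation by background subtraction.

The scene (tank floor, walls, enrichment structure) is static over a clip, so
a robust per-pixel location/spread model estimated over time separates moving
fish from everything else.  The model is a per-pixel temporal *lower median*
with a scaled median-absolute-deviation spread: both are robust to fish
transiting any given pixel in a minority of the sampled frames, and both are
deterministic (no tie-averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

#: 1.4826 makes the MAD a consistent estimator of sigma for Gaussian noise.
MAD_SCALE = 1.4826

VALID_POLARITIES = ("dark_fish", "light_fish", "two_sided")


@dataclass
class FrameSequence:
    """Ordered raster frames with a timebase and a pixel-to-cm scale."""

    frames: np.ndarray  # (n_frames, height, width), intensity
    fps: float
    px_per_cm: float
    monitored_mask: Optional[np.ndarray] = None  # static bool raster, None = all
    timestamp_origin: float = 0.0
    clip_id: str = ""
    tank_id: str = ""
    week: Optional[int] = None
    timepoint: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.monitored_mask is not None:
            self.monitored_mask = np.asarray(self.monitored_mask, dtype=bool)
            if self.monitored_mask.shape != self.frames.shape[1:]:
                raise ValueError("monitored_mask shape does not match frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        return self.timestamp_origin + np.arange(self.n_frames) / self.fps

    @property
    def monitored_area_cm2(self) -> float:
        if self.monitored_mask is None:
            h, w = self.shape
            n_px = h * w
        else:
            n_px = int(self.monitored_mask.sum())
        return n_px / self.px_per_cm**2


@dataclass
class BackgroundModel:
    """Per-pixel location/spread statistics of the static scene."""

    location: np.ndarray  # (h, w) lower-median intensity
    spread: np.ndarray  # (h, w) scaled MAD, >= 0
    n_frames_used: int
    polarity: str = "dark_fish"

    def __post_init__(self) -> None:
        if self.polarity not in VALID_POLARITIES:
            raise ValueError(f"polarity must be one of {VALID_POLARITIES}")
        if self.location.shape != self.spread.shape:
            raise ValueError("location/spread shape mismatch")
        if np.any(self.spread < 0):
            raise ValueError("spread must be non-negative")


def _lower_median(stack: np.ndarray) -> np.ndarray:
    """Lower median along axis 0 (element at index (n-1)//2 of the sorted
    column), a deterministic tie rule for even sample counts."""
    n = stack.shape[0]
    k = (n - 1) // 2
    return np.partition(stack, k, axis=0)[k]


def fit_background(
    seq: FrameSequence,
    sample_stride: Optional[int] = None,
    polarity: str = "dark_fish",
    max_samples: int = 60,
) -> BackgroundModel:
    """Fit the per-pixel lower-median / scaled-MAD background model.

    Parameters
    ----------
    sample_stride
        Temporal subsampling stride.  ``None`` picks the stride that yields
        about ``max_samples`` frames; estimating the median over ~60 frames
        spread across the clip is ample for a static scene.
    """
    if sample_stride is None:
        sample_stride = max(1, seq.n_frames // max_samples)
    if sample_stride < 1:
        raise ValueError("sample_stride must be >= 1")
    sampled = np.asarray(seq.frames[::sample_stride], dtype=np.float32)
    if sampled.shape[0] < 10:
        raise ValueError(
            f"need >= 10 sampled frames to fit a background model, "
            f"got {sampled.shape[0]} (n_frames={seq.n_frames}, stride={sample_stride})"
        )
    location = _lower_median(sampled)
    spread = MAD_SCALE * _lower_median(np.abs(sampled - location[None]))
    return BackgroundModel(
        location=location,
        spread=spread,
        n_frames_used=sampled.shape[0],
        polarity=polarity,
    )


def _opening_structure(r_open: int) -> np.ndarray:
    from skimage.morphology import disk

    return disk(r_open).astype(bool)


def segment_foreground(
    seq: FrameSequence,
    model: BackgroundModel,
    k_sigma: float = 4.0,
    min_spread_floor: float = 1.0,
    r_open: int = 1,
    reconstruct: bool = True,
) -> np.ndarray:
    """Foreground (fish) masks by per-pixel deviation from the background.

    A pixel is foreground iff its deviation from the background location, in
    the direction given by the model polarity, exceeds
    ``k_sigma * max(spread, min_spread_floor)``.  The raw mask is cleaned by a
    morphological opening with a disc of radius ``r_open`` px (by default an
    opening *by reconstruction*: the opened mask seeds a propagation back into
    the raw mask, so isolated noise pixels vanish while thin fish bodies that
    survive erosion anywhere are kept whole) and intersected with the
    monitored-region mask.

    Returns a boolean (n_frames, h, w) array.
    """
    if model.location.shape != seq.shape:
        raise ValueError("background model geometry does not match frames")
    thresh = k_sigma * np.maximum(model.spread, min_spread_floor)
    frames = np.asarray(seq.frames, dtype=np.float32)
    dev = model.location[None] - frames
    if model.polarity == "dark_fish":
        fg = dev > thresh[None]
    elif model.polarity == "light_fish":
        fg = -dev > thresh[None]
    else:
        fg = np.abs(dev) > thresh[None]
    if r_open >= 1:
        structure = _opening_structure(r_open)
        for i in range(fg.shape[0]):
            opened = ndimage.binary_opening(fg[i], structure=structure)
            if reconstruct:
                fg[i] = ndimage.binary_propagation(opened, mask=fg[i])
            else:
                fg[i] = opened
    if seq.monitored_mask is not None:
        fg &= seq.monitored_mask[None]
    return fg
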