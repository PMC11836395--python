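"""Per-frame object extraction from foreground masks: connected components,
single-fish size estimation, main-group / individual / outlier labelling,
enrichment-region detection, and frame-to-frame centroid linking.

A tight shoal appears as a single merged blob, so objects carry an estimated
fish count (area divided by the single-fish area) rather than assuming one
object = one fish.  Grouping, outlier removal and link gating all scale with
the estimated body length, so one configuration keeps working as fish grow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

LABEL_GROUP = "group"
LABEL_INDIVIDUAL = "individual"
LABEL_OUTLIER = "outlier"


@dataclass
class FrameDetections:
    """Detected objects of one frame.

    Centroids are real-valued pixel coordinates (x = column, y = row, origin
    at the top-left) with cm equivalents; ``labels`` holds one of
    ``group`` / ``individual`` / ``outlier`` per object (empty string before
    :func:`assign_groups` runs).
    """

    frame_index: int
    centroids_px: np.ndarray  # (n, 2) float, columns (x, y)
    areas_px: np.ndarray  # (n,) int
    px_per_cm: float
    est_fish_count: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.areas_px)
        self.centroids_px = np.asarray(self.centroids_px, dtype=float).reshape(n, 2)
        self.areas_px = np.asarray(self.areas_px, dtype=np.int64)
        if self.est_fish_count is None:
            self.est_fish_count = np.full(n, np.nan)
        if self.labels is None:
            self.labels = np.array([""] * n, dtype=object)

    @property
    def n_objects(self) -> int:
        return len(self.areas_px)

    @property
    def centroids_cm(self) -> np.ndarray:
        return self.centroids_px / self.px_per_cm

    @property
    def areas_cm2(self) -> np.ndarray:
        return self.areas_px / self.px_per_cm**2

    @property
    def total_fish_area_cm2(self) -> float:
        return float(self.areas_cm2.sum())

    def members(self, label: str) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


@dataclass
class SizeModel:
    """Single-fish size estimate with a growth-correction factor.

    ``growth_correction_factor`` is ``reference_area / current_area`` clamped
    to (0, 1]: it shrinks area-derived ratios to the week-0 scale so that a
    group of bigger fish is not read as more dispersed.
    """

    single_fish_area_cm2: float
    body_length_cm: float
    aspect_ratio: float = 3.0
    reference_area_cm2: Optional[float] = None
    source: str = "isolated_mode"

    def __post_init__(self) -> None:
        if self.single_fish_area_cm2 <= 0 or self.body_length_cm <= 0:
            raise ValueError("size model requires positive area and length")

    @property
    def growth_correction_factor(self) -> float:
        if self.reference_area_cm2 is None:
            return 1.0
        return float(
            np.clip(self.reference_area_cm2 / self.single_fish_area_cm2, 1e-12, 1.0)
        )


@dataclass
class EnrichmentRegion:
    mask: np.ndarray  # bool raster
    px_per_cm: float
    source: str = "config"  # config_polygon | config_circle | static_dark_region | none

    @property
    def area_cm2(self) -> float:
        return float(self.mask.sum()) / self.px_per_cm**2


class EnrichmentNotFoundError(RuntimeError):
    """Auto-detection found no static dark structure although one was declared."""


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def label_objects(
    masks: np.ndarray,
    px_per_cm: float,
    min_blob_px: int = 3,
    connectivity: int = 8,
) -> list[FrameDetections]:
    """Connected-component labelling of a (n_frames, h, w) mask stack.

    Components with fewer than ``min_blob_px`` pixels are dropped as noise.
    Centroids are the pixel-coordinate means of each component.
    """
    structure = _connectivity_structure(connectivity)
    out: list[FrameDetections] = []
    for i in range(masks.shape[0]):
        lab, n_lab = ndimage.label(masks[i], structure=structure)
        if n_lab == 0:
            out.append(
                FrameDetections(i, np.empty((0, 2)), np.empty(0, dtype=np.int64), px_per_cm)
            )
            continue
        flat = lab.ravel()
        areas = np.bincount(flat, minlength=n_lab + 1)[1:]
        ys, xs = np.nonzero(lab)
        ids = lab[ys, xs]
        sum_x = np.bincount(ids, weights=xs, minlength=n_lab + 1)[1:]
        sum_y = np.bincount(ids, weights=ys, minlength=n_lab + 1)[1:]
        keep = areas >= min_blob_px
        areas_k = areas[keep]
        cx = sum_x[keep] / areas_k
        cy = sum_y[keep] / areas_k
        out.append(
            FrameDetections(
                i, np.column_stack([cx, cy]), areas_k.astype(np.int64), px_per_cm
            )
        )
    return out


def estimate_fish_size(
    detections: Sequence[FrameDetections],
    n_fish_nominal: int,
    aspect_ratio: float = 3.0,
    reference_area_cm2: Optional[float] = None,
    min_frames: int = 100,
    n_mode_bins: int = 30,
) -> SizeModel:
    """Estimate the single-fish area from a clip's detections.

    Isolated-fish candidates are the objects whose area lies below the 50th
    percentile of all object areas; the estimate is the centre of the most
    populated area bin among them.  When the group never splits (at most one
    object per frame) or no candidate exists, falls back to the mean total
    area divided by the nominal group size.  The derived body length is
    ``sqrt(area * aspect_ratio)``.
    """
    if len(detections) < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {len(detections)}")
    nonempty = [d.areas_cm2 for d in detections if d.n_objects > 0]
    if not nonempty:
        raise ValueError("no detections in clip: cannot estimate fish size")
    all_areas = np.concatenate(nonempty)
    max_objects = max(d.n_objects for d in detections)

    single_area = None
    source = "isolated_mode"
    if max_objects > 1:
        cut = np.percentile(all_areas, 50)
        candidates = all_areas[all_areas < cut]
        if candidates.size > 0:
            hist, edges = np.histogram(candidates, bins=n_mode_bins)
            k = int(np.argmax(hist))
            in_bin = candidates[(candidates >= edges[k]) & (candidates <= edges[k + 1])]
            single_area = float(in_bin.mean())
    if single_area is None or single_area <= 0:
        totals = [d.total_fish_area_cm2 for d in detections if d.n_objects > 0]
        single_area = float(np.mean(totals)) / n_fish_nominal
        source = "total_over_nominal"

    return SizeModel(
        single_fish_area_cm2=single_area,
        body_length_cm=float(np.sqrt(single_area * aspect_ratio)),
        aspect_ratio=aspect_ratio,
        reference_area_cm2=reference_area_cm2,
        source=source,
    )


def assign_groups(
    detections: Sequence[FrameDetections],
    size: SizeModel,
    linkage_factor: float = 4.0,
    outlier_factor: float = 2.5,
) -> list[FrameDetections]:
    """Label each object as main-group member, outlier, or individual.

    Objects are clustered by single linkage on centroid distance with cutoff
    ``linkage_factor * body_length``; the cluster with the largest summed
    estimated fish count is the main group (ties resolved to the cluster
    containing the lowest object index).  In one pass, group members farther
    from the group centroid than ``outlier_factor`` times the RMS member
    distance are re-labelled outliers.  The result is order-invariant.
    """
    cutoff = linkage_factor * size.body_length_cm
    out: list[FrameDetections] = []
    for det in detections:
        n = det.n_objects
        counts = det.areas_cm2 / size.single_fish_area_cm2
        labels = np.array([""] * n, dtype=object)
        if n == 1:
            labels[0] = LABEL_GROUP
        elif n > 1:
            d = pdist(det.centroids_cm)
            cl = fcluster(linkage(d, method="single"), t=cutoff, criterion="distance")
            sums = np.zeros(cl.max() + 1)
            np.add.at(sums, cl, counts)
            best = sums.max()
            tied = np.nonzero(np.isclose(sums, best))[0]
            if len(tied) == 1:
                main = tied[0]
            else:
                # deterministic tie-break: cluster holding the lowest object index
                first_idx = {c: int(np.nonzero(cl == c)[0][0]) for c in tied}
                main = min(tied, key=lambda c: first_idx[c])
            in_main = cl == main
            labels[in_main] = LABEL_GROUP
            labels[~in_main] = LABEL_INDIVIDUAL
            members = np.nonzero(in_main)[0]
            if len(members) > 1:
                pts = det.centroids_cm[members]
                center = pts.mean(axis=0)
                dist = np.linalg.norm(pts - center, axis=1)
                rms = np.sqrt((dist**2).mean())
                if rms > 0:
                    labels[members[dist > outlier_factor * rms]] = LABEL_OUTLIER
        out.append(
            FrameDetections(
                det.frame_index,
                det.centroids_px,
                det.areas_px,
                det.px_per_cm,
                est_fish_count=counts,
                labels=labels,
            )
        )
    return out


def detect_enrichment_region(
    location: np.ndarray,
    px_per_cm: float,
    monitored_mask: Optional[np.ndarray] = None,
    circle_cm: Optional[tuple[tuple[float, float], float]] = None,
    polygon_px: Optional[np.ndarray] = None,
    origin_px: Optional[tuple[float, float]] = None,
    declared_present: bool = True,
    dark_factor: float = 0.92,
) -> EnrichmentRegion:
    """Locate the static enrichment structure.

    If a circle (``(center_cm, diameter_cm)`` relative to ``origin_px``) or a
    polygon (``(n, 2)`` pixel vertices, x=col/y=row) is configured it is
    rasterised; otherwise the structure is recovered from the *background
    location raster*: being static, it is absorbed into the background, so
    its footprint is the largest connected dark region in the monitored
    area.  The dark threshold is Otsu's between-class split of the monitored
    background intensities (robust when the structure covers a large share
    of the view), tightened to at most ``dark_factor`` times the upper-mode
    median.

    Raises :class:`EnrichmentNotFoundError` when auto-detection finds nothing
    although the structure is declared present.
    """
    shape = location.shape
    mon = np.ones(shape, dtype=bool) if monitored_mask is None else monitored_mask

    if circle_cm is not None:
        from . import geometry

        (cx_cm, cy_cm), diameter_cm = circle_cm
        if origin_px is None:
            origin_px = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
        center_px = (origin_px[0] + cx_cm * px_per_cm, origin_px[1] + cy_cm * px_per_cm)
        mask = geometry.disc_mask(shape, center_px, diameter_cm / 2 * px_per_cm)
        return EnrichmentRegion(mask & mon, px_per_cm, source="config_circle")

    if polygon_px is not None:
        from skimage.draw import polygon as draw_polygon

        poly = np.asarray(polygon_px, dtype=float)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return EnrichmentRegion(mask & mon, px_per_cm, source="config_polygon")

    if not declared_present:
        return EnrichmentRegion(np.zeros(shape, dtype=bool), px_per_cm, source="none")

    from skimage.filters import threshold_otsu

    vals = location[mon]
    try:
        t_otsu = threshold_otsu(vals)
    except ValueError:  # constant background
        t_otsu = -np.inf
    bright_med = np.median(vals[vals >= t_otsu]) if np.isfinite(t_otsu) else np.median(vals)
    thresh = min(t_otsu, dark_factor * bright_med)
    dark = (location < thresh) & mon
    dark = ndimage.binary_closing(
        dark, structure=ndimage.generate_binary_structure(2, 2), iterations=2
    )
    lab, n_lab = ndimage.label(dark)
    if n_lab == 0:
        raise EnrichmentNotFoundError(
            "enrichment declared present but no static dark region found"
        )
    areas = np.bincount(lab.ravel())[1:]
    mask = lab == (int(np.argmax(areas)) + 1)
    mask = ndimage.binary_fill_holes(mask)
    return EnrichmentRegion(mask & mon, px_per_cm, source="static_dark_region")


@dataclass
class FrameLinks:
    """Accepted object correspondences between frames t and t+1."""

    frame_index: int  # index of the earlier frame
    idx_t: np.ndarray  # object indices in frame t
    idx_t1: np.ndarray  # matched object indices in frame t+1
    displacements_cm: np.ndarray  # per-match Euclidean displacement
    weights: np.ndarray  # est_fish_count of the frame-t object

    @property
    def n_matches(self) -> int:
        return len(self.idx_t)


def link_frames(
    det_t: FrameDetections,
    det_t1: FrameDetections,
    size: SizeModel,
    gate_factor: float = 2.0,
) -> FrameLinks:
    """Greedy mutual-nearest-centroid matching between consecutive frames.

    Candidate pairs within ``gate_factor * body_length`` are accepted in
    ascending distance order (ties broken by lowest object indices), each
    object at most once; unmatched objects contribute no displacement.
    """
    gate = gate_factor * size.body_length_cm
    if det_t.n_objects == 0 or det_t1.n_objects == 0:
        empty = np.empty(0)
        return FrameLinks(det_t.frame_index, empty.astype(int), empty.astype(int), empty, empty)
    dist = cdist(det_t.centroids_cm, det_t1.centroids_cm)
    ii, jj = np.nonzero(dist <= gate)
    order = np.lexsort((jj, ii, dist[ii, jj]))
    used_t = np.zeros(det_t.n_objects, dtype=bool)
    used_t1 = np.zeros(det_t1.n_objects, dtype=bool)
    mi, mj, md = [], [], []
    for k in order:
        i, j = ii[k], jj[k]
        if used_t[i] or used_t1[j]:
            continue
        used_t[i] = used_t1[j] = True
        mi.append(i)
        mj.append(j)
        md.append(dist[i, j])
    weights = (
        det_t.est_fish_count[mi] if len(mi) else np.empty(0)
    )
    weights = np.where(np.isnan(weights), 1.0, weights) if len(mi) else weights
    return FrameLinks(
        det_t.frame_index,
        np.asarray(mi, dtype=int),
        np.asarray(mj, dtype=int),
        np.asarray(md, dtype=float),
        np.asarray(weights, dtype=float),
    )


def link_clip(
    detections: Sequence[FrameDetections],
    size: SizeModel,
    gate_factor: float = 2.0,
) -> list[FrameLinks]:
    """Link every consecutive frame pair of a clip."""
    return [
        link_frames(detections[i], detections[i + 1], size, gate_factor)
        for i in range(len(detections) - 1)
    ]


def build_tracklets(
    detections: Sequence[FrameDetections],
    links: Sequence[FrameLinks],
    fps: float,
) -> "np.recarray":
    """Chain frame-to-frame links into short tracklets and compute per-step
    speeds.

    Returns a record array with fields ``frame`` (index of the later frame of
    the step), ``track`` (tracklet id), ``speed_cmps`` and ``weight`` (the
    larger estimated fish count of the step's two endpoint objects, so steps
    into or out of a merged blob are recognisable).  Tracklets are not
    persistent identities — a lost link starts a new tracklet.
    """
    next_track = 0
    track_of: dict[int, int] = {}
    rows: list[tuple[int, int, float, float]] = []
    for lk in links:
        det_t1 = detections[lk.frame_index + 1]
        new_track_of: dict[int, int] = {}
        for i, j, d, w in zip(lk.idx_t, lk.idx_t1, lk.displacements_cm, lk.weights):
            tid = track_of.get(int(i))
            if tid is None:
                tid = next_track
                next_track += 1
            new_track_of[int(j)] = tid
            w1 = det_t1.est_fish_count[int(j)]
            w_step = float(max(w, w1)) if np.isfinite(w1) else float(w)
            rows.append((lk.frame_index + 1, tid, d * fps, w_step))
        track_of = new_track_of
    rec = np.recarray(
        len(rows),
        dtype=[("frame", int), ("track", int), ("speed_cmps", float), ("weight", float)],
    )
    for k, (f, t, s, w) in enumerate(rows):
        rec[k] = (f, t, s, w)
    return rec
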