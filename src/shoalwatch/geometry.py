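"""Tank-scene geometry: circular tank, monitored chord region, enrichment disc.

Coordinates
-----------
World coordinates are centimetres with the origin at the tank centre,
x increasing rightwards (image columns) and y increasing downwards (image
rows), so a point maps to pixels as ``px = image_centre + pos_cm * px_per_cm``.
The monitored region is the lower part of the tank disc cut by a horizontal
chord, emulating a camera that sees only part of the tank.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def chord_offset_for_fraction(radius: float, fraction: float) -> float:
    """Signed y-offset (cm, downward positive) of the horizontal chord such
    that the region ``y >= offset`` of the disc has the given area fraction.

    ``fraction=1`` returns ``-radius`` (whole disc), ``fraction=0.5`` returns 0.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"monitored fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return -radius

    def seg_area(d: float) -> float:
        # area of {y >= d} inside a disc of given radius
        return radius**2 * np.arccos(d / radius) - d * np.sqrt(radius**2 - d**2)

    target = fraction * np.pi * radius**2
    return brentq(lambda d: seg_area(d) - target, -radius + 1e-9, radius - 1e-9)


def segment_centroid_y(radius: float, offset: float) -> float:
    """Centroid y (cm) of the circular segment ``{y >= offset}``."""
    if offset <= -radius:
        return 0.0
    area = radius**2 * np.arccos(offset / radius) - offset * np.sqrt(
        radius**2 - offset**2
    )
    # \int y dA over the segment
    moment = (2.0 / 3.0) * (radius**2 - offset**2) ** 1.5
    return moment / area


def disc_mask(shape: tuple[int, int], center_px: tuple[float, float], radius_px: float) -> np.ndarray:
    """Boolean raster of a disc; ``center_px`` is (x=col, y=row)."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - center_px[0]) ** 2 + (yy - center_px[1]) ** 2 <= radius_px**2


def points_in_disc(points: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of (n, 2) points lying inside a disc (cm coordinates)."""
    d2 = ((points - np.asarray(center)) ** 2).sum(axis=-1)
    return d2 <= radius**2


def convex_hull_area(points: np.ndarray) -> float:
    """Area (cm^2) of the convex hull of (n, 2) points; 0 for degenerate sets."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0
    from scipy.spatial import ConvexHull, QhullError

    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0
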