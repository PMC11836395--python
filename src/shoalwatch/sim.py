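"""Agent-based simulation of a fish group in a circular tank, rendered to
overhead-view frames with full ground truth.

The simulator emulates the study scene the pipeline is built for: a 1 m
circular tank of which the camera monitors a partial field of view, an
optional suspended enrichment structure (a 70 cm disc) rendered as a static
darker texture, and a group of fish whose cohesion, swimming speed, dwelling
under the enrichment, and post-stimulus darting are all controllable.  Every
run emits per-frame agent positions and darting flags, so each pipeline stage
can be checked against exact ground truth.

Kinematics are a discrete-time correlated random walk: each agent moves a
fixed step ``mean_speed / fps`` per frame along a heading blended from its
previous heading (persistence), a unit pull toward the current group centroid
whose weight decays with ``dispersion``, an optional pull toward the
enrichment centre weighted by ``enrichment_affinity``, and isotropic noise.
The tank wall reflects specularly.  Darting is an inhomogeneous Poisson
process per agent with exponentially decaying rate after stimulus onset; an
active dart multiplies the step length for a fixed duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .background import FrameSequence

# Direction-blend weights of the correlated random walk.  Persistence and
# noise are fixed; centroid attraction is 1/(1+dispersion) and enrichment
# attraction is ENRICHMENT_WEIGHT * enrichment_affinity.
PERSISTENCE_WEIGHT = 0.6
NOISE_WEIGHT = 0.8
ENRICHMENT_WEIGHT = 1.5
REPULSION_WEIGHT = 1.2
REPULSION_RADIUS_BL = 1.0  # zone of repulsion, in body lengths

#: Fraction of the shorter image side spanned by the tank diameter.
TANK_IMAGE_FILL = 0.92

BACKGROUND_LEVEL = 200.0
BACKGROUND_TEXTURE_SD = 12.0
ENRICHMENT_SHADE = 0.85  # static multiplicative darkening under the structure
FISH_INTENSITY = 60.0
OUTSIDE_TANK_LEVEL = 120.0


@dataclass
class TankScene:
    """Static scene geometry: tank, monitored field of view, enrichment."""

    tank_diameter_cm: float = 100.0
    monitored_fraction: float = 0.5
    enrichment_center_cm: Optional[tuple[float, float]] = None  # None = no structure
    enrichment_diameter_cm: float = 70.0
    image_size_px: tuple[int, int] = (512, 512)  # (height, width)
    background_texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.tank_diameter_cm <= 0:
            raise ValueError("tank_diameter_cm must be positive")
        if not 0.0 < self.monitored_fraction <= 1.0:
            raise ValueError("monitored_fraction must be in (0, 1]")
        if self.enrichment_center_cm is not None:
            c = np.asarray(self.enrichment_center_cm, dtype=float)
            if np.hypot(*c) + self.enrichment_diameter_cm / 2 > self.tank_radius_cm + 1e-9:
                raise ValueError("enrichment disc must lie within the tank")

    @property
    def tank_radius_cm(self) -> float:
        return self.tank_diameter_cm / 2.0

    @property
    def px_per_cm(self) -> float:
        return TANK_IMAGE_FILL * min(self.image_size_px) / self.tank_diameter_cm

    @property
    def center_px(self) -> tuple[float, float]:
        h, w = self.image_size_px
        return ((w - 1) / 2.0, (h - 1) / 2.0)  # (x=col, y=row)

    @property
    def monitored_chord_cm(self) -> float:
        """y offset of the chord bounding the monitored region (cm)."""
        return geometry.chord_offset_for_fraction(
            self.tank_radius_cm, self.monitored_fraction
        )

    @property
    def monitored_area_cm2(self) -> float:
        return self.monitored_fraction * np.pi * self.tank_radius_cm**2

    def monitored_centroid_cm(self) -> np.ndarray:
        y = geometry.segment_centroid_y(self.tank_radius_cm, self.monitored_chord_cm)
        return np.array([0.0, y])

    def cm_to_px(self, pos_cm: np.ndarray) -> np.ndarray:
        cx, cy = self.center_px
        return np.asarray(pos_cm) * self.px_per_cm + np.array([cx, cy])

    def tank_mask(self) -> np.ndarray:
        return geometry.disc_mask(
            self.image_size_px, self.center_px, self.tank_radius_cm * self.px_per_cm
        )

    def monitored_mask(self) -> np.ndarray:
        mask = self.tank_mask()
        if self.monitored_fraction < 1.0:
            h, w = self.image_size_px
            rows = np.arange(h)[:, None]
            chord_row = self.center_px[1] + self.monitored_chord_cm * self.px_per_cm
            mask &= np.broadcast_to(rows >= chord_row, (h, w))
        return mask

    def enrichment_mask(self) -> np.ndarray:
        """Full enrichment-disc raster (not clipped to the monitored region)."""
        if self.enrichment_center_cm is None:
            return np.zeros(self.image_size_px, dtype=bool)
        center_px = self.cm_to_px(np.asarray(self.enrichment_center_cm, dtype=float))
        return geometry.disc_mask(
            self.image_size_px,
            tuple(center_px),
            self.enrichment_diameter_cm / 2 * self.px_per_cm,
        )

    def in_enrichment(self, points_cm: np.ndarray) -> np.ndarray:
        if self.enrichment_center_cm is None:
            return np.zeros(len(points_cm), dtype=bool)
        return geometry.points_in_disc(
            points_cm,
            np.asarray(self.enrichment_center_cm, dtype=float),
            self.enrichment_diameter_cm / 2,
        )

    def in_monitored(self, points_cm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_cm)
        inside = geometry.points_in_disc(pts, np.zeros(2), self.tank_radius_cm)
        if self.monitored_fraction < 1.0:
            inside &= pts[:, 1] >= self.monitored_chord_cm
        return inside

    def to_dict(self) -> dict:
        return {
            "tank_diameter_cm": self.tank_diameter_cm,
            "monitored_fraction": self.monitored_fraction,
            "enrichment_center_cm": (
                None
                if self.enrichment_center_cm is None
                else [float(v) for v in self.enrichment_center_cm]
            ),
            "enrichment_diameter_cm": self.enrichment_diameter_cm,
            "image_size_px": [int(v) for v in self.image_size_px],
            "background_texture_seed": int(self.background_texture_seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TankScene":
        d = dict(d)
        if d.get("enrichment_center_cm") is not None:
            d["enrichment_center_cm"] = tuple(d["enrichment_center_cm"])
        if "image_size_px" in d:
            d["image_size_px"] = tuple(d["image_size_px"])
        return cls(**d)


@dataclass
class SchoolParams:
    """Group composition and behaviour parameters."""

    n_fish: int = 20
    body_length_cm: float = 5.0
    aspect_ratio: float = 3.0  # body length / body width
    mean_speed_cmps: float = 6.0
    dispersion: float = 1.0  # 0 = maximally tight group
    enrichment_affinity: float = 0.0  # in [0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if self.mean_speed_cmps < 0:
            raise ValueError("mean_speed_cmps must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.enrichment_affinity <= 1.0:
            raise ValueError("enrichment_affinity must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_fish": self.n_fish,
            "body_length_cm": self.body_length_cm,
            "aspect_ratio": self.aspect_ratio,
            "mean_speed_cmps": self.mean_speed_cmps,
            "dispersion": self.dispersion,
            "enrichment_affinity": self.enrichment_affinity,
            "seed": self.seed,
        }


@dataclass
class StimulusParams:
    """Novel-object stimulus: darting bursts decaying after onset.

    The per-agent dart rate at time t >= onset is
    ``initial_dart_rate_per_fish_per_s * exp(-(t - onset) / decay_timescale_s)``;
    each dart multiplies the agent's speed by ``dart_speed_multiplier`` for
    ``dart_duration_s`` seconds.
    """

    onset_s: float = 0.0
    initial_dart_rate_per_fish_per_s: float = 0.1
    decay_timescale_s: float = 15.0
    dart_speed_multiplier: float = 4.0
    dart_duration_s: float = 0.5

    def __post_init__(self) -> None:
        if self.initial_dart_rate_per_fish_per_s < 0 or self.decay_timescale_s < 0:
            raise ValueError("dart rate and decay timescale must be >= 0")
        if self.dart_speed_multiplier <= 1:
            raise ValueError("dart_speed_multiplier must be > 1")
        if self.dart_duration_s < 0:
            raise ValueError("dart_duration_s must be >= 0")

    def to_dict(self) -> dict:
        return {
            "onset_s": self.onset_s,
            "initial_dart_rate_per_fish_per_s": self.initial_dart_rate_per_fish_per_s,
            "decay_timescale_s": self.decay_timescale_s,
            "dart_speed_multiplier": self.dart_speed_multiplier,
            "dart_duration_s": self.dart_duration_s,
        }


@dataclass
class Trajectories:
    """Simulated agent state per frame (the renderer's input)."""

    positions_cm: np.ndarray  # (n_frames, n_fish, 2)
    headings: np.ndarray  # (n_frames, n_fish, 2) unit vectors
    darting: np.ndarray  # (n_frames, n_fish) bool
    fps: float
    school: SchoolParams

    @property
    def n_frames(self) -> int:
        return self.positions_cm.shape[0]

    @property
    def n_fish(self) -> int:
        return self.positions_cm.shape[1]


@dataclass
class GroundTruth:
    """Per-frame oracle for every pipeline stage."""

    positions_cm: np.ndarray  # (n_frames, n_fish, 2)
    darting: np.ndarray  # (n_frames, n_fish) bool
    hull_area_cm2: np.ndarray  # (n_frames,)
    frac_in_enrichment: np.ndarray  # (n_frames,), over all agents
    frac_in_enrichment_monitored: np.ndarray  # among agents in the monitored region
    fps: float
    scene: TankScene
    school: SchoolParams
    stimulus: Optional[StimulusParams] = None

    def mean_step_cm(self) -> float:
        """Mean per-agent displacement per frame step (cm)."""
        steps = np.linalg.norm(np.diff(self.positions_cm, axis=0), axis=-1)
        return float(steps.mean())

    def dart_onsets(self) -> list[tuple[float, int]]:
        """(time_s, agent_id) of each dart onset (rising edge of the flag)."""
        onsets: list[tuple[float, int]] = []
        d = self.darting
        rising = d & ~np.vstack([np.zeros((1, d.shape[1]), dtype=bool), d[:-1]])
        frames, agents = np.nonzero(rising)
        for f, a in zip(frames, agents):
            onsets.append((f / self.fps, int(a)))
        return onsets


def simulate_school(
    scene: TankScene,
    school: SchoolParams,
    stimulus: Optional[StimulusParams] = None,
    duration_s: float = 60.0,
    fps: float = 10.0,
) -> tuple[Trajectories, GroundTruth]:
    """Run the correlated-random-walk school simulation.

    Deterministic for a fixed ``school.seed``.  Returns the trajectory set and
    the ground-truth record (positions, darting flags, per-frame convex-hull
    area and enrichment-occupancy fractions).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fps <= 0:
        raise ValueError("fps must be positive")
    n_frames = int(round(duration_s * fps))
    if n_frames < 1:
        raise ValueError("duration too short for the frame rate")
    n = school.n_fish
    rng = np.random.default_rng(school.seed)
    radius = scene.tank_radius_cm
    # keep half a body length of clearance from the wall
    r_eff = max(radius - school.body_length_cm / 2.0, radius * 0.5)

    # Initial spread grows with dispersion; dispersion 0 puts every agent at
    # the common start point (the monitored-region centroid).
    start_center = scene.monitored_centroid_cm()
    spread_sd = 0.25 * radius * (1.0 - np.exp(-school.dispersion))
    pos = start_center + spread_sd * rng.standard_normal((n, 2))
    r = np.linalg.norm(pos, axis=1)
    too_far = r > r_eff
    if np.any(too_far):
        pos[too_far] *= (r_eff / r[too_far])[:, None] * 0.95

    angles = rng.uniform(0, 2 * np.pi, size=n)
    heading = np.column_stack([np.cos(angles), np.sin(angles)])

    # attraction decays exponentially so high dispersion approaches free
    # diffusion and the group can fill the tank
    w_c = np.exp(-school.dispersion)
    w_e = ENRICHMENT_WEIGHT * school.enrichment_affinity
    enr_center = (
        None
        if scene.enrichment_center_cm is None
        else np.asarray(scene.enrichment_center_cm, dtype=float)
    )
    enr_radius = scene.enrichment_diameter_cm / 2.0
    r_rep = REPULSION_RADIUS_BL * school.body_length_cm

    step = school.mean_speed_cmps / fps
    dart_frames_left = np.zeros(n, dtype=int)
    dart_len = 0 if stimulus is None else int(round(stimulus.dart_duration_s * fps))

    positions = np.empty((n_frames, n, 2))
    headings = np.empty((n_frames, n, 2))
    darting = np.zeros((n_frames, n), dtype=bool)
    positions[0] = pos
    headings[0] = heading
    darting[0] = dart_frames_left > 0

    for i in range(1, n_frames):
        t = i / fps
        if stimulus is not None and t >= stimulus.onset_s:
            rate = stimulus.initial_dart_rate_per_fish_per_s * np.exp(
                -(t - stimulus.onset_s) / max(stimulus.decay_timescale_s, 1e-12)
            )
            p_event = -np.expm1(-rate / fps)
            fire = rng.random(n) < p_event
            dart_frames_left = np.where(
                fire & (dart_frames_left == 0), dart_len, dart_frames_left
            )

        centroid = pos.mean(axis=0)
        to_c = centroid - pos
        norm_c = np.linalg.norm(to_c, axis=1, keepdims=True)
        unit_c = np.divide(to_c, norm_c, out=np.zeros_like(to_c), where=norm_c > 1e-12)

        drift = PERSISTENCE_WEIGHT * heading + w_c * unit_c
        if n > 1:
            # zone of repulsion: push away from neighbours within one body
            # length so agents do not stack on top of each other
            diff = pos[:, None, :] - pos[None, :, :]
            d2 = (diff**2).sum(axis=-1)
            np.fill_diagonal(d2, np.inf)
            close = d2 < r_rep**2
            if close.any():
                dd = np.sqrt(d2)
                inv = np.zeros_like(dd)
                ok = np.isfinite(dd) & (dd > 1e-12)
                inv[ok] = 1.0 / dd[ok]
                rep = np.where(close[:, :, None], diff * inv[:, :, None], 0.0).sum(axis=1)
                norm_r = np.linalg.norm(rep, axis=1, keepdims=True)
                drift += REPULSION_WEIGHT * np.divide(
                    rep, norm_r, out=np.zeros_like(rep), where=norm_r > 1e-12
                )
        if enr_center is not None and w_e > 0:
            # homing bias acts only on agents outside the structure's disc,
            # so affinity tunes the dwell fraction instead of pinning agents
            # to the disc centre
            to_e = enr_center - pos
            norm_e = np.linalg.norm(to_e, axis=1, keepdims=True)
            outside_enr = (norm_e[:, 0] > enr_radius)[:, None]
            drift += np.where(outside_enr, w_e, 0.0) * np.divide(
                to_e, norm_e, out=np.zeros_like(to_e), where=norm_e > 1e-12
            )
        noise_angles = rng.uniform(0, 2 * np.pi, size=n)
        drift += NOISE_WEIGHT * np.column_stack(
            [np.cos(noise_angles), np.sin(noise_angles)]
        )
        norm_d = np.linalg.norm(drift, axis=1, keepdims=True)
        direction = np.where(norm_d > 1e-12, drift / np.maximum(norm_d, 1e-12), heading)

        active = dart_frames_left > 0
        mult = np.where(
            active, stimulus.dart_speed_multiplier if stimulus else 1.0, 1.0
        )
        new_pos = pos + direction * (step * mult)[:, None]

        # specular reflection at the tank wall
        r_new = np.linalg.norm(new_pos, axis=1)
        outside = r_new > r_eff
        if np.any(outside):
            normal = new_pos[outside] / r_new[outside, None]
            overshoot = np.clip(2 * r_eff - r_new[outside], 0.0, r_eff)
            new_pos[outside] = normal * overshoot[:, None]
            dn = (direction[outside] * normal).sum(axis=1, keepdims=True)
            direction[outside] = direction[outside] - 2 * dn * normal

        # heading follows the realised movement; a non-swimming fish keeps
        # its previous orientation
        moved = new_pos - pos
        norm_m = np.linalg.norm(moved, axis=1, keepdims=True)
        heading = np.where(norm_m > 1e-12, moved / np.maximum(norm_m, 1e-12), heading)
        pos = new_pos

        positions[i] = pos
        headings[i] = heading
        darting[i] = active
        dart_frames_left = np.maximum(dart_frames_left - 1, 0)

    hull = np.array([geometry.convex_hull_area(positions[i]) for i in range(n_frames)])
    if enr_center is not None:
        frac = np.array(
            [scene.in_enrichment(positions[i]).mean() for i in range(n_frames)]
        )
        frac_mon = np.empty(n_frames)
        for i in range(n_frames):
            mon = scene.in_monitored(positions[i])
            if mon.any():
                inside = scene.in_enrichment(positions[i]) & mon
                frac_mon[i] = inside.sum() / mon.sum()
            else:
                frac_mon[i] = np.nan
    else:
        frac = np.zeros(n_frames)
        frac_mon = np.zeros(n_frames)

    traj = Trajectories(
        positions_cm=positions,
        headings=headings,
        darting=darting,
        fps=fps,
        school=school,
    )
    gt = GroundTruth(
        positions_cm=positions,
        darting=darting,
        hull_area_cm2=hull,
        frac_in_enrichment=frac,
        frac_in_enrichment_monitored=frac_mon,
        fps=fps,
        scene=scene,
        school=school,
        stimulus=stimulus,
    )
    return traj, gt


def render_background(scene: TankScene) -> np.ndarray:
    """Noise-free static background raster (float32), fish-free.

    Light textured tank floor, darker matte outside the tank disc, and a
    semi-transparent darker texture under the enrichment structure.
    """
    rng = np.random.default_rng(scene.background_texture_seed)
    h, w = scene.image_size_px
    from scipy.ndimage import gaussian_filter

    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    texture *= BACKGROUND_TEXTURE_SD / max(texture.std(), 1e-9)
    bg = BACKGROUND_LEVEL + texture
    tank = scene.tank_mask()
    bg[~tank] = OUTSIDE_TANK_LEVEL
    enr = scene.enrichment_mask()
    if enr.any():
        grain = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
        grain *= 4.0 / max(grain.std(), 1e-9)
        bg[enr & tank] = bg[enr & tank] * ENRICHMENT_SHADE + grain[enr & tank]
    return np.clip(bg, 0, 255).astype(np.float32)


def _draw_ellipse(
    img: np.ndarray,
    center_px: np.ndarray,
    a_px: float,
    b_px: float,
    heading: np.ndarray,
    value: float,
) -> None:
    h, w = img.shape
    cx, cy = center_px
    ext = a_px + 1.0
    x0, x1 = int(np.floor(cx - ext)), int(np.ceil(cx + ext)) + 1
    y0, y1 = int(np.floor(cy - ext)), int(np.ceil(cy + ext)) + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    xx, yy = np.meshgrid(xs, ys)
    hx, hy = heading
    u = (xx * hx + yy * hy) / a_px
    v = (-xx * hy + yy * hx) / b_px
    inside = u * u + v * v <= 1.0
    img[y0:y1, x0:x1][inside] = value


def render_frames(
    traj: Trajectories,
    scene: TankScene,
    noise_sd: float = 2.0,
    noise_seed: int = 0,
    clip_id: str = "",
) -> FrameSequence:
    """Rasterise trajectories into a grayscale frame sequence.

    Fish are dark ellipses of length ``body_length_cm`` oriented along the
    velocity, on the static textured background; i.i.d. Gaussian pixel noise
    of standard deviation ``noise_sd`` is added per frame.
    """
    body_px = traj.school.body_length_cm * scene.px_per_cm
    if body_px < 2.0:
        raise ValueError(
            f"image too small: body length is {body_px:.2f} px, need >= 2 px"
        )
    a_px = body_px / 2.0
    b_px = body_px / (2.0 * traj.school.aspect_ratio)
    bg = render_background(scene)
    rng = np.random.default_rng(noise_seed)
    frames = np.empty((traj.n_frames, *scene.image_size_px), dtype=np.uint8)
    buf = np.empty_like(bg)
    for i in range(traj.n_frames):
        np.copyto(buf, bg)
        centers = scene.cm_to_px(traj.positions_cm[i])
        for j in range(traj.n_fish):
            _draw_ellipse(buf, centers[j], a_px, b_px, traj.headings[i, j], FISH_INTENSITY)
        if noise_sd > 0:
            noisy = buf + rng.standard_normal(buf.shape).astype(np.float32) * noise_sd
        else:
            noisy = buf
        frames[i] = np.clip(noisy, 0, 255).astype(np.uint8)
    return FrameSequence(
        frames=frames,
        fps=traj.fps,
        px_per_cm=scene.px_per_cm,
        monitored_mask=scene.monitored_mask(),
        clip_id=clip_id,
        meta={
            "scene": scene.to_dict(),
            "school": traj.school.to_dict(),
            "noise_sd": noise_sd,
            "noise_seed": noise_seed,
        },
    )


def true_fish_mask(traj: Trajectories, scene: TankScene, frame: int) -> np.ndarray:
    """Exact rasterised fish-pixel mask for one frame (rendering oracle)."""
    body_px = traj.school.body_length_cm * scene.px_per_cm
    a_px = body_px / 2.0
    b_px = body_px / (2.0 * traj.school.aspect_ratio)
    img = np.zeros(scene.image_size_px, dtype=np.float32)
    centers = scene.cm_to_px(traj.positions_cm[frame])
    for j in range(traj.n_fish):
        _draw_ellipse(img, centers[j], a_px, b_px, traj.headings[frame, j], 1.0)
    return img > 0


def write_ground_truth(gt: GroundTruth, path: str | Path) -> pd.DataFrame:
    """Write ground truth as a tidy CSV (one row per frame x agent) with the
    scene/school/stimulus parameters in a YAML sidecar next to it."""
    path = Path(path)
    n_frames, n = gt.darting.shape
    frames = np.repeat(np.arange(n_frames), n)
    agents = np.tile(np.arange(n), n_frames)
    df = pd.DataFrame(
        {
            "frame": frames,
            "time_s": frames / gt.fps,
            "agent": agents,
            "x_cm": gt.positions_cm[:, :, 0].ravel(),
            "y_cm": gt.positions_cm[:, :, 1].ravel(),
            "darting": gt.darting.ravel(),
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "scene": gt.scene.to_dict(),
        "school": gt.school.to_dict(),
        "stimulus": None if gt.stimulus is None else gt.stimulus.to_dict(),
        "fps": gt.fps,
        "seed": gt.school.seed,
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return df


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
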