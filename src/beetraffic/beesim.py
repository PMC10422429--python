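"""Synthetic on-hive video generator with per-frame ground truth.

Renders bee-sized dark ellipses moving over a static procedural
hive-entrance background (textured field plus a bright landing-pad band at
the bottom), following the four qualitative flight patterns observed at
hive entrances: *straight* (fast, near-linear in/out), *inward/outward
zigzag* (repeated reversals of the approach component), *land-and-crawl*
(flight ending on the landing pad followed by crawling or stillness), and
*parallel* (flight parallel to the pad).  Every frame comes with tight
ground-truth boxes and a known motion state per bee, so the whole pipeline —
detection, motion, alignment, evaluation — is testable without real videos.

Bees are uniform dark ellipses rather than textured sprites: enough to drive
a difference-based motion detector and the oracle detector; photorealism is
a non-goal.  The default geometry is a 240×320 test frame; area thresholds
of the motion detector should be rescaled with
:func:`beetraffic.motion_detect.scaled_min_area`.
"""

from __future__ import annotations

import csv
import enum
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .evaluation import GroundTruthEvent, MotionState
from .frames_io import Frame, GroundTruthBox, frame_filename, write_labels

__all__ = [
    "FlightPattern",
    "SimConfig",
    "Trajectory",
    "SimScene",
    "pattern_waypoints",
    "simulate",
    "write_scene",
    "count_flying_truth",
]


class FlightPattern(enum.Enum):
    STRAIGHT = "STRAIGHT"
    INWARD_ZIGZAG = "INWARD_ZIGZAG"
    OUTWARD_ZIGZAG = "OUTWARD_ZIGZAG"
    LAND_AND_CRAWL = "LAND_AND_CRAWL"
    PARALLEL = "PARALLEL"


def _default_mix() -> dict[FlightPattern, float]:
    # straight in/out dominates real entrance traffic
    return {FlightPattern.STRAIGHT: 0.40,
            FlightPattern.INWARD_ZIGZAG: 0.15,
            FlightPattern.OUTWARD_ZIGZAG: 0.15,
            FlightPattern.LAND_AND_CRAWL: 0.15,
            FlightPattern.PARALLEL: 0.15}


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters.

    Speeds are px/frame at the default 240×320 test geometry; the straight
    pattern is the fastest of the mix.  ``camera_height_class`` 2 (logger on
    the second super) shrinks the apparent bee size.  Motion-state
    thresholds: flying ≥ ``flying_min_speed``, crawling ≥
    ``crawling_min_speed``, else stationary.
    """

    frame_size: tuple[int, int] = (240, 320)   # (H, W)
    n_frames: int = 30
    camera_height_class: int = 1
    n_bees: int = 5
    pattern_mix: dict[FlightPattern, float] = field(default_factory=_default_mix)
    bee_half_axes: tuple[float, float] = (7.0, 4.0)  # (along heading, across)
    bee_size_spread: float = 1.0
    speed_straight: tuple[float, float] = (8.0, 12.0)
    speed_zigzag: tuple[float, float] = (3.5, 6.0)
    speed_parallel: tuple[float, float] = (3.5, 6.0)
    speed_land_flight: tuple[float, float] = (4.0, 8.0)
    crawl_max_speed: float = 2.0
    flying_min_speed: float = 3.0
    crawling_min_speed: float = 1.0
    landing_pad_frac: float = 0.18   # bottom band of the frame
    bee_intensity: float = 35.0
    pixel_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_mix must sum to 1, got {total}")
        if min(self.bee_half_axes) <= 0:
            raise ValueError("bee size must be positive")
        h, w = self.frame_size
        if 2 * max(self.bee_half_axes) >= min(h, w):
            raise ValueError("bee size larger than frame")

    @property
    def size_scale(self) -> float:
        return 1.0 if self.camera_height_class == 1 else 0.55

    @property
    def pad_top_row(self) -> float:
        return self.frame_size[0] * (1.0 - self.landing_pad_frac)


@dataclass(frozen=True)
class Trajectory:
    """Per-frame centers and motion states of one bee."""

    pattern: FlightPattern
    waypoints: np.ndarray           # n_frames × 2 of (x, y)
    motion_states: tuple[MotionState, ...]
    half_axes: tuple[float, float]  # (a along heading, b across)

    def heading(self, i: int) -> float:
        """Orientation angle at frame i (radians), along the displacement."""
        n = len(self.waypoints)
        j0, j1 = (i - 1, i) if i > 0 else (0, min(1, n - 1))
        dx, dy = self.waypoints[j1] - self.waypoints[j0]
        if dx == 0 and dy == 0:
            return 0.0
        return float(np.arctan2(dy, dx))


def _states_from_displacements(wp: np.ndarray, cfg: SimConfig
                               ) -> tuple[MotionState, ...]:
    disp = np.linalg.norm(np.diff(wp, axis=0), axis=1)
    states = []
    for i in range(len(wp)):
        d = disp[i - 1] if i > 0 else (disp[0] if len(disp) else 0.0)
        if d >= cfg.flying_min_speed:
            states.append(MotionState.FLYING)
        elif d >= cfg.crawling_min_speed:
            states.append(MotionState.CRAWLING)
        else:
            states.append(MotionState.STATIONARY)
    return tuple(states)


def _zigzag_velocities(n: int, speed: float, inward: bool,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-frame velocities with 2–4 sign reversals of the approach (y)
    component; inward starts toward the pad (vy > 0)."""
    if n < 8:
        raise ValueError("zigzag patterns need at least 8 frames")
    n_rev = int(rng.integers(2, 5))
    # segment boundaries splitting the n-1 steps into n_rev+1 runs
    cuts = np.sort(rng.choice(np.arange(1, n - 1), size=n_rev, replace=False))
    bounds = np.concatenate([[0], cuts, [n - 1]])
    v = np.zeros((n - 1, 2))
    sign = 1.0 if inward else -1.0
    for k in range(len(bounds) - 1):
        seg = slice(bounds[k], bounds[k + 1])
        ang = rng.uniform(np.pi / 6, np.pi / 2.2)  # mostly vertical
        vy = sign * speed * np.sin(ang)
        vx = speed * np.cos(ang) * (1 if rng.random() < 0.5 else -1)
        v[seg] = (vx, vy)
        sign = -sign
    return v


def pattern_waypoints(pattern: FlightPattern, start: tuple[float, float],
                      config: SimConfig, rng: np.random.Generator
                      ) -> Trajectory:
    """Build one trajectory of ``config.n_frames`` waypoints from ``start``."""
    n = config.n_frames
    x0, y0 = start
    wp = np.zeros((n, 2))
    wp[0] = (x0, y0)
    scale = config.size_scale
    a = max(1.5, (config.bee_half_axes[0] +
                  rng.normal(0, config.bee_size_spread)) * scale)
    b = max(1.0, (config.bee_half_axes[1] +
                  rng.normal(0, config.bee_size_spread * 0.5)) * scale)

    if pattern is FlightPattern.STRAIGHT:
        speed = rng.uniform(*config.speed_straight)
        # near-vertical in or out, slight heading noise per frame
        ang = rng.uniform(np.pi / 3, 2 * np.pi / 3)
        if rng.random() < 0.5:
            ang = -ang
        for i in range(1, n):
            ang += rng.normal(0.0, 0.03)
            wp[i] = wp[i - 1] + speed * np.array([np.cos(ang), np.sin(ang)])
    elif pattern in (FlightPattern.INWARD_ZIGZAG, FlightPattern.OUTWARD_ZIGZAG):
        speed = rng.uniform(*config.speed_zigzag)
        v = _zigzag_velocities(n, speed,
                               pattern is FlightPattern.INWARD_ZIGZAG, rng)
        wp[1:] = wp[0] + np.cumsum(v, axis=0)
    elif pattern is FlightPattern.PARALLEL:
        speed = rng.uniform(*config.speed_parallel)
        direction = 1 if rng.random() < 0.5 else -1
        for i in range(1, n):
            wp[i] = wp[i - 1] + (direction * speed, 0.0)
    elif pattern is FlightPattern.LAND_AND_CRAWL:
        speed = rng.uniform(*config.speed_land_flight)
        land_y = config.pad_top_row + rng.uniform(0, 0.6) * (
            config.frame_size[0] - config.pad_top_row - 2 * b) + b
        # guarantee touchdown well inside the clip so the crawl phase exists
        t_land = rng.uniform(0.3, 0.7) * n
        if speed > 0 and land_y > y0:
            speed = max(speed, (land_y - y0) / max(t_land, 1.0))
        crawling = rng.random() < 0.5
        crawl_v = (rng.uniform(config.crawling_min_speed,
                               config.crawl_max_speed)
                   * (1 if rng.random() < 0.5 else -1)) if crawling else 0.0
        landed = False
        for i in range(1, n):
            if not landed:
                step = np.array([rng.normal(0, 0.3), speed])
                nxt = wp[i - 1] + step
                if nxt[1] >= land_y:
                    nxt[1] = land_y
                    landed = True
                wp[i] = nxt
            else:
                wp[i] = wp[i - 1] + (crawl_v, 0.0)
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern {pattern}")
    return Trajectory(pattern=pattern, waypoints=wp,
                      motion_states=_states_from_displacements(wp, config),
                      half_axes=(a, b))


def _ellipse_bbox(cx: float, cy: float, a: float, b: float, theta: float
                  ) -> tuple[float, float, float, float]:
    hw = float(np.hypot(a * np.cos(theta), b * np.sin(theta)))
    hh = float(np.hypot(a * np.sin(theta), b * np.cos(theta)))
    return (cx - hw, cy - hh, cx + hw, cy + hh)


def _render_ellipse(img: np.ndarray, cx: float, cy: float, a: float,
                    b: float, theta: float, intensity: float) -> None:
    """Alpha-composite an anti-aliased dark ellipse onto a gray image."""
    h, w = img.shape
    x1, y1, x2, y2 = _ellipse_bbox(cx, cy, a, b, theta)
    c0 = max(0, int(np.floor(x1)) - 1)
    c1 = min(w, int(np.ceil(x2)) + 2)
    r0 = max(0, int(np.floor(y1)) - 1)
    r1 = min(h, int(np.ceil(y2)) + 2)
    if c0 >= c1 or r0 >= r1:
        return
    ys, xs = np.mgrid[r0:r1, c0:c1]
    dx = xs - cx
    dy = ys - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    rho = np.sqrt(u ** 2 + v ** 2)
    # ~1 px anti-aliased edge in units of the smaller half-axis
    alpha = np.clip((1.0 - rho) * min(a, b) + 0.5, 0.0, 1.0)
    img[r0:r1, c0:c1] = img[r0:r1, c0:c1] * (1 - alpha) + intensity * alpha


def _background(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.frame_size
    noise = rng.normal(0.0, 1.0, (h, w))
    texture = ndimage.gaussian_filter(noise, sigma=6.0)
    texture = texture / (np.abs(texture).max() + 1e-12)
    bg = 130.0 + 25.0 * texture
    bg[int(cfg.pad_top_row):, :] = 205.0  # bright landing pad band
    return bg


@dataclass
class SimScene:
    """Simulator output: frames plus per-frame ground truth."""

    config: SimConfig
    frames: list[Frame]
    truth: dict[int, list[GroundTruthEvent]]       # pixel boxes + states
    truth_boxes: dict[int, list[GroundTruthBox]]   # normalized label dialect
    trajectories: list[Trajectory]


def simulate(config: SimConfig = SimConfig()) -> SimScene:
    """Render the scene and emit ground truth.

    Truth includes only fully visible, in-frame bees (mirroring the manual
    labeling protocol of full-size unoccluded bees).  Bit-identical under a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_size
    bg = _background(config, rng)

    patterns = list(config.pattern_mix.keys())
    probs = np.array([config.pattern_mix[p] for p in patterns])
    trajectories: list[Trajectory] = []
    for _ in range(config.n_bees):
        pattern = patterns[int(rng.choice(len(patterns), p=probs))]
        margin = 2 * max(config.bee_half_axes) + 2
        if pattern is FlightPattern.LAND_AND_CRAWL:
            start = (rng.uniform(margin, w - margin),
                     rng.uniform(margin, config.pad_top_row * 0.4))
        else:
            start = (rng.uniform(margin, w - margin),
                     rng.uniform(margin, h - margin))
        trajectories.append(pattern_waypoints(pattern, start, config, rng))

    frames: list[Frame] = []
    truth: dict[int, list[GroundTruthEvent]] = {}
    truth_boxes: dict[int, list[GroundTruthBox]] = {}
    for i in range(config.n_frames):
        img = bg.copy()
        events: list[GroundTruthEvent] = []
        boxes: list[GroundTruthBox] = []
        for traj in trajectories:
            cx, cy = traj.waypoints[i]
            a, b = traj.half_axes
            theta = traj.heading(i)
            bbox = _ellipse_bbox(cx, cy, a, b, theta)
            if bbox[0] > -2 * a and bbox[2] < w + 2 * a:  # near/inside frame
                _render_ellipse(img, cx, cy, a, b, theta, config.bee_intensity)
            fully_visible = (bbox[0] >= 0 and bbox[1] >= 0 and
                             bbox[2] <= w and bbox[3] <= h)
            if fully_visible:
                events.append(GroundTruthEvent(
                    frame_index=i + 1, box=bbox,
                    motion_state=traj.motion_states[i]))
                boxes.append(GroundTruthBox(
                    frame_index=i + 1,
                    cx_norm=(bbox[0] + bbox[2]) / 2 / w,
                    cy_norm=(bbox[1] + bbox[3]) / 2 / h,
                    w_norm=(bbox[2] - bbox[0]) / w,
                    h_norm=(bbox[3] - bbox[1]) / h))
        if config.pixel_noise_sigma > 0:
            img = img + rng.normal(0.0, config.pixel_noise_sigma, img.shape)
        gray = np.clip(img, 0, 255).astype(np.uint8)
        pixels = np.stack([gray] * 3, axis=-1)
        frames.append(Frame(index=i + 1, pixels=pixels))
        truth[i + 1] = events
        truth_boxes[i + 1] = boxes
    return SimScene(config=config, frames=frames, truth=truth,
                    truth_boxes=truth_boxes, trajectories=trajectories)


def count_flying_truth(scene: SimScene, first: int = 2) -> int:
    """Number of (frame, flying-bee) ground-truth pairs in frames >= first."""
    return sum(1 for idx, events in scene.truth.items() if idx >= first
               for e in events if e.motion_state is MotionState.FLYING)


def write_scene(scene: SimScene, outdir: str | os.PathLike) -> None:
    """Write frame PNGs, per-frame Darknet labels, and truth.csv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    labels = out / "labels"
    labels.mkdir(exist_ok=True)
    for frame in scene.frames:
        iio.imwrite(out / frame_filename(frame.index), frame.pixels)
    for idx, boxes in scene.truth_boxes.items():
        write_labels(boxes, labels / f"frame_{idx:06d}.txt")
    with open(out / "truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "x1", "y1", "x2", "y2", "motion_state"])
        for idx in sorted(scene.truth):
            for e in scene.truth[idx]:
                writer.writerow([idx, *(f"{v:.3f}" for v in e.box),
                                 e.motion_state.value])
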