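"""Synthetic assay generator: larva behavior model plus frame renderer.

The behavior model is a correlated random walk with additive stimulus
biases.  Each frame, a larva's heading is the direction of

    persistence * u(heading_prev) + weight * u(target)

plus von Mises noise, where the target direction and weight depend on the
active stimulus epoch: away from the bar half (weight ``beta_bar``), toward
the lane's up end while dots drift up (``beta_dots``), or along the local
on-screen tangential direction of the rotating cross (``kappa_cross``).
Blind larvae (emulating photoreceptor-ablated groups) have all stimulus
weights forced to zero and perform the unbiased baseline walk.  Larvae step
forward a fixed distance per frame and reflect off the ROI walls, mimicking
the agarose walls of the plates.

The renderer composites dark ~4 mm larvae over the stimulus frame.  Each
larva is a gray capsule with a darker, wider head disc near the front, so
the intensity-weighted centroid of the dark silhouette is displaced from
the bounding-box center toward the head — the contrast and offset the
detection and orientation rules rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .geometry import PlateLayout, RoiShape, RoiSpec
from .stimuli import (
    AssaySchedule,
    StimulusEpoch,
    StimulusKind,
    render_on_background,
)

TRUTH_COLUMNS = ["frame", "t_s", "roi_id", "larva_id", "x_px", "y_px", "heading_deg", "group"]


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the correlated random walk (lengths in mm, per frame).

    ``beta_bar``, ``beta_dots`` and ``kappa_cross`` are the stimulus-bias
    weights mixed against ``heading_persistence``; zero means no response.
    ``blind=True`` forces all three to zero regardless of their values.
    """

    step_length_mm: float = 1.0
    heading_persistence: float = 0.7
    beta_bar: float = 0.0
    beta_dots: float = 0.0
    kappa_cross: float = 0.0
    heading_noise_kappa: float = 4.0
    blind: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.heading_persistence <= 1.0):
            raise ValueError("heading_persistence must be in [0, 1]")
        for name in ("step_length_mm", "beta_bar", "beta_dots", "kappa_cross"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")

    @classmethod
    def responder(cls, strength: float = 2.0, **kw) -> "BehaviorParams":
        """A larva that responds to all stimuli with the given bias weight."""
        return cls(beta_bar=strength, beta_dots=strength, kappa_cross=strength, **kw)

    @classmethod
    def blind_larva(cls, **kw) -> "BehaviorParams":
        return cls(blind=True, **kw)


@dataclass(frozen=True)
class LarvaMorphology:
    """Rendered larva shape (mm) and gray levels (uint8, lower = darker)."""

    length_mm: float = 4.0
    width_mm: float = 0.8
    head_offset_mm: float = 1.3
    head_radius_mm: float = 0.7
    body_gray: int = 70
    head_gray: int = 30


@dataclass(frozen=True)
class SimulationConfig:
    layout: PlateLayout
    schedule: AssaySchedule
    larvae_per_roi: int = 5
    groups: dict[int, BehaviorParams] = field(default_factory=dict)
    group_labels: dict[int, str] = field(default_factory=dict)
    frame_interval_s: float = 6.0
    seed: int = 0
    morphology: LarvaMorphology = field(default_factory=LarvaMorphology)
    n_frames: int | None = None
    t_start_s: float = 0.0
    behavior_step_s: float = 6.0  # time base of one behavior step

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval must be positive")
        if self.behavior_step_s <= 0:
            raise ValueError("behavior_step must be positive")
        if self.larvae_per_roi < 1:
            raise ValueError("larvae_per_roi must be >= 1")

    @property
    def substeps_per_frame(self) -> int:
        """Behavior micro-steps folded into one acquisition interval.

        The walk parameters are defined per 6-s behavior step; when frames
        are taken more sparsely the larvae still move at the 6-s dynamics
        between frames, so sparse sampling does not slow them down.
        """
        return max(1, int(round(self.frame_interval_s / self.behavior_step_s)))

    def params_for(self, roi_id: int) -> BehaviorParams:
        return self.groups.get(roi_id, BehaviorParams())

    def label_for(self, roi_id: int) -> str:
        return self.group_labels.get(roi_id, "default")

    @property
    def frame_count(self) -> int:
        total = int(
            math.floor((self.schedule.total_duration_s - self.t_start_s) / self.frame_interval_s)
        )
        return total if self.n_frames is None else min(self.n_frames, total)


@dataclass
class _LarvaState:
    roi_id: int
    larva_id: int
    x: float
    y: float
    heading: float  # radians, screen frame (y down)


def _unit(theta: float) -> tuple[float, float]:
    return math.cos(theta), math.sin(theta)


def _stimulus_bias(
    epoch: StimulusEpoch,
    roi: RoiSpec,
    state: _LarvaState,
    params: BehaviorParams,
) -> tuple[float, float, float]:
    """(target_ux, target_uy, weight) for the active epoch; weight 0 = none."""
    if params.blind:
        return 0.0, 0.0, 0.0
    kind = epoch.kind
    if kind in (StimulusKind.BAR_UP_HALF, StimulusKind.BAR_DOWN_HALF):
        if params.beta_bar == 0:
            return 0.0, 0.0, 0.0
        up = _up_direction(roi)
        # avoidance: drift into the half opposite the bar
        sign = -1.0 if kind is StimulusKind.BAR_UP_HALF else 1.0
        return sign * up[0], sign * up[1], params.beta_bar
    if kind is StimulusKind.DOTS_MOVING_UP:
        if params.beta_dots == 0:
            return 0.0, 0.0, 0.0
        up = _up_direction(roi)
        return up[0], up[1], params.beta_dots
    if kind in (StimulusKind.CROSS_CW, StimulusKind.CROSS_CCW):
        if params.kappa_cross == 0:
            return 0.0, 0.0, 0.0
        tx, ty = cw_tangent(state.x, state.y, roi)
        if kind is StimulusKind.CROSS_CCW:
            tx, ty = -tx, -ty
        return tx, ty, params.kappa_cross
    return 0.0, 0.0, 0.0


def _up_direction(roi: RoiSpec) -> tuple[float, float]:
    """Unit vector pointing toward the lane's up end (screen frame)."""
    if roi.long_axis == "vertical":
        return (0.0, -1.0) if roi.up_end == "low_y" else (0.0, 1.0)
    return (-1.0, 0.0) if roi.up_end == "low_x" else (1.0, 0.0)


def cw_tangent(x: float, y: float, well_roi: RoiSpec) -> tuple[float, float]:
    """Unit tangent of on-screen clockwise motion at (x, y) about the well center.

    With d the offset from the center, the clockwise tangent in screen
    coordinates (y down) is (-d_y, d_x), normalized.
    """
    cx, cy = well_roi.center
    dx, dy = x - cx, y - cy
    n = math.hypot(dx, dy)
    if n < 1e-9:
        return 1.0, 0.0
    return -dy / n, dx / n


def _roi_margin_px(config: SimulationConfig) -> float:
    return config.morphology.length_mm / 2 * config.layout.px_per_mm + 2.0


def _place_larvae(config: SimulationConfig, rng: np.random.Generator) -> list[_LarvaState]:
    """Random non-overlapping initial positions, bounded rejection sampling."""
    margin = _roi_margin_px(config)
    min_sep = config.morphology.length_mm * config.layout.px_per_mm
    states: list[_LarvaState] = []
    for roi in config.layout.rois:
        placed: list[tuple[float, float]] = []
        for j in range(config.larvae_per_roi):
            for _ in range(500):
                x, y = _sample_point(roi, margin, rng)
                if all(math.hypot(x - px, y - py) > min_sep for px, py in placed):
                    placed.append((x, y))
                    break
            else:
                raise ValueError(
                    f"could not place {config.larvae_per_roi} non-overlapping larvae "
                    f"in ROI {roi.roi_id}"
                )
            states.append(
                _LarvaState(roi.roi_id, j, placed[-1][0], placed[-1][1],
                            rng.uniform(-math.pi, math.pi))
            )
    return states


def _sample_point(roi: RoiSpec, margin: float, rng: np.random.Generator) -> tuple[float, float]:
    x0, y0, x1, y1 = roi.bounds
    if roi.shape is RoiShape.RECTANGLE:
        return (
            rng.uniform(x0 + margin, x1 - margin),
            rng.uniform(y0 + margin, y1 - margin),
        )
    cx, cy = roi.center
    rmax = float(roi.extent) - margin  # type: ignore[arg-type]
    r = rmax * math.sqrt(rng.uniform())
    a = rng.uniform(0, 2 * math.pi)
    return cx + r * math.cos(a), cy + r * math.sin(a)


def _step_larva(
    state: _LarvaState,
    roi: RoiSpec,
    epoch: StimulusEpoch,
    params: BehaviorParams,
    step_px: float,
    margin: float,
    rng: np.random.Generator,
) -> None:
    ux, uy = _unit(state.heading)
    tx, ty, w = _stimulus_bias(epoch, roi, state, params)
    vx = params.heading_persistence * ux + w * tx
    vy = params.heading_persistence * uy + w * ty
    if math.hypot(vx, vy) < 1e-9:
        mean = state.heading
    else:
        mean = math.atan2(vy, vx)
    theta = mean + rng.vonmises(0.0, params.heading_noise_kappa)
    dx, dy = math.cos(theta), math.sin(theta)
    nx, ny = state.x + step_px * dx, state.y + step_px * dy
    nx, ny, dx, dy = _reflect(nx, ny, dx, dy, roi, margin)
    state.x, state.y = nx, ny
    state.heading = math.atan2(dy, dx)


def _reflect(
    x: float, y: float, ux: float, uy: float, roi: RoiSpec, margin: float
) -> tuple[float, float, float, float]:
    if roi.shape is RoiShape.RECTANGLE:
        x0, y0, x1, y1 = roi.bounds
        lo_x, hi_x = x0 + margin, x1 - margin
        lo_y, hi_y = y0 + margin, y1 - margin
        if x < lo_x:
            x, ux = 2 * lo_x - x, -ux
        elif x > hi_x:
            x, ux = 2 * hi_x - x, -ux
        if y < lo_y:
            y, uy = 2 * lo_y - y, -uy
        elif y > hi_y:
            y, uy = 2 * hi_y - y, -uy
        x = min(max(x, lo_x), hi_x)
        y = min(max(y, lo_y), hi_y)
        return x, y, ux, uy
    cx, cy = roi.center
    rmax = float(roi.extent) - margin  # type: ignore[arg-type]
    dx, dy = x - cx, y - cy
    d = math.hypot(dx, dy)
    if d > rmax:
        nx_, ny_ = dx / d, dy / d
        # fold the overshoot back inside and mirror the direction
        d_new = max(2 * rmax - d, 0.0)
        x, y = cx + d_new * nx_, cy + d_new * ny_
        dot = ux * nx_ + uy * ny_
        ux, uy = ux - 2 * dot * nx_, uy - 2 * dot * ny_
    return x, y, ux, uy


def render_larva(
    canvas: np.ndarray,
    position: tuple[float, float],
    heading_deg: float,
    morphology: LarvaMorphology,
    px_per_mm: float,
) -> np.ndarray:
    """Draw one larva on the RGB canvas; returns the canvas (modified in place).

    The body is a capsule of ``length_mm`` x ``width_mm`` centered on
    ``position`` and aligned with ``heading_deg`` (screen frame, 0 deg =
    right, 90 deg = down); the head disc sits ``head_offset_mm`` forward
    of the center, darker and wider than the trunk, pulling the
    intensity-weighted centroid toward the head while the bounding box
    stays centered on the body.
    """
    h, w = canvas.shape[:2]
    x, y = position
    theta = math.radians(heading_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    half_len = morphology.length_mm / 2 * px_per_mm
    half_w = morphology.width_mm / 2 * px_per_mm
    head_off = morphology.head_offset_mm * px_per_mm
    head_r = morphology.head_radius_mm * px_per_mm

    reach = int(math.ceil(half_len + head_r)) + 2
    x0, x1 = max(int(x) - reach, 0), min(int(x) + reach + 1, w)
    y0, y1 = max(int(y) - reach, 0), min(int(y) + reach + 1, h)
    if x0 >= x1 or y0 >= y1:
        return canvas
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rx = xx - x
    ry = yy - y
    # distance to the body's center segment (capsule axis), caps included
    seg_half = max(half_len - half_w, 0.0)
    along = rx * ux + ry * uy
    clamped = np.clip(along, -seg_half, seg_half)
    dx = rx - clamped * ux
    dy = ry - clamped * uy
    body = dx * dx + dy * dy <= half_w * half_w
    hx, hy = x + head_off * ux, y + head_off * uy
    head = (xx - hx) ** 2 + (yy - hy) ** 2 <= head_r * head_r

    patch = canvas[y0:y1, x0:x1]
    patch[body] = morphology.body_gray
    patch[head] = morphology.head_gray
    return canvas


def iter_simulation(
    config: SimulationConfig,
) -> Iterator[tuple[int, float, np.ndarray, list[dict]]]:
    """Yield (frame_index, t_seconds, RGB frame, ground-truth records).

    Deterministic for a fixed config (including seed): identical configs
    yield bit-identical frames and records.
    """
    rng = np.random.default_rng(config.seed)
    states = _place_larvae(config, rng)
    layout = config.layout
    margin = _roi_margin_px(config)
    step_px = {
        roi.roi_id: config.params_for(roi.roi_id).step_length_mm * layout.px_per_mm
        for roi in layout.rois
    }
    rois = {roi.roi_id: roi for roi in layout.rois}
    substeps = config.substeps_per_frame
    for idx in range(config.frame_count):
        t = config.t_start_s + idx * config.frame_interval_s
        _, epoch, t_rel = config.schedule.locate(t)
        if idx > 0:
            dt = config.frame_interval_s / substeps
            for k in range(substeps):
                t_micro = t - config.frame_interval_s + k * dt
                _, micro_epoch, _ = config.schedule.locate(t_micro)
                for s in states:
                    _step_larva(
                        s, rois[s.roi_id], micro_epoch, config.params_for(s.roi_id),
                        step_px[s.roi_id], margin, rng,
                    )
        frame = render_on_background(epoch, t_rel, layout, config.schedule.background)
        records = []
        for s in states:
            heading_deg = math.degrees(s.heading) % 360.0
            render_larva(frame, (s.x, s.y), heading_deg, config.morphology, layout.px_per_mm)
            records.append(
                {
                    "frame": idx,
                    "t_s": t,
                    "roi_id": s.roi_id,
                    "larva_id": s.larva_id,
                    "x_px": s.x,
                    "y_px": s.y,
                    "heading_deg": heading_deg,
                    "group": config.label_for(s.roi_id),
                }
            )
        yield idx, t, frame, records


def simulate_assay(config: SimulationConfig) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Run the simulation, returning all frames and the ground-truth table.

    The ground truth has one row per larva per frame with the true position
    (px), true heading (deg, screen frame), ROI id and group label.
    """
    frames: list[np.ndarray] = []
    rows: list[dict] = []
    for _, _, frame, records in iter_simulation(config):
        frames.append(frame)
        rows.extend(records)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return frames, truth
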