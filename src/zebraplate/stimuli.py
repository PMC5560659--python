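"""Assay schedules and the stimulus renderer.

An assay is an ordered list of timed stimulus epochs shown underneath the
plate: a blank background, a moving colored bar confined to one half of
each lane, a grid of colored dots drifting toward the up end of each lane,
or a colored cross rotating clockwise / counter-clockwise about each well
center.  The six named schedules reproduce the published assay designs:

* ``bar_dots``      - 15 min blank, 15 min red bar (upper half), 15 min
                      0.5 mm red dots moving up.
* ``two_bar``       - 15 min blank, 15 min red bar up, 15 min red bar down.
* ``two_bar_4x``    - 20 min blank, then 4 x (10 min bar up + 10 min bar
                      down), red.
* ``bar_dots_rgby`` - 4 x (10 min blank + 10 min bar + 10 min 1 mm dots),
                      cycling red, green, blue, yellow.
* ``cross_rgbyc``   - 20 min blank, then 5 x (10 min cw + 10 min ccw cross)
                      in red, green, blue, yellow, cyan at 90 deg / 5 s
                      (3 rotations per minute).
* ``red_cross_4x``  - 20 min blank, then 4 x (10 min cw + 10 min ccw),
                      red, 3 rotations per minute.

Cross assays use a light gray background for color separation; bar and dot
assays use white.
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .geometry import PlateKind, PlateLayout, RoiSpec

# Stimulus RGB values.  The assays name colors only; saturated primaries
# make the channel-selection rule in the detection stage unambiguous.
COLORS: dict[str, tuple[int, int, int]] = {
    "red": (255, 0, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
    "yellow": (255, 255, 0),
    "cyan": (0, 255, 255),
    "none": (0, 0, 0),
}
BACKGROUNDS: dict[str, tuple[int, int, int]] = {
    "white": (255, 255, 255),
    "light_gray": (230, 230, 230),
}


class StimulusKind(str, enum.Enum):
    BLANK = "blank"
    BAR_UP_HALF = "bar_up_half"
    BAR_DOWN_HALF = "bar_down_half"
    DOTS_MOVING_UP = "dots_moving_up"
    CROSS_CW = "cross_cw"
    CROSS_CCW = "cross_ccw"


LANE_KINDS = {StimulusKind.BAR_UP_HALF, StimulusKind.BAR_DOWN_HALF, StimulusKind.DOTS_MOVING_UP}
WELL_KINDS = {StimulusKind.CROSS_CW, StimulusKind.CROSS_CCW}
CROSS_ANGULAR_SPEED_DEG_S = 90.0 / 5.0  # 90 deg / 5 s = 3 rotations per minute


@dataclass(frozen=True)
class StimulusParams:
    """Geometry and motion of the moving patterns (all lengths in mm).

    Bar/dot translation speeds and the dot grid pitch are configuration
    choices; the cross angular speed of 18 deg/s is the published
    90 deg / 5 s.
    """

    dot_diameter_mm: float = 0.5
    dot_pitch_mm: float = 5.0
    dot_speed_mm_s: float = 5.0
    bar_height_mm: float = 10.0
    bar_speed_mm_s: float = 5.0
    angular_speed_deg_s: float = CROSS_ANGULAR_SPEED_DEG_S
    initial_angle_deg: float = 0.0
    arm_width_mm: float = 2.0
    arm_length_frac: float = 0.9  # fraction of the well radius


@dataclass(frozen=True)
class StimulusEpoch:
    kind: StimulusKind
    color: str
    duration_s: float
    params: StimulusParams = field(default_factory=StimulusParams)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be positive")
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.kind in WELL_KINDS and self.params.angular_speed_deg_s <= 0:
            raise ValueError("cross epochs need angular_speed > 0")
        if self.kind is StimulusKind.DOTS_MOVING_UP and self.params.dot_diameter_mm <= 0:
            raise ValueError("dot epochs need dot_diameter > 0")

    @property
    def label(self) -> str:
        if self.kind is StimulusKind.BLANK:
            return "blank"
        return f"{self.kind.value}_{self.color}"


@dataclass(frozen=True)
class AssaySchedule:
    name: str
    epochs: tuple[StimulusEpoch, ...]
    background: str = "white"

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise ValueError(f"unknown background {self.background!r}")
        if not self.epochs:
            raise ValueError("schedule has no epochs")

    @property
    def total_duration_s(self) -> float:
        return sum(e.duration_s for e in self.epochs)

    @property
    def plate_kind(self) -> PlateKind | None:
        """The plate kind this schedule requires, or None if blank-only."""
        kinds = {e.kind for e in self.epochs}
        if kinds & LANE_KINDS:
            return PlateKind.FIVE_LANE
        if kinds & WELL_KINDS:
            return PlateKind.SIX_WELL
        return None

    def locate(self, t_seconds: float) -> tuple[int, StimulusEpoch, float]:
        """(epoch index, epoch, time since epoch start) at time ``t``.

        Epochs occupy half-open intervals [start, end): a boundary instant
        belongs to the next epoch.
        """
        if t_seconds < 0 or t_seconds >= self.total_duration_s:
            raise ValueError(
                f"t={t_seconds} s outside schedule '{self.name}' "
                f"[0, {self.total_duration_s}) s"
            )
        start = 0.0
        for i, ep in enumerate(self.epochs):
            if t_seconds < start + ep.duration_s:
                return i, ep, t_seconds - start
            start += ep.duration_s
        raise AssertionError("unreachable")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "background": self.background,
            "epochs": [
                {
                    "kind": e.kind.value,
                    "color": e.color,
                    "duration_s": e.duration_s,
                    "params": asdict(e.params),
                }
                for e in self.epochs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssaySchedule":
        epochs = tuple(
            StimulusEpoch(
                kind=StimulusKind(e["kind"]),
                color=e["color"],
                duration_s=float(e["duration_s"]),
                params=StimulusParams(**e.get("params", {})),
            )
            for e in d["epochs"]
        )
        return cls(name=d["name"], epochs=epochs, background=d.get("background", "white"))


def epoch_at(schedule: AssaySchedule, t_seconds: float) -> StimulusEpoch:
    """The epoch active at time ``t`` (half-open intervals)."""
    return schedule.locate(t_seconds)[1]


ASSAY_NAMES = (
    "bar_dots",
    "two_bar",
    "two_bar_4x",
    "bar_dots_rgby",
    "cross_rgbyc",
    "red_cross_4x",
)

_MIN = 60.0


def make_schedule(assay_name: str) -> AssaySchedule:
    """Build one of the six named assay schedules."""

    def blank(minutes: float) -> StimulusEpoch:
        return StimulusEpoch(StimulusKind.BLANK, "none", minutes * _MIN)

    def bar(kind: StimulusKind, color: str, minutes: float) -> StimulusEpoch:
        return StimulusEpoch(kind, color, minutes * _MIN)

    def dots(color: str, minutes: float, diameter_mm: float) -> StimulusEpoch:
        return StimulusEpoch(
            StimulusKind.DOTS_MOVING_UP,
            color,
            minutes * _MIN,
            StimulusParams(dot_diameter_mm=diameter_mm),
        )

    def cross(kind: StimulusKind, color: str, minutes: float) -> StimulusEpoch:
        return StimulusEpoch(kind, color, minutes * _MIN)

    if assay_name == "bar_dots":
        epochs = [blank(15), bar(StimulusKind.BAR_UP_HALF, "red", 15), dots("red", 15, 0.5)]
        return AssaySchedule("bar_dots", tuple(epochs), "white")
    if assay_name == "two_bar":
        epochs = [
            blank(15),
            bar(StimulusKind.BAR_UP_HALF, "red", 15),
            bar(StimulusKind.BAR_DOWN_HALF, "red", 15),
        ]
        return AssaySchedule("two_bar", tuple(epochs), "white")
    if assay_name == "two_bar_4x":
        epochs = [blank(20)]
        for _ in range(4):
            epochs += [
                bar(StimulusKind.BAR_UP_HALF, "red", 10),
                bar(StimulusKind.BAR_DOWN_HALF, "red", 10),
            ]
        return AssaySchedule("two_bar_4x", tuple(epochs), "white")
    if assay_name == "bar_dots_rgby":
        epochs = []
        for color in ("red", "green", "blue", "yellow"):
            epochs += [
                blank(10),
                bar(StimulusKind.BAR_UP_HALF, color, 10),
                dots(color, 10, 1.0),
            ]
        return AssaySchedule("bar_dots_rgby", tuple(epochs), "white")
    if assay_name == "cross_rgbyc":
        epochs = [blank(20)]
        for color in ("red", "green", "blue", "yellow", "cyan"):
            epochs += [
                cross(StimulusKind.CROSS_CW, color, 10),
                cross(StimulusKind.CROSS_CCW, color, 10),
            ]
        return AssaySchedule("cross_rgbyc", tuple(epochs), "light_gray")
    if assay_name == "red_cross_4x":
        epochs = [blank(20)]
        for _ in range(4):
            epochs += [
                cross(StimulusKind.CROSS_CW, "red", 10),
                cross(StimulusKind.CROSS_CCW, "red", 10),
            ]
        return AssaySchedule("red_cross_4x", tuple(epochs), "light_gray")
    raise ValueError(f"unknown assay {assay_name!r}; valid names: {', '.join(ASSAY_NAMES)}")


def render_stimulus(
    epoch: StimulusEpoch, t_seconds: float, layout: PlateLayout
) -> np.ndarray:
    """Render the stimulus-only frame (no larvae) at time ``t`` within the epoch.

    Returns an (H, W, 3) uint8 RGB image.  Rendering is deterministic and,
    for crosses, periodic with period 360 / angular_speed seconds.
    """
    # cross epochs imply the light gray assay background; a standalone blank
    # renders white (within a schedule, render_schedule_frame applies the
    # assay's own background instead)
    background = "light_gray" if epoch.kind in WELL_KINDS else "white"
    return render_on_background(epoch, t_seconds, layout, background)


def render_schedule_frame(
    schedule: AssaySchedule, t_seconds: float, layout: PlateLayout
) -> np.ndarray:
    """Render the frame the schedule displays at absolute time ``t``."""
    _, epoch, t_rel = schedule.locate(t_seconds)
    return render_on_background(epoch, t_rel, layout, schedule.background)


def render_on_background(
    epoch: StimulusEpoch, t_seconds: float, layout: PlateLayout, background: str
) -> np.ndarray:
    w, h = layout.image_size
    frame = np.empty((h, w, 3), dtype=np.uint8)
    frame[:] = BACKGROUNDS[background]
    if epoch.kind is StimulusKind.BLANK:
        return frame
    if epoch.kind in LANE_KINDS and layout.plate_kind is not PlateKind.FIVE_LANE:
        raise ValueError(f"{epoch.kind.value} stimulus requires a five_lane layout")
    if epoch.kind in WELL_KINDS and layout.plate_kind is not PlateKind.SIX_WELL:
        raise ValueError(f"{epoch.kind.value} stimulus requires a six_well layout")
    color = np.array(COLORS[epoch.color], dtype=np.uint8)
    for roi in layout.rois:
        if epoch.kind in (StimulusKind.BAR_UP_HALF, StimulusKind.BAR_DOWN_HALF):
            _draw_bar(frame, roi, epoch, t_seconds, layout.px_per_mm, color)
        elif epoch.kind is StimulusKind.DOTS_MOVING_UP:
            _draw_dots(frame, roi, epoch, t_seconds, layout.px_per_mm, color)
        else:
            _draw_cross(frame, roi, epoch, t_seconds, layout.px_per_mm, color)
    return frame


def _draw_bar(
    frame: np.ndarray,
    roi: RoiSpec,
    epoch: StimulusEpoch,
    t: float,
    px_per_mm: float,
    color: np.ndarray,
) -> None:
    # Bar spans the lane width and oscillates (triangle wave) inside the
    # stated half of the lane.  Lanes are vertical with up = low y.
    x0, y0, x1, y1 = roi.bounds
    cy = roi.center[1]
    bar_h = epoch.params.bar_height_mm * px_per_mm
    if epoch.kind is StimulusKind.BAR_UP_HALF:
        lo, hi = y0, cy
    else:
        lo, hi = cy, y1
    travel = max(hi - lo - bar_h, 0.0)
    speed_px = epoch.params.bar_speed_mm_s * px_per_mm
    offset = _triangle(speed_px * t, travel)
    top = lo + offset
    rr0, rr1 = int(round(top)), int(round(min(top + bar_h, hi)))
    cc0, cc1 = int(round(x0)), int(round(x1))
    frame[max(rr0, 0) : rr1, max(cc0, 0) : cc1] = color


def _triangle(s: float, travel: float) -> float:
    """Position of a point bouncing between 0 and ``travel`` after path length s."""
    if travel <= 0:
        return 0.0
    period = 2 * travel
    s = s % period
    return s if s <= travel else period - s


def _draw_dots(
    frame: np.ndarray,
    roi: RoiSpec,
    epoch: StimulusEpoch,
    t: float,
    px_per_mm: float,
    color: np.ndarray,
) -> None:
    x0, y0, x1, y1 = roi.bounds
    pitch = epoch.params.dot_pitch_mm * px_per_mm
    r = epoch.params.dot_diameter_mm * px_per_mm / 2
    # dots drift toward the up end (decreasing y), wrapped on the grid pitch
    phase = (-epoch.params.dot_speed_mm_s * px_per_mm * t) % pitch
    ys = np.arange(y0 + phase, y1, pitch)
    xs = np.arange(x0 + pitch / 2, x1, pitch)
    h, w = frame.shape[:2]
    for yc in ys:
        for xc in xs:
            rr, cc = draw_disk((yc, xc), max(r, 1.0), shape=(h, w))
            # clip to the lane rectangle
            keep = (cc >= x0) & (cc < x1) & (rr >= y0) & (rr < y1)
            frame[rr[keep], cc[keep]] = color


def _draw_cross(
    frame: np.ndarray,
    roi: RoiSpec,
    epoch: StimulusEpoch,
    t: float,
    px_per_mm: float,
    color: np.ndarray,
) -> None:
    # Four arms rotating about the well center.  In screen coordinates
    # (y down) a visually clockwise rotation advances the screen-frame
    # angle; the angle is reduced mod 360 before the trig so frames one
    # full period apart are bit-identical.
    cx, cy = roi.center
    radius = float(roi.extent)  # type: ignore[arg-type]
    length = epoch.params.arm_length_frac * radius
    half_w = epoch.params.arm_width_mm * px_per_mm / 2
    omega = epoch.params.angular_speed_deg_s
    sign = 1.0 if epoch.kind is StimulusKind.CROSS_CW else -1.0
    theta0 = (epoch.params.initial_angle_deg + sign * omega * t) % 360.0
    h, w = frame.shape[:2]
    for k in range(4):
        a = np.deg2rad((theta0 + 90.0 * k) % 360.0)
        ux, uy = np.cos(a), np.sin(a)  # arm direction (screen frame)
        nx, ny = -uy, ux  # normal
        corners_x = [cx + half_w * nx, cx + length * ux + half_w * nx,
                     cx + length * ux - half_w * nx, cx - half_w * nx]
        corners_y = [cy + half_w * ny, cy + length * uy + half_w * ny,
                     cy + length * uy - half_w * ny, cy - half_w * ny]
        rr, cc = draw_polygon(corners_y, corners_x, shape=(h, w))
        # keep the arm inside the well disc
        keep = (cc - cx) ** 2 + (rr - cy) ** 2 <= radius**2
        frame[rr[keep], cc[keep]] = color
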