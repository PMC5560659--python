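"""Behavioral measures: lane halves, heading, clockwise/counter-clockwise
orientation, per-well per-epoch summaries, and swim speed.

A "larval measurement" is one detection of one larva in one frame; all
measurements within a well are pooled equally.  In lanes the measure is
%up — the fraction of measurements whose centroid lies in the upper half
of the lane.  In wells the measure is %CW — the fraction of measurements
whose heading is classified clockwise relative to the well center.

Orientation comes from the offset between the intensity-weighted centroid
and the bounding-box center: the head end of a larva is darker and wider,
so the centroid is displaced toward the head.  The offset is quantized to
four 90-degree sectors (up/down/left/right on screen), and a heading is
clockwise in a given quadrant of the well when it points along the local
tangential direction of clockwise rotation — e.g. a larva facing up
(+/-45 deg) or right (+/-45 deg) in the top-left quarter is clockwise.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Detection
from .geometry import (
    Half,
    PlateLayout,
    Quadrant,
    RoiShape,
    classify_half,
    classify_quadrant,
)
from .stimuli import StimulusEpoch

logger = logging.getLogger(__name__)


class HeadingClass(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


class Rotational(str, enum.Enum):
    CW = "cw"
    CCW = "ccw"
    UNCLASSIFIED = "unclassified"


HEADING_VECTORS = {
    HeadingClass.UP: (0.0, -1.0),  # screen frame: up = decreasing y
    HeadingClass.RIGHT: (1.0, 0.0),
    HeadingClass.DOWN: (0.0, 1.0),
    HeadingClass.LEFT: (-1.0, 0.0),
}

# Clockwise headings per quadrant.  In each quadrant exactly two of the
# four quantized headings point along the on-screen clockwise tangent
# (positive h . (-d_y, d_x) at the quadrant's offset d from the center).
CW_TABLE: dict[Quadrant, frozenset[HeadingClass]] = {
    Quadrant.TL: frozenset({HeadingClass.UP, HeadingClass.RIGHT}),
    Quadrant.TR: frozenset({HeadingClass.RIGHT, HeadingClass.DOWN}),
    Quadrant.BR: frozenset({HeadingClass.DOWN, HeadingClass.LEFT}),
    Quadrant.BL: frozenset({HeadingClass.LEFT, HeadingClass.UP}),
}


@dataclass(frozen=True)
class LarvaMeasurement:
    frame_index: int
    roi_id: int
    epoch_label: str
    half: Half | None = None  # lanes only
    heading: HeadingClass = HeadingClass.NONE
    quadrant: Quadrant | None = None  # wells only
    rotational: Rotational | None = None  # wells only


@dataclass(frozen=True)
class WellPeriodSummary:
    """Per-well, per-epoch aggregate.  Percentages are fractions in [0, 1];
    None marks an undefined value (no classifiable measurements)."""

    roi_id: int
    epoch_label: str
    n_measurements: int
    pct_up: float | None = None
    pct_cw: float | None = None
    swim_speed_mm_min: float | None = None


def heading_from_offset(
    centroid: tuple[float, float],
    bbox_center: tuple[float, float],
    min_offset_px: float = 1.0,
) -> HeadingClass:
    """Quantize the centroid - bbox-center offset into up/down/left/right.

    Offsets shorter than ``min_offset_px`` are below measurement noise and
    return ``none``.  Sector boundaries (exact 45-degree diagonals) break
    toward the horizontal direction.
    """
    dx = centroid[0] - bbox_center[0]
    dy = centroid[1] - bbox_center[1]
    if math.hypot(dx, dy) < min_offset_px:
        return HeadingClass.NONE
    if abs(dx) >= abs(dy):  # ties toward horizontal
        return HeadingClass.RIGHT if dx > 0 else HeadingClass.LEFT
    return HeadingClass.DOWN if dy > 0 else HeadingClass.UP


def rotational_class(heading: HeadingClass, quadrant: Quadrant) -> Rotational:
    """Clockwise/counter-clockwise orientation of a quantized heading in a quadrant."""
    if heading is HeadingClass.NONE:
        raise ValueError("heading 'none' cannot be classified; filter it first")
    return Rotational.CW if heading in CW_TABLE[quadrant] else Rotational.CCW


def score_frame(
    detections: list[Detection],
    layout: PlateLayout,
    epoch: StimulusEpoch | str,
    min_offset_px: float = 1.0,
) -> list[LarvaMeasurement]:
    """One LarvaMeasurement per detection: halves for lanes, quadrant and
    rotational class for wells."""
    label = epoch if isinstance(epoch, str) else epoch.label
    out: list[LarvaMeasurement] = []
    for det in detections:
        roi = layout.roi(det.roi_id)
        heading = heading_from_offset(det.centroid, det.bbox_center, min_offset_px)
        if roi.shape is RoiShape.RECTANGLE:
            out.append(
                LarvaMeasurement(
                    frame_index=det.frame_index,
                    roi_id=det.roi_id,
                    epoch_label=label,
                    half=classify_half(det.centroid, roi),
                    heading=heading,
                )
            )
        else:
            quadrant = classify_quadrant(det.centroid, roi)
            rot = (
                Rotational.UNCLASSIFIED
                if heading is HeadingClass.NONE
                else rotational_class(heading, quadrant)
            )
            out.append(
                LarvaMeasurement(
                    frame_index=det.frame_index,
                    roi_id=det.roi_id,
                    epoch_label=label,
                    heading=heading,
                    quadrant=quadrant,
                    rotational=rot,
                )
            )
    return out


def summarize_period(
    measurements: list[LarvaMeasurement],
    epoch_label: str,
    roi_id: int,
    swim_speed_mm_min: float | None = None,
) -> WellPeriodSummary:
    """Pool all measurements of one ROI within one epoch.

    All larvae in the well count equally: a well with 5 larvae imaged for
    10 minutes at 10 frames per minute provides 500 larval measurements,
    averaged as a whole.  %up uses up/(up+down); %CW uses cw/(cw+ccw),
    excluding unclassified measurements from the denominator.
    """
    ms = [m for m in measurements if m.roi_id == roi_id and m.epoch_label == epoch_label]
    n = len(ms)
    n_up = sum(1 for m in ms if m.half is Half.UP)
    n_down = sum(1 for m in ms if m.half is Half.DOWN)
    n_cw = sum(1 for m in ms if m.rotational is Rotational.CW)
    n_ccw = sum(1 for m in ms if m.rotational is Rotational.CCW)
    pct_up = n_up / (n_up + n_down) if (n_up + n_down) > 0 else None
    pct_cw = n_cw / (n_cw + n_ccw) if (n_cw + n_ccw) > 0 else None
    if n > 0 and pct_up is None and pct_cw is None:
        logger.info("ROI %d epoch %s: no classifiable measurements", roi_id, epoch_label)
    return WellPeriodSummary(
        roi_id=roi_id,
        epoch_label=epoch_label,
        n_measurements=n,
        pct_up=pct_up,
        pct_cw=pct_cw,
        swim_speed_mm_min=swim_speed_mm_min,
    )


def swim_speed(
    detections: list[Detection],
    roi_id: int,
    frame_interval_s: float,
    px_per_mm: float,
    max_step_mm: float = 5.0,
) -> float:
    """Mean swim speed (mm/min) in one ROI from frame-to-frame displacements.

    Detections in consecutive frames are linked by greedy nearest-neighbor
    assignment with a maximum step gate; unmatched detections start or end
    tracks.  The speed is the mean over all linked steps, matching the
    per-well pooling of the other measures.  Returns NaN when no step
    could be linked.
    """
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        if det.roi_id == roi_id:
            by_frame.setdefault(det.frame_index, []).append(det)
    frames = sorted(by_frame)
    if len(frames) < 2:
        raise ValueError(f"ROI {roi_id}: need detections in >= 2 frames for swim speed")
    gate_px = max_step_mm * px_per_mm
    steps_px: list[float] = []
    for fa, fb in zip(frames[:-1], frames[1:]):
        if fb != fa + 1:
            continue  # only consecutive frames form a step
        steps_px.extend(_greedy_link(by_frame[fa], by_frame[fb], gate_px))
    if not steps_px:
        return float("nan")
    mean_px = float(np.mean(steps_px))
    return (mean_px / px_per_mm) / (frame_interval_s / 60.0)


def _greedy_link(
    prev: list[Detection], curr: list[Detection], gate_px: float
) -> list[float]:
    """Distances of greedily matched nearest-neighbor pairs within the gate."""
    pairs = []
    for i, a in enumerate(prev):
        for j, b in enumerate(curr):
            d = math.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
            if d <= gate_px:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append(d)
    return out


def measurements_to_frame(measurements: list[LarvaMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": m.frame_index,
                "roi": m.roi_id,
                "epoch": m.epoch_label,
                "half": m.half.value if m.half else "n/a",
                "heading": m.heading.value,
                "quadrant": m.quadrant.value if m.quadrant else "n/a",
                "rotational": m.rotational.value if m.rotational else "n/a",
            }
            for m in measurements
        ],
        columns=["frame", "roi", "epoch", "half", "heading", "quadrant", "rotational"],
    )


def summaries_to_frame(summaries: list[WellPeriodSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi": s.roi_id,
                "epoch": s.epoch_label,
                "n": s.n_measurements,
                "pct_up": np.nan if s.pct_up is None else s.pct_up,
                "pct_cw": np.nan if s.pct_cw is None else s.pct_cw,
                "speed": np.nan if s.swim_speed_mm_min is None else s.swim_speed_mm_min,
            }
            for s in summaries
        ],
        columns=["roi", "epoch", "n", "pct_up", "pct_cw", "speed"],
    )


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": d.frame_index,
                "roi": d.roi_id,
                "cx": d.centroid[0],
                "cy": d.centroid[1],
                "bbx0": d.bbox[0],
                "bby0": d.bbox[1],
                "bbx1": d.bbox[2],
                "bby1": d.bbox[3],
                "area": d.area,
            }
            for d in detections
        ],
        columns=["frame", "roi", "cx", "cy", "bbx0", "bby0", "bbx1", "bby1", "area"],
    )
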