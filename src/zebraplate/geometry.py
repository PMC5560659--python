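"""Plate layouts, ROIs and the half/quadrant partitions used for scoring.

Coordinate convention: image coordinates, origin at the top-left corner,
x to the right, y downward.  "Up" on screen therefore means decreasing y.
All headings and tangents elsewhere in the package use this frame.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence


class PlateKind(str, enum.Enum):
    FIVE_LANE = "five_lane"
    SIX_WELL = "six_well"


class RoiShape(str, enum.Enum):
    RECTANGLE = "rectangle"
    DISC = "disc"


class Half(str, enum.Enum):
    UP = "up"
    DOWN = "down"


class Quadrant(str, enum.Enum):
    TL = "TL"
    TR = "TR"
    BL = "BL"
    BR = "BR"


@dataclass(frozen=True)
class RoiSpec:
    """One region of interest: a rectangular lane or a circular well.

    ``center`` is in pixels. For rectangles ``extent`` is (width, height)
    in pixels; for discs it is the radius in pixels. Lanes additionally
    declare which end of the long axis counts as "up" (``up_end``):
    ``low_y`` means the up end is toward the top of the image.
    """

    roi_id: int
    shape: RoiShape
    center: tuple[float, float]
    extent: tuple[float, float] | float
    long_axis: str | None = None  # "vertical" | "horizontal", lanes only
    up_end: str | None = None  # "low_y" | "high_y" (vert) | "low_x" | "high_x"

    def __post_init__(self) -> None:
        if self.shape is RoiShape.RECTANGLE:
            w, h = self.extent  # type: ignore[misc]
            if w <= 0 or h <= 0:
                raise ValueError(f"ROI {self.roi_id}: non-positive extent {self.extent}")
            if self.long_axis is not None and self.up_end is None:
                raise ValueError(f"lane ROI {self.roi_id} must declare up_end")
        else:
            if float(self.extent) <= 0:  # type: ignore[arg-type]
                raise ValueError(f"ROI {self.roi_id}: non-positive radius {self.extent}")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the ROI in pixels."""
        cx, cy = self.center
        if self.shape is RoiShape.RECTANGLE:
            w, h = self.extent  # type: ignore[misc]
            return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        r = float(self.extent)  # type: ignore[arg-type]
        return (cx - r, cy - r, cx + r, cy + r)

    def contains(self, point: tuple[float, float]) -> bool:
        x, y = point
        if self.shape is RoiShape.RECTANGLE:
            x0, y0, x1, y1 = self.bounds
            return x0 <= x <= x1 and y0 <= y <= y1
        cx, cy = self.center
        r = float(self.extent)  # type: ignore[arg-type]
        return (x - cx) ** 2 + (y - cy) ** 2 <= r**2


@dataclass(frozen=True)
class PlateLayout:
    plate_kind: PlateKind
    rois: tuple[RoiSpec, ...]
    px_per_mm: float
    image_size: tuple[int, int]  # (width, height) px

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        w, h = self.image_size
        for roi in self.rois:
            x0, y0, x1, y1 = roi.bounds
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                raise ValueError(
                    f"ROI {roi.roi_id} with bounds {roi.bounds} exceeds "
                    f"image size {self.image_size}"
                )
        for i, a in enumerate(self.rois):
            for b in self.rois[i + 1 :]:
                if _bounds_overlap(a.bounds, b.bounds):
                    raise ValueError(f"ROIs {a.roi_id} and {b.roi_id} overlap")

    def roi(self, roi_id: int) -> RoiSpec:
        for r in self.rois:
            if r.roi_id == roi_id:
                return r
        raise KeyError(f"no ROI with id {roi_id}")

    def mm(self, px: float) -> float:
        return px / self.px_per_mm

    def px(self, mm: float) -> float:
        return mm * self.px_per_mm


def _bounds_overlap(a: Sequence[float], b: Sequence[float]) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


# Physical plate dimensions (mm).  The 5-lane plate is moulded in agarose:
# each lane is 70 x 18 mm at the rim sloping to a 66 x 14 mm bottom; larvae
# swim over the 66 x 14 mm inner bottom, which is the analysis ROI.  The
# 6-well plate has a 27 mm diameter hole stamped in the agarose of each well.
LANE_INNER_LENGTH_MM = 66.0
LANE_INNER_WIDTH_MM = 14.0
LANE_PITCH_MM = 18.0
N_LANES = 5
WELL_DIAMETER_MM = 27.0
WELL_GRID = (3, 2)  # columns x rows
WELL_PITCH_MM = 39.0


def build_layout(
    plate_kind: PlateKind | str,
    image_size: tuple[int, int],
    px_per_mm: float,
    margins: tuple[float, float] | None = None,
) -> PlateLayout:
    """Construct a regular-grid layout for one plate.

    Five-lane plates get 5 vertical rectangular lane ROIs (66 x 14 mm
    inner bottom, "up" = top of the image); six-well plates get a 3 x 2
    grid of 27 mm diameter disc ROIs.  ``margins`` (x, y, px) positions
    the grid; by default the grid is centered in the image.

    Raises ``ValueError`` naming the first ROI that would exceed the
    image bounds.
    """
    plate_kind = PlateKind(plate_kind)
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    w, h = image_size
    rois: list[RoiSpec] = []
    if plate_kind is PlateKind.FIVE_LANE:
        lane_w = LANE_INNER_WIDTH_MM * px_per_mm
        lane_h = LANE_INNER_LENGTH_MM * px_per_mm
        pitch = LANE_PITCH_MM * px_per_mm
        grid_w = pitch * (N_LANES - 1) + lane_w
        x0, y0 = _grid_origin(margins, (w, h), (grid_w, lane_h))
        for i in range(N_LANES):
            rois.append(
                RoiSpec(
                    roi_id=i,
                    shape=RoiShape.RECTANGLE,
                    center=(x0 + lane_w / 2 + i * pitch, y0 + lane_h / 2),
                    extent=(lane_w, lane_h),
                    long_axis="vertical",
                    up_end="low_y",
                )
            )
    else:
        r = WELL_DIAMETER_MM / 2 * px_per_mm
        pitch = WELL_PITCH_MM * px_per_mm
        ncol, nrow = WELL_GRID
        grid_w = pitch * (ncol - 1) + 2 * r
        grid_h = pitch * (nrow - 1) + 2 * r
        x0, y0 = _grid_origin(margins, (w, h), (grid_w, grid_h))
        k = 0
        for row in range(nrow):
            for col in range(ncol):
                rois.append(
                    RoiSpec(
                        roi_id=k,
                        shape=RoiShape.DISC,
                        center=(x0 + r + col * pitch, y0 + r + row * pitch),
                        extent=r,
                    )
                )
                k += 1
    return PlateLayout(plate_kind, tuple(rois), px_per_mm, image_size)


def _grid_origin(
    margins: tuple[float, float] | None,
    image_size: tuple[float, float],
    grid_size: tuple[float, float],
) -> tuple[float, float]:
    if margins is not None:
        return margins
    return ((image_size[0] - grid_size[0]) / 2, (image_size[1] - grid_size[1]) / 2)


def classify_half(point: tuple[float, float], lane_roi: RoiSpec) -> Half:
    """Classify a lane point as "up" or "down" relative to the lane midline.

    A point is "up" iff it lies strictly on the ``up_end`` side of the
    transverse midline through the lane center; a point exactly on the
    midline counts as "down" (fixed tie-break).
    """
    if lane_roi.shape is not RoiShape.RECTANGLE or lane_roi.up_end is None:
        raise ValueError(f"ROI {lane_roi.roi_id} is not a lane")
    if not lane_roi.contains(point):
        raise ValueError(f"point {point} outside lane ROI {lane_roi.roi_id}")
    x, y = point
    cx, cy = lane_roi.center
    if lane_roi.long_axis == "vertical":
        coord, c = y, cy
        up_is_low = lane_roi.up_end == "low_y"
    else:
        coord, c = x, cx
        up_is_low = lane_roi.up_end == "low_x"
    if up_is_low:
        return Half.UP if coord < c else Half.DOWN
    return Half.UP if coord > c else Half.DOWN


def classify_quadrant(point: tuple[float, float], well_roi: RoiSpec) -> Quadrant:
    """Quadrant of a well point relative to the well center (screen frame).

    TL means x < cx and y < cy.  Points exactly on an axis go to the
    right column / bottom row (fixed tie-break).
    """
    if not well_roi.contains(point):
        raise ValueError(f"point {point} outside well ROI {well_roi.roi_id}")
    x, y = point
    cx, cy = well_roi.center
    left = x < cx
    top = y < cy
    if top:
        return Quadrant.TL if left else Quadrant.TR
    return Quadrant.BL if left else Quadrant.BR
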