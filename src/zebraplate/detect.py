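"""Detection pipeline: channel selection, background subtraction,
per-ROI auto-thresholding, and particle analysis.

The stages mirror the classic plate-imaging macro: split the RGB frame,
pick the channel in which the stimulus and the background have the most
similar intensity (so the colored pattern vanishes and only the dark
larvae remain), remove the smoothly varying background, auto-threshold
each well/lane separately, and reduce connected components to per-larva
detections with an intensity-weighted centroid and a tight bounding box.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .geometry import PlateLayout, RoiShape, RoiSpec
from .stimuli import BACKGROUNDS, COLORS

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("R", "G", "B")


@dataclass(frozen=True)
class Detection:
    """One candidate larva in one frame and ROI.

    ``centroid`` is the intensity-weighted centroid (x, y, px; weights =
    darkness in the background-corrected image).  ``bbox`` is the tight
    inclusive bounding box (x_min, y_min, x_max, y_max, px).  ``area`` is
    the component's pixel count.
    """

    frame_index: int
    roi_id: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    area: int

    @property
    def bbox_center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the detection stage.

    Physical units scale with the layout's px_per_mm: the background
    radius must be much larger than a larva's width but smaller than the
    stimulus feature scale, and the area window brackets one larva
    (about 4 x 0.8 mm) while rejecting specks and clumps of more than
    two larvae.
    """

    threshold_method: str = "isodata"  # or "otsu"
    background_radius_mm: float = 5.0
    area_range_mm2: tuple[float, float] = (0.5, 8.0)
    min_contrast: int = 25  # below this intensity range an ROI counts as empty

    def background_radius_px(self, px_per_mm: float) -> int:
        return max(int(round(self.background_radius_mm * px_per_mm)), 1)

    def area_range_px(self, px_per_mm: float) -> tuple[float, float]:
        lo, hi = self.area_range_mm2
        return lo * px_per_mm**2, hi * px_per_mm**2


def select_channel(
    frame: np.ndarray | None,
    stimulus_color: str,
    background: str,
) -> int:
    """Index (0=R, 1=G, 2=B) of the channel where stimulus and background match best.

    Returns the argmin over channels of |stimulus value - background value|
    for the configured RGB palette; ties prefer R, then G, then B.  A blank
    epoch ("none" color) matches the background in every channel and falls
    through to R.  The frame itself is not inspected: the schedule always
    knows the active color.
    """
    if stimulus_color == "none":
        return 0
    stim = COLORS[stimulus_color]
    bg = BACKGROUNDS[background]
    diffs = [abs(stim[c] - bg[c]) for c in range(3)]
    return int(np.argmin(diffs))  # argmin takes the first minimum: R, then G, then B


def subtract_background(
    channel_image: np.ndarray,
    radius_px: int,
    larva_width_px: float | None = None,
) -> np.ndarray:
    """Remove the smooth background, leaving dark larvae on a flat bright field.

    The background is estimated by grayscale morphological closing with a
    (2*radius+1) square window, which fills dark features smaller than the
    window; the darkness signal (background - image) is then mapped back
    onto a flat 255 field.  ``radius_px`` must exceed the larva width or
    the larvae themselves are absorbed into the background estimate (a
    warning is emitted when ``larva_width_px`` says so).
    """
    if larva_width_px is not None and radius_px <= larva_width_px:
        warnings.warn(
            f"background radius {radius_px} px <= larva width {larva_width_px} px; "
            "larvae may be erased",
            stacklevel=2,
        )
    img = np.asarray(channel_image)
    size = 2 * int(radius_px) + 1
    background = ndi.grey_closing(img, size=(size, size), mode="nearest")
    darkness = background.astype(np.int16) - img.astype(np.int16)
    corrected = 255 - np.clip(darkness, 0, 255)
    return corrected.astype(np.uint8)


def roi_pixel_mask(roi: RoiSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the ROI's pixels on an (H, W) grid."""
    h, w = shape
    x0, y0, x1, y1 = roi.bounds
    mask = np.zeros((h, w), dtype=bool)
    if roi.shape is RoiShape.RECTANGLE:
        mask[
            max(int(np.ceil(y0)), 0) : min(int(np.floor(y1)) + 1, h),
            max(int(np.ceil(x0)), 0) : min(int(np.floor(x1)) + 1, w),
        ] = True
        return mask
    cx, cy = roi.center
    r = float(roi.extent)  # type: ignore[arg-type]
    yy, xx = np.ogrid[:h, :w]
    mask[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = True
    return mask


def threshold_well(
    corrected: np.ndarray,
    roi: RoiSpec,
    method: str = "isodata",
    min_contrast: int = 25,
) -> np.ndarray:
    """Binary mask of dark objects within one ROI (full-frame shape).

    The threshold is recomputed per ROI from the ROI's own histogram
    (IsoData by default, Otsu selectable).  ROIs whose intensity range is
    below ``min_contrast`` are considered empty (degenerate histogram)
    and yield an empty mask.
    """
    if method not in ("isodata", "otsu"):
        raise ValueError(f"unknown threshold method {method!r}")
    roi_mask = roi_pixel_mask(roi, corrected.shape[:2])
    values = corrected[roi_mask]
    out = np.zeros(corrected.shape[:2], dtype=bool)
    if values.size == 0:
        logger.info("ROI %d: no pixels inside image; empty mask", roi.roi_id)
        return out
    if int(values.max()) - int(values.min()) < min_contrast:
        logger.debug("ROI %d: contrast below %d; empty mask", roi.roi_id, min_contrast)
        return out
    thr = threshold_isodata(values) if method == "isodata" else threshold_otsu(values)
    out[roi_mask] = corrected[roi_mask] <= thr
    return out


def particle_analysis(
    mask: np.ndarray,
    corrected: np.ndarray,
    roi: RoiSpec,
    area_range: tuple[float, float],
    frame_index: int = 0,
) -> list[Detection]:
    """Connected components of the mask, filtered by area, as Detections.

    Centroids are intensity-weighted with darkness (255 - corrected) as
    the weight, so the heavier head pulls the centroid forward of the
    bounding-box center.  Components are clipped to the ROI (the mask is
    already ROI-restricted).  Zero detections is a valid result.
    """
    lo, hi = area_range
    labels = cc_label(mask, connectivity=2)
    weights = (255 - corrected.astype(np.int16)).astype(np.float64)
    detections: list[Detection] = []
    for prop in regionprops(labels, intensity_image=weights):
        if not (lo <= prop.area <= hi):
            continue
        cyx = prop.centroid_weighted
        y0, x0, y1, x1 = prop.bbox  # skimage: half-open rows/cols
        detections.append(
            Detection(
                frame_index=frame_index,
                roi_id=roi.roi_id,
                centroid=(float(cyx[1]), float(cyx[0])),
                bbox=(int(x0), int(y0), int(x1) - 1, int(y1) - 1),
                area=int(prop.area),
            )
        )
    if not detections:
        logger.debug("ROI %d frame %d: zero detections", roi.roi_id, frame_index)
    return detections


def detect_frame(
    frame: np.ndarray,
    layout: PlateLayout,
    stimulus_color: str,
    background: str,
    params: DetectionParams = DetectionParams(),
    frame_index: int = 0,
) -> list[Detection]:
    """Full per-frame pipeline over all ROIs of the layout.

    Background subtraction and thresholding run on a padded crop of each
    ROI, which matches the macro's per-well processing and keeps the cost
    proportional to the ROI area.
    """
    channel = select_channel(frame, stimulus_color, background)
    ch_img = frame[:, :, channel]
    radius = params.background_radius_px(layout.px_per_mm)
    area_range = params.area_range_px(layout.px_per_mm)
    larva_w = 0.8 * layout.px_per_mm
    h, w = ch_img.shape
    detections: list[Detection] = []
    for roi in layout.rois:
        x0, y0, x1, y1 = roi.bounds
        pad = radius
        cx0, cy0 = max(int(x0) - pad, 0), max(int(y0) - pad, 0)
        cx1, cy1 = min(int(np.ceil(x1)) + pad, w), min(int(np.ceil(y1)) + pad, h)
        crop = ch_img[cy0:cy1, cx0:cx1]
        corrected = subtract_background(crop, radius, larva_width_px=larva_w)
        local_roi = RoiSpec(
            roi_id=roi.roi_id,
            shape=roi.shape,
            center=(roi.center[0] - cx0, roi.center[1] - cy0),
            extent=roi.extent,
            long_axis=roi.long_axis,
            up_end=roi.up_end,
        )
        mask = threshold_well(corrected, local_roi, params.threshold_method, params.min_contrast)
        for det in particle_analysis(mask, corrected, local_roi, area_range, frame_index):
            detections.append(
                Detection(
                    frame_index=det.frame_index,
                    roi_id=det.roi_id,
                    centroid=(det.centroid[0] + cx0, det.centroid[1] + cy0),
                    bbox=(
                        det.bbox[0] + cx0,
                        det.bbox[1] + cy0,
                        det.bbox[2] + cx0,
                        det.bbox[3] + cy0,
                    ),
                    area=det.area,
                )
            )
    logger.info(
        "frame %d: %d detections across %d ROIs", frame_index, len(detections), len(layout.rois)
    )
    return detections
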