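"""Validation of detection and scoring against simulator ground truth.

The simulator logs every larva's true position and heading; this module
matches detections to those records to measure per-frame recall and
precision, heading agreement, and swim-speed recovery.  Recall and heading
agreement are evaluated on well-separated larvae only (touching larvae
legitimately merge into one particle); precision counts any detection near
a true larva as correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Detection
from .geometry import PlateLayout
from .score import HeadingClass, heading_from_offset
from .simulate import LarvaMorphology


@dataclass(frozen=True)
class DetectionFidelity:
    recall: float
    precision: float
    heading_accuracy: float
    n_truth_separated: int
    n_truth_total: int
    n_detections: int
    n_recalled: int = 0
    n_det_matched: int = 0
    n_heading_classified: int = 0
    n_heading_correct: int = 0

    @classmethod
    def combine(cls, parts: list["DetectionFidelity"]) -> "DetectionFidelity":
        """Pool the raw counts of several evaluations into one summary."""
        n_sep = sum(p.n_truth_separated for p in parts)
        n_rec = sum(p.n_recalled for p in parts)
        n_det = sum(p.n_detections for p in parts)
        n_match = sum(p.n_det_matched for p in parts)
        n_h = sum(p.n_heading_classified for p in parts)
        n_h_ok = sum(p.n_heading_correct for p in parts)
        return cls(
            recall=n_rec / n_sep if n_sep else float("nan"),
            precision=n_match / n_det if n_det else float("nan"),
            heading_accuracy=n_h_ok / n_h if n_h else float("nan"),
            n_truth_separated=n_sep,
            n_truth_total=sum(p.n_truth_total for p in parts),
            n_detections=n_det,
            n_recalled=n_rec,
            n_det_matched=n_match,
            n_heading_classified=n_h,
            n_heading_correct=n_h_ok,
        )


def quantize_heading(heading_deg: float) -> HeadingClass:
    """True heading quantized into the same four sectors the scorer uses."""
    a = math.radians(heading_deg)
    return heading_from_offset((math.cos(a), math.sin(a)), (0.0, 0.0), 0.0)


def evaluate_detections(
    truth: pd.DataFrame,
    detections: list[Detection],
    layout: PlateLayout,
    match_tol_mm: float = 2.0,
    min_sep_mm: float = 6.0,
    min_offset_px: float = 1.0,
) -> DetectionFidelity:
    """Match detections to ground truth frame by frame and ROI by ROI.

    A truth larva is "separated" when its nearest same-ROI neighbor in the
    same frame is farther than ``min_sep_mm``.  Matching is greedy nearest-
    neighbor within ``match_tol_mm``.
    """
    tol_px = match_tol_mm * layout.px_per_mm
    sep_px = min_sep_mm * layout.px_per_mm
    det_by_key: dict[tuple[int, int], list[Detection]] = {}
    for d in detections:
        det_by_key.setdefault((d.frame_index, d.roi_id), []).append(d)

    n_sep = 0
    n_sep_recalled = 0
    n_det_true = 0
    n_det = len(detections)
    n_heading = 0
    n_heading_ok = 0

    for (frame, roi_id), group in truth.groupby(["frame", "roi_id"], sort=True):
        pts = group[["x_px", "y_px"]].to_numpy(dtype=float)
        headings = group["heading_deg"].to_numpy(dtype=float)
        k = len(pts)
        if k > 1:
            d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            separated = np.sqrt(d2.min(axis=1)) > sep_px
        else:
            separated = np.ones(k, dtype=bool)
        dets = det_by_key.get((int(frame), int(roi_id)), [])
        # greedy nearest-neighbor matching truth <-> detections
        pairs = []
        for ti in range(k):
            for dj, det in enumerate(dets):
                dist = math.hypot(det.centroid[0] - pts[ti, 0], det.centroid[1] - pts[ti, 1])
                if dist <= tol_px:
                    pairs.append((dist, ti, dj))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        matches: dict[int, int] = {}
        for _, ti, dj in pairs:
            if ti in used_t or dj in used_d:
                continue
            used_t.add(ti)
            used_d.add(dj)
            matches[ti] = dj
        # a detection is a true positive if it lies within tol of ANY truth
        for dj, det in enumerate(dets):
            if any(
                math.hypot(det.centroid[0] - pts[ti, 0], det.centroid[1] - pts[ti, 1]) <= tol_px
                for ti in range(k)
            ):
                n_det_true += 1
        for ti in range(k):
            if not separated[ti]:
                continue
            n_sep += 1
            if ti in matches:
                n_sep_recalled += 1
                det = dets[matches[ti]]
                pred = heading_from_offset(det.centroid, det.bbox_center, min_offset_px)
                if pred is not HeadingClass.NONE:
                    n_heading += 1
                    if pred is quantize_heading(headings[ti]):
                        n_heading_ok += 1

    return DetectionFidelity(
        recall=n_sep_recalled / n_sep if n_sep else float("nan"),
        precision=n_det_true / n_det if n_det else float("nan"),
        heading_accuracy=n_heading_ok / n_heading if n_heading else float("nan"),
        n_truth_separated=n_sep,
        n_truth_total=len(truth),
        n_detections=n_det,
        n_recalled=n_sep_recalled,
        n_det_matched=n_det_true,
        n_heading_classified=n_heading,
        n_heading_correct=n_heading_ok,
    )


def truth_as_detections(
    truth: pd.DataFrame,
    layout: PlateLayout,
    morphology: LarvaMorphology = LarvaMorphology(),
    centroid_offset_px: float = 2.0,
) -> list[Detection]:
    """Idealized Detections straight from ground truth (perfect detection).

    Each record becomes a detection whose bounding box is centered on the
    true position and whose centroid is displaced ``centroid_offset_px``
    toward the true heading — the geometry the renderer guarantees.
    Useful for exercising the scoring and statistics stages without the
    image pipeline.
    """
    half = morphology.length_mm / 2 * layout.px_per_mm
    area = int(morphology.length_mm * morphology.width_mm * layout.px_per_mm**2)
    out = []
    for row in truth.itertuples(index=False):
        a = math.radians(row.heading_deg)
        cx = row.x_px + centroid_offset_px * math.cos(a)
        cy = row.y_px + centroid_offset_px * math.sin(a)
        x0, y0 = int(round(row.x_px - half)), int(round(row.y_px - half))
        x1, y1 = x0 + int(2 * half), y0 + int(2 * half)
        out.append(
            Detection(
                frame_index=int(row.frame),
                roi_id=int(row.roi_id),
                centroid=(cx, cy),
                bbox=(x0, y0, x1, y1),
                area=area,
            )
        )
    return out


def true_mean_speed_mm_min(
    truth: pd.DataFrame, roi_id: int, frame_interval_s: float, px_per_mm: float
) -> float:
    """Ground-truth mean step speed (mm/min) of all larvae in one ROI."""
    sub = truth[truth["roi_id"] == roi_id].sort_values(["larva_id", "frame"])
    steps = []
    for _, g in sub.groupby("larva_id"):
        dx = np.diff(g["x_px"].to_numpy())
        dy = np.diff(g["y_px"].to_numpy())
        steps.extend(np.hypot(dx, dy))
    if not steps:
        return float("nan")
    return (float(np.mean(steps)) / px_per_mm) / (frame_interval_s / 60.0)
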