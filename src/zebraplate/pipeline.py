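"""End-to-end frame analysis: detection -> scoring -> per-well summaries.

Ties the detection and scoring stages together for an ordered series of
frames under one experiment configuration.  Each epoch occurrence gets a
unique label ``"<index>:<kind>_<color>"`` so repeated presentations of the
same stimulus (the 4x assays) stay distinct in the summary table and can
feed the repeated-measures ANOVA.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .detect import Detection, detect_frame
from .score import (
    LarvaMeasurement,
    detections_to_frame,
    measurements_to_frame,
    score_frame,
    summaries_to_frame,
    summarize_period,
    swim_speed,
)
from .stimuli import StimulusEpoch

logger = logging.getLogger(__name__)


def epoch_occurrence_label(index: int, epoch: StimulusEpoch) -> str:
    return f"{index:02d}:{epoch.label}"


def analyze_frames(
    frames: Iterable[np.ndarray],
    cfg: ExperimentConfig,
) -> tuple[list[Detection], list[LarvaMeasurement], pd.DataFrame]:
    """Run detection and scoring over an ordered frame series.

    Frame ``i`` is taken at ``t_start + i * frame_interval``.  Frames past
    the end of the schedule raise a warning and are dropped (truncated
    analysis).  Returns the detections, the measurements, and the per-well
    per-epoch summary table (with swim speed where computable).
    """
    schedule = cfg.schedule
    layout = cfg.layout
    detections: list[Detection] = []
    measurements: list[LarvaMeasurement] = []
    frame_epochs: dict[int, str] = {}
    n_processed = 0
    for i, frame in enumerate(frames):
        t = cfg.t_start_s + i * cfg.frame_interval_s
        if t >= schedule.total_duration_s:
            warnings.warn(
                f"frame {i} at t={t:.0f}s is beyond the schedule "
                f"({schedule.total_duration_s:.0f}s); truncating analysis",
                stacklevel=2,
            )
            break
        ep_index, epoch, _ = schedule.locate(t)
        label = epoch_occurrence_label(ep_index, epoch)
        frame_epochs[i] = label
        dets = detect_frame(
            frame,
            layout,
            epoch.color,
            schedule.background,
            cfg.detection,
            frame_index=i,
        )
        detections.extend(dets)
        measurements.extend(score_frame(dets, layout, label, cfg.min_offset_px))
        n_processed += 1
    logger.info("analyzed %d frames: %d detections", n_processed, len(detections))
    summaries = summarize_experiment(detections, measurements, frame_epochs, cfg)
    return detections, measurements, summaries


def summarize_experiment(
    detections: Sequence[Detection],
    measurements: Sequence[LarvaMeasurement],
    frame_epochs: dict[int, str],
    cfg: ExperimentConfig,
) -> pd.DataFrame:
    """One summary row per (ROI, epoch occurrence), in schedule order."""
    labels_in_order: list[str] = []
    for i in sorted(frame_epochs):
        if frame_epochs[i] not in labels_in_order:
            labels_in_order.append(frame_epochs[i])
    rows = []
    for label in labels_in_order:
        frames_in_epoch = {i for i, l in frame_epochs.items() if l == label}
        for roi in cfg.layout.rois:
            dets = [d for d in detections if d.roi_id == roi.roi_id and d.frame_index in frames_in_epoch]
            speed = None
            if len({d.frame_index for d in dets}) >= 2:
                speed = swim_speed(
                    dets, roi.roi_id, cfg.frame_interval_s, cfg.layout.px_per_mm, cfg.max_step_mm
                )
                if np.isnan(speed):
                    speed = None
            ms = [m for m in measurements if m.roi_id == roi.roi_id and m.epoch_label == label]
            rows.append(summarize_period(ms, label, roi.roi_id, speed))
    return summaries_to_frame(rows)


__all__ = [
    "analyze_frames",
    "summarize_experiment",
    "epoch_occurrence_label",
    "detections_to_frame",
    "measurements_to_frame",
]
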