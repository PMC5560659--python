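"""Experiment configuration: one YAML document describing the plate layout,
the assay schedule, the group assignment, and the detection / scoring /
statistics parameters.

Every parameter has a default; ``resolved_config`` re-emits the fully
resolved configuration (defaults included) so a run's provenance is
self-contained.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectionParams
from .geometry import (
    LANE_INNER_LENGTH_MM,
    LANE_PITCH_MM,
    N_LANES,
    WELL_DIAMETER_MM,
    WELL_GRID,
    WELL_PITCH_MM,
    PlateKind,
    PlateLayout,
    build_layout,
)
from .simulate import BehaviorParams, LarvaMorphology, SimulationConfig
from .stats import ComparisonDesign
from .stimuli import AssaySchedule, make_schedule

BEHAVIOR_PRESETS = {
    "baseline": lambda: BehaviorParams(),
    "responder": lambda: BehaviorParams.responder(),
    "blind": lambda: BehaviorParams.blind_larva(),
}


def default_image_size(plate_kind: PlateKind | str, px_per_mm: float, border_mm: float = 5.0) -> tuple[int, int]:
    """Image size that holds the standard plate grid plus a border."""
    plate_kind = PlateKind(plate_kind)
    if plate_kind is PlateKind.FIVE_LANE:
        w_mm = LANE_PITCH_MM * (N_LANES - 1) + 14.0 + 2 * border_mm
        h_mm = LANE_INNER_LENGTH_MM + 2 * border_mm
    else:
        ncol, nrow = WELL_GRID
        w_mm = WELL_PITCH_MM * (ncol - 1) + WELL_DIAMETER_MM + 2 * border_mm
        h_mm = WELL_PITCH_MM * (nrow - 1) + WELL_DIAMETER_MM + 2 * border_mm
    return (int(math.ceil(w_mm * px_per_mm)), int(math.ceil(h_mm * px_per_mm)))


@dataclass
class ExperimentConfig:
    layout: PlateLayout
    schedule: AssaySchedule
    seed: int = 0
    larvae_per_roi: int = 5
    groups: dict[int, BehaviorParams] = field(default_factory=dict)
    group_labels: dict[int, str] = field(default_factory=dict)
    frame_interval_s: float = 6.0
    n_frames: int | None = None
    t_start_s: float = 0.0
    behavior_step_s: float = 6.0
    morphology: LarvaMorphology = field(default_factory=LarvaMorphology)
    detection: DetectionParams = field(default_factory=DetectionParams)
    min_offset_px: float = 1.0
    max_step_mm: float = 5.0
    design: ComparisonDesign | None = None

    def __post_init__(self) -> None:
        sched_kind = self.schedule.plate_kind
        if sched_kind is not None and sched_kind is not self.layout.plate_kind:
            raise ValueError(
                f"schedule '{self.schedule.name}' needs a {sched_kind.value} layout, "
                f"got {self.layout.plate_kind.value}"
            )
        for roi in self.layout.rois:
            if roi.roi_id not in self.group_labels:
                raise ValueError(f"no group assigned to ROI {roi.roi_id}")

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(
            layout=self.layout,
            schedule=self.schedule,
            larvae_per_roi=self.larvae_per_roi,
            groups=self.groups,
            group_labels=self.group_labels,
            frame_interval_s=self.frame_interval_s,
            seed=self.seed,
            morphology=self.morphology,
            n_frames=self.n_frames,
            t_start_s=self.t_start_s,
            behavior_step_s=self.behavior_step_s,
        )


def _parse_behavior(spec) -> BehaviorParams:
    if isinstance(spec, str):
        try:
            return BEHAVIOR_PRESETS[spec]()
        except KeyError:
            raise ValueError(
                f"unknown behavior preset {spec!r}; valid: {sorted(BEHAVIOR_PRESETS)}"
            ) from None
    spec = dict(spec)
    preset = spec.pop("preset", "baseline")
    base = _parse_behavior(preset)
    return dataclasses.replace(base, **spec)


def parse_config(doc: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a parsed YAML document."""
    lay = dict(doc.get("layout", {}))
    plate_kind = PlateKind(lay.get("plate_kind", "six_well"))
    px_per_mm = float(lay.get("px_per_mm", 10.0))
    image_size = lay.get("image_size") or default_image_size(plate_kind, px_per_mm)
    layout = build_layout(plate_kind, tuple(image_size), px_per_mm, lay.get("margins"))

    sched_spec = doc.get("schedule", "red_cross_4x")
    if isinstance(sched_spec, str):
        schedule = make_schedule(sched_spec)
    else:
        schedule = AssaySchedule.from_dict(sched_spec)

    groups_doc = dict(doc.get("groups", {}))
    default_group = groups_doc.pop("default", None)
    groups: dict[int, BehaviorParams] = {}
    labels: dict[int, str] = {}
    for roi in layout.rois:
        entry = groups_doc.get(roi.roi_id, groups_doc.get(str(roi.roi_id), default_group))
        if entry is None:
            raise ValueError(f"no group assigned to ROI {roi.roi_id} and no default group")
        entry = dict(entry) if not isinstance(entry, str) else {"behavior": entry}
        labels[roi.roi_id] = str(entry.get("label", "default"))
        groups[roi.roi_id] = _parse_behavior(entry.get("behavior", "baseline"))

    det_doc = dict(doc.get("detection", {}))
    if "area_range_mm2" in det_doc:
        det_doc["area_range_mm2"] = tuple(det_doc["area_range_mm2"])
    detection = DetectionParams(**det_doc)
    scoring = dict(doc.get("scoring", {}))
    sim_doc = dict(doc.get("simulate", {}))
    morphology = LarvaMorphology(**sim_doc.get("morphology", {}))

    design = None
    if "stats" in doc:
        st = dict(doc["stats"])
        design = ComparisonDesign(
            metric=st.get("metric", "pct_cw"),
            pairs=tuple(tuple(p) for p in st.get("pairs", [])),
            m=st.get("m"),
            rm_epochs=tuple(st.get("rm_epochs", [])),
            alpha=float(st.get("alpha", 0.01)),
            always_gg=bool(st.get("always_gg", False)),
        )

    return ExperimentConfig(
        layout=layout,
        schedule=schedule,
        seed=int(doc.get("seed", 0)),
        larvae_per_roi=int(doc.get("larvae_per_roi", 5)),
        groups=groups,
        group_labels=labels,
        frame_interval_s=float(doc.get("frame_interval_s", 6.0)),
        n_frames=sim_doc.get("n_frames"),
        t_start_s=float(sim_doc.get("t_start_s", 0.0)),
        behavior_step_s=float(sim_doc.get("behavior_step_s", 6.0)),
        morphology=morphology,
        detection=detection,
        min_offset_px=float(scoring.get("min_offset_px", 1.0)),
        max_step_mm=float(scoring.get("max_step_mm", 5.0)),
        design=design,
    )


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return parse_config(doc)


def resolved_config(cfg: ExperimentConfig) -> dict:
    """The fully resolved configuration, every default made explicit."""
    return {
        "seed": cfg.seed,
        "layout": {
            "plate_kind": cfg.layout.plate_kind.value,
            "px_per_mm": cfg.layout.px_per_mm,
            "image_size": list(cfg.layout.image_size),
            "rois": [
                {
                    "roi_id": r.roi_id,
                    "shape": r.shape.value,
                    "center": [float(r.center[0]), float(r.center[1])],
                    "extent": list(r.extent) if isinstance(r.extent, tuple) else float(r.extent),
                    "long_axis": r.long_axis,
                    "up_end": r.up_end,
                }
                for r in cfg.layout.rois
            ],
        },
        "schedule": cfg.schedule.to_dict(),
        "larvae_per_roi": cfg.larvae_per_roi,
        "frame_interval_s": cfg.frame_interval_s,
        "groups": {
            r.roi_id: {
                "label": cfg.group_labels[r.roi_id],
                "behavior": dataclasses.asdict(cfg.groups.get(r.roi_id, BehaviorParams())),
            }
            for r in cfg.layout.rois
        },
        "simulate": {
            "n_frames": cfg.n_frames,
            "t_start_s": cfg.t_start_s,
            "behavior_step_s": cfg.behavior_step_s,
            "morphology": dataclasses.asdict(cfg.morphology),
        },
        "detection": {
            "threshold_method": cfg.detection.threshold_method,
            "background_radius_mm": cfg.detection.background_radius_mm,
            "area_range_mm2": list(cfg.detection.area_range_mm2),
            "min_contrast": cfg.detection.min_contrast,
        },
        "scoring": {"min_offset_px": cfg.min_offset_px, "max_step_mm": cfg.max_step_mm},
        "stats": None
        if cfg.design is None
        else {
            "metric": cfg.design.metric,
            "pairs": [list(p) for p in cfg.design.pairs],
            "m": cfg.design.family_size,
            "rm_epochs": list(cfg.design.rm_epochs),
            "alpha": cfg.design.alpha,
            "always_gg": cfg.design.always_gg,
        },
    }
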