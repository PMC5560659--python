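"""Standard validation experiments run entirely on simulated data.

Each function here wires the simulator, the detection pipeline, the scorer
and the statistics into one self-contained experiment with the layout,
group sizes and assay schedules the plates are designed around: 5-lane
plates analyzed as n = 10 lanes (two plates), 6-well plates as n = 12
wells (two plates), 5 larvae per well/lane (or 1 larva per well for the
repeated-cross design).  Frame counts are reduced relative to a full
bench recording by sampling the same epochs more sparsely; the behavioral
effect sizes come from the generator defaults.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd

from .config import default_image_size
from .detect import DetectionParams, detect_frame
from .geometry import PlateKind, build_layout
from .pipeline import analyze_frames, epoch_occurrence_label
from .score import summarize_period, score_frame, swim_speed
from .simulate import BehaviorParams, SimulationConfig, simulate_assay
from .stats import ComparisonDesign, RMAnovaResult, compare_epochs, welch_t
from .stimuli import (
    AssaySchedule,
    StimulusEpoch,
    StimulusKind,
    StimulusParams,
    make_schedule,
    render_schedule_frame,
)
from .validate import (
    DetectionFidelity,
    evaluate_detections,
    true_mean_speed_mm_min,
    truth_as_detections,
)

LANE_COLORS = ("red", "green", "blue", "yellow")
WELL_COLORS = ("red", "green", "blue", "yellow", "cyan")


def _single_epoch_schedule(kind: StimulusKind, color: str) -> AssaySchedule:
    background = "light_gray" if kind in (StimulusKind.CROSS_CW, StimulusKind.CROSS_CCW) else "white"
    params = StimulusParams(dot_diameter_mm=1.0) if kind is StimulusKind.DOTS_MOVING_UP else StimulusParams()
    return AssaySchedule(
        name=f"{kind.value}_{color}",
        epochs=(StimulusEpoch(kind, color, 1200.0, params),),
        background=background,
    )


def _sim(layout, schedule, seed, *, larvae_per_roi=5, n_frames=10, t_start_s=0.0,
         frame_interval_s=6.0, behavior=None) -> SimulationConfig:
    behavior = behavior or BehaviorParams.responder()
    return SimulationConfig(
        layout=layout,
        schedule=schedule,
        larvae_per_roi=larvae_per_roi,
        groups={r.roi_id: behavior for r in layout.rois},
        frame_interval_s=frame_interval_s,
        seed=seed,
        n_frames=n_frames,
        t_start_s=t_start_s,
    )



def detection_fidelity_suite(
    seed: int,
    frames_per_condition: int = 5,
    px_per_mm: float = 10.0,
    larvae_per_roi: int = 5,
) -> tuple[DetectionFidelity, dict[str, DetectionFidelity]]:
    """Detection fidelity over every stimulus kind and color at default parameters.

    Simulates ``frames_per_condition`` frames for each (kind, color)
    condition — bars and dots in red/green/blue/yellow on lanes, crosses in
    all five colors on wells, plus blank frames on both plate kinds — runs
    the detection pipeline, and matches against ground truth.  Returns the
    pooled fidelity and the per-condition breakdown.
    """
    lane_layout = build_layout("five_lane", default_image_size("five_lane", px_per_mm), px_per_mm)
    well_layout = build_layout("six_well", default_image_size("six_well", px_per_mm), px_per_mm)
    conditions: list[tuple[StimulusKind, str]] = [(StimulusKind.BLANK, "none")]
    for color in LANE_COLORS:
        for kind in (StimulusKind.BAR_UP_HALF, StimulusKind.BAR_DOWN_HALF, StimulusKind.DOTS_MOVING_UP):
            conditions.append((kind, color))
    for color in WELL_COLORS:
        for kind in (StimulusKind.CROSS_CW, StimulusKind.CROSS_CCW):
            conditions.append((kind, color))

    per_condition: dict[str, DetectionFidelity] = {}
    rng = np.random.default_rng(seed)
    for kind, color in conditions:
        schedule = _single_epoch_schedule(kind, color)
        layouts = (
            [lane_layout, well_layout]
            if kind is StimulusKind.BLANK
            else [lane_layout if schedule.plate_kind is PlateKind.FIVE_LANE else well_layout]
        )
        parts = []
        for layout in layouts:
            cfg = _sim(layout, schedule, int(rng.integers(2**31)),
                       larvae_per_roi=larvae_per_roi, n_frames=frames_per_condition)
            frames, truth = simulate_assay(cfg)
            dets = []
            for i, frame in enumerate(frames):
                dets += detect_frame(frame, layout, color, schedule.background,
                                     DetectionParams(), frame_index=i)
            parts.append(evaluate_detections(truth, dets, layout))
        per_condition[f"{kind.value}:{color}"] = DetectionFidelity.combine(parts)
    overall = DetectionFidelity.combine(list(per_condition.values()))
    return overall, per_condition


def measurement_bookkeeping(seed: int, px_per_mm: float = 5.0) -> list[int]:
    """Measurement counts for 6 wells of 5 larvae imaged 10 min at 10 frames/min.

    Uses ground-truth positions as idealized detections (perfect detection)
    so the count reflects the bookkeeping alone: 5 larvae x 10 min x
    10 frames/min = 500 measurements per well.
    """
    layout = build_layout("six_well", default_image_size("six_well", px_per_mm), px_per_mm)
    schedule = make_schedule("red_cross_4x")
    cfg = _sim(layout, schedule, seed, larvae_per_roi=5, n_frames=100,
               frame_interval_s=6.0, behavior=BehaviorParams())
    _, truth = simulate_assay(cfg)
    dets = truth_as_detections(truth, layout)
    label = epoch_occurrence_label(0, schedule.epochs[0])
    ms = score_frame(dets, layout, label)
    return [
        summarize_period(ms, label, roi.roi_id).n_measurements for roi in layout.rois
    ]


def cross_period_identity(px_per_mm: float = 10.0) -> float:
    """Fraction of identical pixels between cross frames one rotation apart.

    At 90 deg / 5 s the cross completes 3 rotations per minute, so the
    frame at t and at t + 20 s must be bit-identical (returns 1.0).
    """
    layout = build_layout("six_well", default_image_size("six_well", px_per_mm), px_per_mm)
    schedule = make_schedule("red_cross_4x")
    f_a = render_schedule_frame(schedule, 1200.0, layout)
    f_b = render_schedule_frame(schedule, 1220.0, layout)
    return float((f_a == f_b).mean())


def type_i_error(
    seed: int,
    n_replicates: int = 200,
    alpha: float = 0.05,
    px_per_mm: float = 5.0,
    frames_per_epoch: int = 10,
) -> dict:
    """Type-I error of the full pipeline on blind larvae.

    Each replicate simulates one 6-well plate of blind larvae through a
    clockwise and a counter-clockwise cross epoch, runs detection and
    scoring, and Welch-tests %CW between the two epochs across wells.
    Under the null (no visual response) the rejection rate at ``alpha``
    estimates the pipeline's false-positive rate.
    """
    from .config import parse_config

    rng = np.random.default_rng(seed)
    rejections = 0
    pvals = []
    for _ in range(n_replicates):
        interval = 600.0 / frames_per_epoch
        doc = {
            "layout": {"plate_kind": "six_well", "px_per_mm": px_per_mm},
            "schedule": "red_cross_4x",
            "seed": int(rng.integers(2**31)),
            "larvae_per_roi": 5,
            "frame_interval_s": interval,
            "groups": {"default": {"label": "blind", "behavior": "blind"}},
            "simulate": {"n_frames": 2 * frames_per_epoch, "t_start_s": 1200.0},
        }
        cfg = parse_config(doc)
        frames, _ = simulate_assay(cfg.simulation())
        _, _, summ = analyze_frames(frames, cfg)
        cw = summ[summ.epoch == "01:cross_cw_red"].set_index("roi")["pct_cw"]
        ccw = summ[summ.epoch == "02:cross_ccw_red"].set_index("roi")["pct_cw"]
        p = welch_t(cw.to_numpy(), ccw.to_numpy()).p_raw
        pvals.append(p)
        rejections += p < alpha
    return {"rate": rejections / n_replicates, "n": n_replicates, "alpha": alpha,
            "pvals": pvals}


def _two_plate_summaries(doc_base: dict, seeds: tuple[int, int]) -> pd.DataFrame:
    """Summaries of two simulated plates, wells of the second re-numbered."""
    from .config import parse_config

    tables = []
    n_rois = 0
    for k, seed in enumerate(seeds):
        doc = dict(doc_base)
        doc["seed"] = int(seed)
        cfg = parse_config(doc)
        frames, _ = simulate_assay(cfg.simulation())
        _, _, summ = analyze_frames(frames, cfg)
        summ = summ.copy()
        summ["roi"] = summ["roi"] + n_rois
        n_rois += len(cfg.layout.rois)
        tables.append(summ)
    return pd.concat(tables, ignore_index=True)


def responder_power_wells(seed: int, px_per_mm: float = 5.0, frames_per_epoch: int = 10) -> dict:
    """Clockwise vs counter-clockwise %CW contrast in 12 responder wells.

    Two 6-well plates (n = 12 wells), 5 larvae per well, one cw + one ccw
    red-cross epoch; Welch t with a Bonferroni family of 2.
    """
    rng = np.random.default_rng(seed)
    interval = 600.0 / frames_per_epoch
    doc = {
        "layout": {"plate_kind": "six_well", "px_per_mm": px_per_mm},
        "schedule": "red_cross_4x",
        "larvae_per_roi": 5,
        "frame_interval_s": interval,
        "groups": {"default": {"label": "responder", "behavior": "responder"}},
        "simulate": {"n_frames": 2 * frames_per_epoch, "t_start_s": 1200.0},
    }
    summ = _two_plate_summaries(doc, tuple(int(s) for s in rng.integers(2**31, size=2)))
    design = ComparisonDesign(metric="pct_cw", pairs=(("01:cross_cw_red", "02:cross_ccw_red"),), m=2)
    report = compare_epochs(summ, design)
    row = report.pairwise.iloc[0]
    cw_mean = summ[summ.epoch == "01:cross_cw_red"]["pct_cw"].mean()
    ccw_mean = summ[summ.epoch == "02:cross_ccw_red"]["pct_cw"].mean()
    return {
        "p_adj": float(row["p_adj"]),
        "t": float(row["t"]),
        "n_wells": int(row["n_a"]),
        "pct_cw_during_cw": float(cw_mean),
        "pct_cw_during_ccw": float(ccw_mean),
    }


def responder_power_lanes(seed: int, px_per_mm: float = 5.0, frames_per_epoch: int = 150) -> dict:
    """Bar vs dots %up contrast in 10 responder lanes (two 5-lane plates).

    Larvae avoid the moving bar (low %up) and follow the upward dots
    (high %up); Welch t on %up with a Bonferroni family of 2.  The default
    150 frames per 15-min epoch is the full 6-s acquisition interval: the
    location measures need the real frame density because the epoch
    average depends on how long larvae have been drifting.
    """
    rng = np.random.default_rng(seed)
    interval = 900.0 / frames_per_epoch
    doc = {
        "layout": {"plate_kind": "five_lane", "px_per_mm": px_per_mm},
        "schedule": "bar_dots",
        "larvae_per_roi": 5,
        "frame_interval_s": interval,
        "groups": {"default": {"label": "responder", "behavior": "responder"}},
        "simulate": {"n_frames": 2 * frames_per_epoch, "t_start_s": 900.0},
    }
    summ = _two_plate_summaries(doc, tuple(int(s) for s in rng.integers(2**31, size=2)))
    design = ComparisonDesign(
        metric="pct_up", pairs=(("01:bar_up_half_red", "02:dots_moving_up_red"),), m=2
    )
    report = compare_epochs(summ, design)
    row = report.pairwise.iloc[0]
    return {
        "p_adj": float(row["p_adj"]),
        "t": float(row["t"]),
        "n_lanes": int(row["n_a"]),
        "pct_up_bar": float(summ[summ.epoch == "01:bar_up_half_red"]["pct_up"].mean()),
        "pct_up_dots": float(summ[summ.epoch == "02:dots_moving_up_red"]["pct_up"].mean()),
    }


def repeated_cross_rm_anova(
    seed: int, px_per_mm: float = 5.0, frames_per_epoch: int = 10
) -> RMAnovaResult:
    """RM-ANOVA over the 8 repeated cross epochs, 12 wells of 1 responder larva.

    Mirrors the single-larva repeated red-cross design: stimulus (cw/ccw
    x 4 repeats) as the within-subject factor and %CW as the response,
    Greenhouse-Geisser applied when sphericity is rejected.
    """
    rng = np.random.default_rng(seed)
    interval = 600.0 / frames_per_epoch
    doc = {
        "layout": {"plate_kind": "six_well", "px_per_mm": px_per_mm},
        "schedule": "red_cross_4x",
        "larvae_per_roi": 1,
        "frame_interval_s": interval,
        "groups": {"default": {"label": "responder", "behavior": "responder"}},
        "simulate": {"n_frames": 8 * frames_per_epoch, "t_start_s": 1200.0},
    }
    summ = _two_plate_summaries(doc, tuple(int(s) for s in rng.integers(2**31, size=2)))
    epochs = sorted(e for e in summ["epoch"].unique() if "cross" in e)
    design = ComparisonDesign(metric="pct_cw", rm_epochs=tuple(epochs))
    report = compare_epochs(summ, design)
    assert report.anova is not None
    return report.anova


def swim_speed_recovery(seed: int, px_per_mm: float = 10.0, n_frames: int = 20) -> dict:
    """Detected vs ground-truth swim speed during the stimulus-free period.

    One 6-well plate of 5 baseline larvae per well imaged during the blank
    epoch; the detector's nearest-neighbor-linked speed is compared to the
    simulator's true mean step speed.
    """
    layout = build_layout("six_well", default_image_size("six_well", px_per_mm), px_per_mm)
    schedule = make_schedule("red_cross_4x")
    cfg = _sim(layout, schedule, seed, larvae_per_roi=5, n_frames=n_frames,
               behavior=BehaviorParams())
    frames, truth = simulate_assay(cfg)
    dets = []
    for i, frame in enumerate(frames):
        dets += detect_frame(frame, layout, "none", schedule.background,
                             DetectionParams(), frame_index=i)
    measured = []
    true = []
    for roi in layout.rois:
        measured.append(swim_speed(dets, roi.roi_id, cfg.frame_interval_s, px_per_mm))
        true.append(true_mean_speed_mm_min(truth, roi.roi_id, cfg.frame_interval_s, px_per_mm))
    return {
        "measured_mm_min": float(np.nanmean(measured)),
        "true_mm_min": float(np.nanmean(true)),
        "n_wells": len(layout.rois),
    }
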