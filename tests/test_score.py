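import math

import numpy as np
import pytest

from zebraplate.detect import Detection
from zebraplate.geometry import Half, Quadrant
from zebraplate.score import (
    CW_TABLE,
    HEADING_VECTORS,
    HeadingClass,
    Rotational,
    heading_from_offset,
    rotational_class,
    score_frame,
    summarize_period,
    swim_speed,
)


class TestHeadingFromOffset:
    @pytest.mark.parametrize(
        "d,expected",
        [
            ((0.0, -3.0), HeadingClass.UP),  # screen-up is negative y
            ((3.0, 0.0), HeadingClass.RIGHT),
            ((0.0, 3.0), HeadingClass.DOWN),
            ((-3.0, 0.0), HeadingClass.LEFT),
            ((0.0, 0.0), HeadingClass.NONE),  # sub-threshold offset
            ((0.5, 0.5), HeadingClass.NONE),
            ((2.0, -2.0), HeadingClass.RIGHT),  # exact diagonal -> horizontal
            ((-2.0, 2.0), HeadingClass.LEFT),
            ((1.9, -2.1), HeadingClass.UP),
        ],
    )
    def test_quantization_and_tie_breaks(self, d, expected):
        assert heading_from_offset(d, (0.0, 0.0), 1.0) is expected

    def test_threshold_is_configurable(self):
        assert heading_from_offset((0.0, -0.5), (0.0, 0.0), 0.1) is HeadingClass.UP


def tangent_sign_oracle(heading: HeadingClass, quadrant: Quadrant) -> Rotational:
    """Independent oracle: cw iff h . (-d_y, d_x) > 0 at the quadrant's
    representative offset d from the well center."""
    reps = {
        Quadrant.TL: (-1.0, -1.0),
        Quadrant.TR: (1.0, -1.0),
        Quadrant.BL: (-1.0, 1.0),
        Quadrant.BR: (1.0, 1.0),
    }
    dx, dy = reps[quadrant]
    tx, ty = -dy, dx  # on-screen clockwise tangent
    hx, hy = HEADING_VECTORS[heading]
    return Rotational.CW if hx * tx + hy * ty > 0 else Rotational.CCW


class TestRotationalClass:
    def test_top_left_quarter_up_and_right_are_clockwise(self):
        assert rotational_class(HeadingClass.UP, Quadrant.TL) is Rotational.CW
        assert rotational_class(HeadingClass.RIGHT, Quadrant.TL) is Rotational.CW
        assert rotational_class(HeadingClass.DOWN, Quadrant.TL) is Rotational.CCW
        assert rotational_class(HeadingClass.LEFT, Quadrant.BR) is Rotational.CW

    def test_all_16_pairs_match_tangent_sign_oracle(self):
        for q in Quadrant:
            for h in (HeadingClass.UP, HeadingClass.RIGHT, HeadingClass.DOWN, HeadingClass.LEFT):
                assert rotational_class(h, q) is tangent_sign_oracle(h, q), (h, q)

    def test_each_quadrant_splits_headings_two_and_two(self):
        for q in Quadrant:
            assert len(CW_TABLE[q]) == 2

    def test_heading_none_rejected(self):
        with pytest.raises(ValueError, match="none"):
            rotational_class(HeadingClass.NONE, Quadrant.TL)


def det(roi_id, cx, cy, off=(0.0, 0.0), frame=0, half_size=20):
    """A detection whose centroid is displaced `off` from the bbox center."""
    return Detection(
        frame_index=frame,
        roi_id=roi_id,
        centroid=(cx + off[0], cy + off[1]),
        bbox=(int(cx - half_size), int(cy - half_size), int(cx + half_size), int(cy + half_size)),
        area=300,
    )


class TestScoreFrame:
    def test_lane_detection_above_midline_is_up(self, lane_layout):
        roi = lane_layout.rois[0]
        cx, cy = roi.center
        ms = score_frame([det(roi.roi_id, cx, cy - 50)], lane_layout, "ep")
        assert ms[0].half is Half.UP
        assert ms[0].quadrant is None

    def test_well_detection_without_heading_is_unclassified(self, well_layout):
        roi = well_layout.rois[0]
        cx, cy = roi.center
        ms = score_frame([det(roi.roi_id, cx - 30, cy - 30)], well_layout, "ep")
        assert ms[0].heading is HeadingClass.NONE
        assert ms[0].rotational is Rotational.UNCLASSIFIED

    def test_well_detection_heading_up_in_tl_is_cw(self, well_layout):
        roi = well_layout.rois[0]
        cx, cy = roi.center
        ms = score_frame([det(roi.roi_id, cx - 30, cy - 30, off=(0.0, -3.0))], well_layout, "ep")
        assert ms[0].quadrant is Quadrant.TL
        assert ms[0].rotational is Rotational.CW

    def test_one_measurement_per_detection(self, well_layout):
        roi = well_layout.rois[0]
        cx, cy = roi.center
        dets = [det(roi.roi_id, cx + dx, cy, off=(3.0, 0.0)) for dx in (-40, -20, 0, 20, 40)]
        ms = score_frame(dets, well_layout, "ep")
        assert len(ms) == 5

    def test_counts_partition_measurements(self, well_layout):
        roi = well_layout.rois[0]
        cx, cy = roi.center
        rng = np.random.default_rng(3)
        dets = []
        for i in range(40):
            off = rng.normal(0, 2.0, size=2)
            dets.append(det(roi.roi_id, cx + rng.uniform(-50, 50), cy + rng.uniform(-50, 50),
                            off=tuple(off), frame=i))
        ms = score_frame(dets, well_layout, "ep")
        n_cw = sum(m.rotational is Rotational.CW for m in ms)
        n_ccw = sum(m.rotational is Rotational.CCW for m in ms)
        n_unc = sum(m.rotational is Rotational.UNCLASSIFIED for m in ms)
        assert n_cw + n_ccw + n_unc == len(ms) == 40


class TestSummarizePeriod:
    def test_five_larvae_ten_minutes_ten_fpm_gives_500(self, well_layout):
        """5 larvae imaged for 10 minutes at 10 frames/min -> 500 measurements."""
        roi = well_layout.rois[0]
        cx, cy = roi.center
        dets = []
        for frame in range(100):  # 10 min at 10 frames/min
            for k in range(5):
                dets.append(det(roi.roi_id, cx - 40 + 20 * k, cy, off=(3.0, 0.0), frame=frame))
        ms = score_frame(dets, well_layout, "cw1")
        s = summarize_period(ms, "cw1", roi.roi_id)
        assert s.n_measurements == 500

    def test_pct_up_ratio(self, lane_layout):
        roi = lane_layout.rois[0]
        cx, cy = roi.center
        dets = [det(roi.roi_id, cx, cy - 10, frame=i) for i in range(300)]
        dets += [det(roi.roi_id, cx, cy + 10, frame=i) for i in range(200)]
        ms = score_frame(dets, lane_layout, "bar")
        s = summarize_period(ms, "bar", roi.roi_id)
        assert s.pct_up == pytest.approx(0.6)
        assert s.n_measurements == 500

    def test_all_cw_gives_pct_cw_one(self, well_layout):
        roi = well_layout.rois[0]
        cx, cy = roi.center
        dets = [det(roi.roi_id, cx - 30, cy - 30, off=(0.0, -3.0), frame=i) for i in range(10)]
        ms = score_frame(dets, well_layout, "cw")
        s = summarize_period(ms, "cw", roi.roi_id)
        assert s.pct_cw == 1.0

    def test_no_classifiable_measurements_gives_none(self, well_layout):
        roi = well_layout.rois[0]
        cx, cy = roi.center
        ms = score_frame([det(roi.roi_id, cx - 30, cy - 30)], well_layout, "ep")
        s = summarize_period(ms, "ep", roi.roi_id)
        assert s.pct_cw is None and s.pct_up is None
        assert s.n_measurements == 1


class TestSwimSpeed:
    def test_stationary_larva_speed_zero(self):
        dets = [det(0, 100, 100, frame=i) for i in range(5)]
        assert swim_speed(dets, 0, 6.0, 10.0) == 0.0

    def test_one_mm_per_six_second_frame_is_10_mm_per_min(self):
        dets = [det(0, 100 + 10 * i, 100, frame=i) for i in range(5)]  # 10 px = 1 mm
        assert swim_speed(dets, 0, 6.0, 10.0) == pytest.approx(10.0)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            swim_speed([det(0, 100, 100)], 0, 6.0, 10.0)

    def test_gate_excludes_implausible_jumps(self):
        dets = [det(0, 100, 100, frame=0), det(0, 500, 100, frame=1)]  # 40 mm jump
        assert math.isnan(swim_speed(dets, 0, 6.0, 10.0, max_step_mm=5.0))

    def test_recovers_simulated_mean_speed(self, small_well_layout):
        from zebraplate.simulate import BehaviorParams, simulate_assay
        from zebraplate.validate import true_mean_speed_mm_min, truth_as_detections

        from conftest import make_sim

        cfg = make_sim(small_well_layout, "red_cross_4x", BehaviorParams(), seed=9,
                       n_frames=20, larvae_per_roi=5)
        _, truth = simulate_assay(cfg)
        dets = truth_as_detections(truth, small_well_layout)
        roi_id = 0
        measured = swim_speed(dets, roi_id, 6.0, small_well_layout.px_per_mm)
        true = true_mean_speed_mm_min(truth, roi_id, 6.0, small_well_layout.px_per_mm)
        assert measured == pytest.approx(true, rel=0.15)
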