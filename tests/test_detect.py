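import numpy as np
import pytest

from zebraplate.detect import (
    Detection,
    DetectionParams,
    detect_frame,
    particle_analysis,
    select_channel,
    subtract_background,
    threshold_well,
)
from zebraplate.geometry import RoiShape, RoiSpec, build_layout
from zebraplate.simulate import LarvaMorphology, render_larva
from zebraplate.stimuli import BACKGROUNDS, COLORS


def channel_diff_oracle(color, background):
    """Independent enumeration of |stimulus - background| per channel."""
    stim = COLORS[color]
    bg = BACKGROUNDS[background]
    return [abs(stim[c] - bg[c]) for c in range(3)]


class TestSelectChannel:
    def test_red_on_white_gives_red_channel(self):
        assert select_channel(None, "red", "white") == 0

    def test_cyan_on_light_gray_gives_green_channel(self):
        # G and B tie at |255-230| = 25; tie broken toward G
        diffs = channel_diff_oracle("cyan", "light_gray")
        assert diffs[1] == diffs[2] == min(diffs)
        assert select_channel(None, "cyan", "light_gray") == 1

    def test_blank_epoch_falls_back_to_red_channel(self):
        assert select_channel(None, "none", "white") == 0
        assert select_channel(None, "none", "light_gray") == 0

    @pytest.mark.parametrize("color", ["red", "green", "blue", "yellow", "cyan"])
    @pytest.mark.parametrize("background", ["white", "light_gray"])
    def test_matches_enumeration_oracle(self, color, background):
        diffs = channel_diff_oracle(color, background)
        chosen = select_channel(None, color, background)
        assert diffs[chosen] == min(diffs)
        # ties prefer the earliest channel
        assert all(diffs[c] > diffs[chosen] for c in range(chosen))


class TestSubtractBackground:
    def test_uniform_image_becomes_flat(self):
        img = np.full((200, 200), 180, dtype=np.uint8)
        out = subtract_background(img, 50)
        assert (out == 255).all()

    def test_gradient_illumination_flattened(self):
        # the corrected field is flat away from the border band (one
        # background radius wide), which the per-ROI crops pad for
        yy, xx = np.mgrid[0:300, 0:300]
        img = (150 + 60 * xx / 300).astype(np.uint8)
        out = subtract_background(img, 50)
        interior = out[50:-50, 50:-50].astype(float)
        assert interior.std() < 1.0
        assert np.abs(interior - 255).max() <= 1

    def test_larva_survives_and_stimulus_edges_vanish(self):
        layout = build_layout("six_well", (1280, 920), 10.0)
        roi = layout.rois[1]
        frame = np.full((920, 1280, 3), 230, dtype=np.uint8)
        render_larva(frame, roi.center, 45.0, LarvaMorphology(), 10.0)
        out = subtract_background(frame[:, :, 0], 50)
        mask = threshold_well(out, roi)
        n_particles = len(particle_analysis(mask, out, roi, (50, 800)))
        assert n_particles == 1

    def test_small_radius_warns(self):
        img = np.full((50, 50), 200, dtype=np.uint8)
        with pytest.warns(UserWarning, match="larva"):
            subtract_background(img, 4, larva_width_px=8.0)


class TestThresholdWell:
    def test_empty_roi_yields_empty_mask(self):
        roi = RoiSpec(0, RoiShape.DISC, (100.0, 100.0), 80.0)
        corrected = np.full((200, 200), 255, dtype=np.uint8)
        assert not threshold_well(corrected, roi).any()

    def test_mask_area_close_to_rendered_silhouette(self):
        layout = build_layout("six_well", (1280, 920), 10.0)
        roi = layout.rois[0]
        frame = np.full((920, 1280, 3), 255, dtype=np.uint8)
        render_larva(frame, roi.center, 30.0, LarvaMorphology(), 10.0)
        true_area = int((frame[:, :, 0] < 128).sum())
        corrected = subtract_background(frame[:, :, 0], 50)
        mask = threshold_well(corrected, roi)
        assert true_area * 0.7 <= mask.sum() <= true_area * 1.3

    def test_five_separated_larvae_give_five_components(self):
        layout = build_layout("six_well", (1280, 920), 10.0)
        roi = layout.rois[0]
        cx, cy = roi.center
        frame = np.full((920, 1280, 3), 255, dtype=np.uint8)
        for k in range(5):
            a = 2 * np.pi * k / 5
            render_larva(frame, (cx + 80 * np.cos(a), cy + 80 * np.sin(a)),
                         60.0 * k, LarvaMorphology(), 10.0)
        corrected = subtract_background(frame[:, :, 0], 50)
        mask = threshold_well(corrected, roi)
        dets = particle_analysis(mask, corrected, roi, (50, 800))
        assert len(dets) == 5

    def test_unknown_method_rejected(self):
        roi = RoiSpec(0, RoiShape.DISC, (100.0, 100.0), 80.0)
        with pytest.raises(ValueError, match="method"):
            threshold_well(np.zeros((200, 200), np.uint8), roi, method="fancy")


class TestParticleAnalysis:
    def test_symmetric_blob_centroid_and_bbox(self):
        roi = RoiSpec(0, RoiShape.RECTANGLE, (15.0, 15.0), (30.0, 30.0))
        mask = np.zeros((40, 40), dtype=bool)
        mask[9:12, 9:12] = True  # 3x3 blob centered at (10, 10)
        corrected = np.where(mask, 0, 255).astype(np.uint8)
        dets = particle_analysis(mask, corrected, roi, (1, 100))
        assert len(dets) == 1
        d = dets[0]
        assert d.centroid == pytest.approx((10.0, 10.0))
        assert d.bbox == (9, 9, 11, 11)
        assert d.bbox_center == (10.0, 10.0)
        assert d.area == 9

    def test_area_filter_drops_small_blob(self):
        roi = RoiSpec(0, RoiShape.RECTANGLE, (20.0, 20.0), (40.0, 40.0))
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:8, 5:8] = True  # area 9
        mask[20:22, 20:22] = True  # area 4, below min
        corrected = np.where(mask, 0, 255).astype(np.uint8)
        dets = particle_analysis(mask, corrected, roi, (5, 100))
        assert len(dets) == 1
        assert dets[0].area == 9

    def test_centroid_inside_bbox(self):
        roi = RoiSpec(0, RoiShape.RECTANGLE, (20.0, 20.0), (40.0, 40.0))
        rng = np.random.default_rng(0)
        mask = rng.random((40, 40)) > 0.7
        corrected = np.where(mask, 30, 255).astype(np.uint8)
        for d in particle_analysis(mask, corrected, roi, (1, 2000)):
            x0, y0, x1, y1 = d.bbox
            assert x0 <= d.centroid[0] <= x1
            assert y0 <= d.centroid[1] <= y1

    def test_offset_points_toward_head_over_many_poses(self):
        """Over >= 100 rendered poses the centroid - bbox-center offset lies
        within 45 degrees of the true heading."""
        layout = build_layout("six_well", (1280, 920), 10.0)
        roi = layout.rois[0]
        cx, cy = roi.center
        rng = np.random.default_rng(42)
        n_ok, n = 0, 120
        for _ in range(n):
            heading = rng.uniform(0, 360)
            pos = (cx + rng.uniform(-60, 60), cy + rng.uniform(-60, 60))
            frame = np.full((920, 1280, 3), 255, dtype=np.uint8)
            render_larva(frame, pos, heading, LarvaMorphology(), 10.0)
            dets = detect_frame(frame, layout, "none", "white")
            assert len(dets) == 1
            d = dets[0]
            off = np.array(d.centroid) - np.array(d.bbox_center)
            u = np.array([np.cos(np.deg2rad(heading)), np.sin(np.deg2rad(heading))])
            cosang = off @ u / np.linalg.norm(off)
            n_ok += cosang > np.cos(np.deg2rad(45))
        assert n_ok / n >= 0.9


class TestDeterminism:
    def test_same_frame_same_detections(self):
        layout = build_layout("six_well", (1280, 920), 10.0)
        frame = np.full((920, 1280, 3), 230, dtype=np.uint8)
        render_larva(frame, layout.rois[2].center, 123.0, LarvaMorphology(), 10.0)
        a = detect_frame(frame, layout, "red", "light_gray")
        b = detect_frame(frame, layout, "red", "light_gray")
        assert a == b
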