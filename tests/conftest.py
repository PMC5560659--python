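import numpy as np
import pytest

from zebraplate import build_layout, make_schedule
from zebraplate.config import default_image_size, parse_config
from zebraplate.simulate import BehaviorParams, SimulationConfig


@pytest.fixture(scope="session")
def lane_layout():
    return build_layout("five_lane", default_image_size("five_lane", 10.0), 10.0)


@pytest.fixture(scope="session")
def well_layout():
    return build_layout("six_well", default_image_size("six_well", 10.0), 10.0)


@pytest.fixture(scope="session")
def small_well_layout():
    """Coarser scale for Monte-Carlo work: same plate, 5 px/mm."""
    return build_layout("six_well", default_image_size("six_well", 5.0), 5.0)


def make_sim(layout, schedule_name, behavior: BehaviorParams, *, seed=0, n_frames=10,
             t_start_s=0.0, larvae_per_roi=5, frame_interval_s=6.0):
    schedule = make_schedule(schedule_name)
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


@pytest.fixture
def sim_factory():
    return make_sim


@pytest.fixture
def experiment_doc():
    """A minimal six-well experiment config document."""
    return {
        "layout": {"plate_kind": "six_well", "px_per_mm": 10.0},
        "schedule": "red_cross_4x",
        "seed": 7,
        "larvae_per_roi": 2,
        "frame_interval_s": 6.0,
        "groups": {"default": {"label": "control", "behavior": "responder"}},
        "simulate": {"n_frames": 4, "t_start_s": 1200.0},
        "stats": {
            "metric": "pct_cw",
            "pairs": [["01:cross_cw_red", "02:cross_ccw_red"]],
            "m": 1,
        },
    }


@pytest.fixture
def experiment_config(experiment_doc):
    return parse_config(experiment_doc)
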