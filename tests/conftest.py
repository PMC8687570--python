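import json

import numpy as np
import pytest

from posefreq import SimulationParams, simulate_task_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def noiseless_trial():
    """Clean 2 Hz finger-tapping trial with frame-aligned events."""
    params = SimulationParams(
        task="finger_tapping",
        frequency_hz=2.0,
        noise_sd_px=0.0,
        dropout_rate=0.0,
        seed=1,
    )
    return simulate_task_trial(params)


def make_frame_doc(
    body=None, left_hand=None, right_hand=None, n_people=1
):
    """Build an OpenPose-dialect JSON document string."""
    if n_people == 0:
        return json.dumps({"version": 1.3, "people": []})
    person = {}
    person["pose_keypoints_2d"] = body if body is not None else [0.0] * 75
    person["hand_left_keypoints_2d"] = left_hand if left_hand is not None else [0.0] * 63
    person["hand_right_keypoints_2d"] = right_hand if right_hand is not None else [0.0] * 63
    return json.dumps({"version": 1.3, "people": [person] * n_people})
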