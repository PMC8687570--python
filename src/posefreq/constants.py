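"""Keypoint index maps for the OpenPose BODY_25 and 21-point hand models.

All keypoint indexing in posefreq goes through these tables; no other module
hard-codes a keypoint index.  Coordinates everywhere follow the image
convention: origin at the top-left corner, x to the right, y *downward* in
pixels.  "Elevation" in task signals is therefore the negated y coordinate.
"""

from __future__ import annotations

N_BODY_KEYPOINTS = 25
N_HAND_KEYPOINTS = 21

#: BODY_25 keypoint ordering of the OpenPose body model.
BODY_25: dict[str, int] = {
    "nose": 0,
    "neck": 1,
    "right_shoulder": 2,
    "right_elbow": 3,
    "right_wrist": 4,
    "left_shoulder": 5,
    "left_elbow": 6,
    "left_wrist": 7,
    "mid_hip": 8,
    "right_hip": 9,
    "right_knee": 10,
    "right_ankle": 11,
    "left_hip": 12,
    "left_knee": 13,
    "left_ankle": 14,
    "right_eye": 15,
    "left_eye": 16,
    "right_ear": 17,
    "left_ear": 18,
    "left_big_toe": 19,
    "left_small_toe": 20,
    "left_heel": 21,
    "right_big_toe": 22,
    "right_small_toe": 23,
    "right_heel": 24,
}

#: 21-keypoint hand model ordering (wrist, then 4 points per digit ending at
#: the fingertip).  Only the landmarks the task signals use are named; the
#: remaining indices follow the same thumb→pinky, base→tip layout.
HAND: dict[str, int] = {
    "wrist": 0,
    "thumb_cmc": 1,
    "thumb_mcp": 2,
    "thumb_ip": 3,
    "thumb_tip": 4,
    "index_mcp": 5,
    "index_pip": 6,
    "index_dip": 7,
    "index_tip": 8,
    "middle_mcp": 9,
    "middle_pip": 10,
    "middle_dip": 11,
    "middle_tip": 12,
    "ring_mcp": 13,
    "ring_pip": 14,
    "ring_dip": 15,
    "ring_tip": 16,
    "pinky_mcp": 17,
    "pinky_pip": 18,
    "pinky_dip": 19,
    "pinky_tip": 20,
}

#: Side-resolved BODY_25 landmarks used by the lower-extremity tasks.
BIG_TOE = {"left": BODY_25["left_big_toe"], "right": BODY_25["right_big_toe"]}
HEEL = {"left": BODY_25["left_heel"], "right": BODY_25["right_heel"]}

#: JSON field names of the OpenPose demo per-frame output.
POSE_FIELD = "pose_keypoints_2d"
HAND_LEFT_FIELD = "hand_left_keypoints_2d"
HAND_RIGHT_FIELD = "hand_right_keypoints_2d"

#: Frame-file naming convention of the OpenPose demo: 12-digit zero-padded
#: frame index followed by this suffix.
KEYPOINT_FILE_SUFFIX = "_keypoints.json"
FRAME_INDEX_DIGITS = 12
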