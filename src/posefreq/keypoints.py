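"""Reading OpenPose-dialect keypoint JSON into per-keypoint time series.

The OpenPose demo writes one JSON file per video frame.  Each file holds a
``"people"`` array; each person carries flat ``[x, y, confidence]`` triples
for the 25-keypoint body model (75 numbers) and the two 21-keypoint hand
models (63 numbers each).  This module validates that dialect, selects a
single person per frame, and stacks frames into :class:`TrajectorySet`
arrays that the rest of the pipeline operates on.

Coordinates are image coordinates: origin top-left, y increasing downward.
A keypoint whose confidence is at or below the missingness threshold is
flagged missing (OpenPose emits ``(0, 0, 0)`` for undetected keypoints).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import constants as C
from .errors import (
    InsufficientDataError,
    KeypointFormatError,
    KeypointParseError,
)

__all__ = [
    "KeypointFrame",
    "TrajectorySet",
    "read_openpose_frame",
    "assemble_trajectories",
    "read_openpose_directory",
]

#: Default confidence threshold: a keypoint with confidence <= this value is
#: treated as missing.  OpenPose reports confidence 0 for undetected points.
DEFAULT_CONFIDENCE_THRESHOLD = 0.0


@dataclass(frozen=True)
class KeypointFrame:
    """One frame's keypoints: body (25,3), left/right hand (21,3) arrays.

    Each row of the arrays is ``(x, y, confidence)``.  Missing keypoints are
    encoded as confidence 0 (the OpenPose convention); ``person_count`` is
    the number of people present in the source document before selection.
    """

    frame_index: int
    body: np.ndarray
    left_hand: np.ndarray
    right_hand: np.ndarray
    person_count: int

    def __post_init__(self) -> None:
        if self.body.shape != (C.N_BODY_KEYPOINTS, 3):
            raise KeypointFormatError(
                f"body keypoints must have shape (25, 3), got {self.body.shape}"
            )
        for name in ("left_hand", "right_hand"):
            arr = getattr(self, name)
            if arr.shape != (C.N_HAND_KEYPOINTS, 3):
                raise KeypointFormatError(
                    f"{name} keypoints must have shape (21, 3), got {arr.shape}"
                )

    @classmethod
    def empty(cls, frame_index: int) -> "KeypointFrame":
        """An all-missing frame (no person detected)."""
        return cls(
            frame_index=frame_index,
            body=np.zeros((C.N_BODY_KEYPOINTS, 3)),
            left_hand=np.zeros((C.N_HAND_KEYPOINTS, 3)),
            right_hand=np.zeros((C.N_HAND_KEYPOINTS, 3)),
            person_count=0,
        )


@dataclass
class TrajectorySet:
    """Per-keypoint time series for one trial.

    ``body``, ``left_hand`` and ``right_hand`` are float arrays of shape
    ``(n_frames, n_keypoints, 3)`` holding ``(x, y, confidence)``;
    the matching ``*_missing`` boolean arrays of shape
    ``(n_frames, n_keypoints)`` are true where the keypoint's confidence was
    at or below the missingness threshold (or its block was absent).
    """

    fps: float
    body: np.ndarray
    left_hand: np.ndarray
    right_hand: np.ndarray
    body_missing: np.ndarray
    left_hand_missing: np.ndarray
    right_hand_missing: np.ndarray
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.body.shape[0]

    @property
    def duration_s(self) -> float:
        """Trial span in seconds (time of last frame, first frame at t=0)."""
        return (self.n_frames - 1) / self.fps

    def series(self, group: str, index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(x, y, missing)`` series for one keypoint.

        ``group`` is one of ``"body"``, ``"left_hand"``, ``"right_hand"``.
        """
        arr = getattr(self, group)
        missing = getattr(self, f"{group}_missing")
        return arr[:, index, 0].copy(), arr[:, index, 1].copy(), missing[:, index].copy()


def _parse_triples(
    values: Sequence[float] | None, n_expected: int, what: str, source: str
) -> np.ndarray:
    if values is None:
        return np.zeros((n_expected, 3))
    n = len(values)
    if n % 3 != 0:
        raise KeypointFormatError(
            f"{source}: {what} array length {n} is not divisible by 3"
        )
    if n != 3 * n_expected:
        raise KeypointFormatError(
            f"{source}: {what} has {n} values, expected {3 * n_expected}"
        )
    return np.asarray(values, dtype=float).reshape(n_expected, 3)


def read_openpose_frame(
    document: str, frame_index: int, source: str = "<string>"
) -> KeypointFrame:
    """Parse one OpenPose per-frame JSON document into a :class:`KeypointFrame`.

    When the ``"people"`` array is empty every keypoint is missing.  When
    several people are present the person with the highest summed body
    confidence is selected (ties go to the lowest array index); the recording
    protocol assumes a single person in the field of view, so multi-person
    frames are handled only as a robustness measure.

    Parameters
    ----------
    document : str
        JSON text of one frame file.
    frame_index : int
        Frame number this document describes.
    source : str
        Name used in error messages (typically the file path).
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise KeypointParseError(f"{source}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "people" not in doc:
        raise KeypointFormatError(f"{source}: missing 'people' array")
    people = doc["people"]
    if not isinstance(people, list):
        raise KeypointFormatError(f"{source}: 'people' is not an array")
    if len(people) == 0:
        return KeypointFrame.empty(frame_index)

    parsed = []
    for i, person in enumerate(people):
        body = _parse_triples(
            person.get(C.POSE_FIELD), C.N_BODY_KEYPOINTS, C.POSE_FIELD, source
        )
        lhand = _parse_triples(
            person.get(C.HAND_LEFT_FIELD), C.N_HAND_KEYPOINTS, C.HAND_LEFT_FIELD, source
        )
        rhand = _parse_triples(
            person.get(C.HAND_RIGHT_FIELD), C.N_HAND_KEYPOINTS, C.HAND_RIGHT_FIELD, source
        )
        parsed.append((body[:, 2].sum(), i, body, lhand, rhand))

    # Highest summed body confidence wins; np.argmax-style lowest index on tie.
    best = max(parsed, key=lambda t: (t[0], -t[1]))
    _, _, body, lhand, rhand = best
    return KeypointFrame(
        frame_index=frame_index,
        body=body,
        left_hand=lhand,
        right_hand=rhand,
        person_count=len(people),
    )


def assemble_trajectories(
    frames: Iterable[KeypointFrame],
    fps: float,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    meta: dict | None = None,
) -> TrajectorySet:
    """Stack ordered :class:`KeypointFrame` objects into a :class:`TrajectorySet`.

    Frames must be ordered by ``frame_index`` with no duplicates; gaps in the
    numbering are inserted as all-missing frames, so the output always covers
    the contiguous range from the first to the last frame index.
    """
    frames = list(frames)
    if not frames:
        raise InsufficientDataError("no keypoint frames to assemble")
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    indices = [f.frame_index for f in frames]
    if len(set(indices)) != len(indices):
        raise KeypointFormatError("duplicate frame_index in input frames")
    if indices != sorted(indices):
        raise KeypointFormatError("frames are not ordered by frame_index")

    first, last = indices[0], indices[-1]
    n_frames = last - first + 1
    body = np.zeros((n_frames, C.N_BODY_KEYPOINTS, 3))
    lhand = np.zeros((n_frames, C.N_HAND_KEYPOINTS, 3))
    rhand = np.zeros((n_frames, C.N_HAND_KEYPOINTS, 3))
    for f in frames:
        k = f.frame_index - first
        body[k] = f.body
        lhand[k] = f.left_hand
        rhand[k] = f.right_hand

    thr = confidence_threshold
    return TrajectorySet(
        fps=float(fps),
        body=body,
        left_hand=lhand,
        right_hand=rhand,
        body_missing=body[:, :, 2] <= thr,
        left_hand_missing=lhand[:, :, 2] <= thr,
        right_hand_missing=rhand[:, :, 2] <= thr,
        confidence_threshold=thr,
        meta=dict(meta or {}),
    )


_FRAME_FILE_RE = re.compile(r"_(\d{%d})%s$" % (C.FRAME_INDEX_DIGITS, re.escape(C.KEYPOINT_FILE_SUFFIX)))


def read_openpose_directory(
    directory: str | Path,
    fps: float,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    meta: dict | None = None,
) -> TrajectorySet:
    """Read a directory of ``<prefix>_NNNNNNNNNNNN_keypoints.json`` files.

    Files are ordered by their 12-digit frame index (the OpenPose demo
    convention); missing frame numbers become all-missing frames.
    """
    directory = Path(directory)
    entries = []
    for path in sorted(directory.glob(f"*{C.KEYPOINT_FILE_SUFFIX}")):
        m = _FRAME_FILE_RE.search(path.name)
        if m is None:
            continue
        entries.append((int(m.group(1)), path))
    if not entries:
        raise InsufficientDataError(f"no keypoint files found in {directory}")
    entries.sort(key=lambda t: t[0])
    frames = [
        read_openpose_frame(path.read_text(), idx, source=str(path))
        for idx, path in entries
    ]
    return assemble_trajectories(
        frames, fps=fps, confidence_threshold=confidence_threshold, meta=meta
    )
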