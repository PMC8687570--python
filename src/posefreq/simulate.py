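"""Synthetic keypoint trials with known ground-truth event times.

The validation videos behind this workflow are not publicly deposited, so
the package ships a simulator that emulates their recording conditions:
~10 s trials at ~30 frames/s of the five repetitive tasks, performed at a
metronome-paced target frequency of 1-4 Hz, written in the exact OpenPose
per-frame JSON dialect the reader consumes.

Kinematics
----------
A static, plausible seated full-body pose (BODY_25 plus both 21-point
hands) is held for the whole trial; only the task keypoints move.  The task
signal is a train of raised-cosine movement cycles at the target frequency:

* finger_tapping / hand_open_close — the index fingertip moves toward the
  stationary thumb tip, closing a raised-cosine aperture each cycle; events
  (taps/closures) are the aperture minima.
* pronation_supination — the thumb tip oscillates vertically; each upward
  extreme (supination) and each downward extreme (pronation) is one event,
  so the vertical oscillation runs at half the target event rate.
* toe_tapping / leg_agility — the big-toe (or heel) keypoint descends to a
  ground line each cycle.  The waveform slightly overshoots the ground and
  is clamped there, producing a brief flat contact dwell (default 60 ms),
  as real taps do; the event is the first frame of ground contact.

On top of the clean kinematics the simulator adds seeded Gaussian pixel
noise to every coordinate and Bernoulli keypoint dropouts, encoded as
``(0, 0, 0)`` triples exactly as OpenPose reports undetected keypoints.
Optionally it plants spurious leading movements (false starts excluded from
the ground truth) and near-zero-amplitude trailing movements (counted in
the ground truth but too small for the detector) to exercise the
event-matching machinery.

All randomness flows from one ``numpy`` generator seeded per trial; the
same parameters and seed reproduce a trial bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np

from . import constants as C
from .errors import ParameterError
from .events import EventSeries, TASKS, SIDES
from .keypoints import KeypointFrame, TrajectorySet, assemble_trajectories

__all__ = [
    "SimulationParams",
    "SimulatedTrial",
    "simulate_task_trial",
    "write_openpose_json",
]

#: Default peak-to-peak movement amplitude per task, in pixels, at the
#: simulated camera distance (whole body in a portrait smartphone frame).
DEFAULT_AMPLITUDE_PX = {
    "finger_tapping": 80.0,
    "hand_open_close": 150.0,
    "pronation_supination": 120.0,
    "toe_tapping": 60.0,
    "leg_agility": 80.0,
}

#: Static seated pose: BODY_25 (x, y) in a 720x1280 portrait image.
STATIC_BODY_XY = np.array([
    [360.0, 300.0],   # nose
    [360.0, 380.0],   # neck
    [300.0, 390.0],   # right shoulder
    [285.0, 480.0],   # right elbow
    [280.0, 570.0],   # right wrist
    [420.0, 390.0],   # left shoulder
    [435.0, 480.0],   # left elbow
    [440.0, 570.0],   # left wrist
    [360.0, 640.0],   # mid hip
    [320.0, 640.0],   # right hip
    [310.0, 800.0],   # right knee
    [305.0, 960.0],   # right ankle
    [400.0, 640.0],   # left hip
    [410.0, 800.0],   # left knee
    [415.0, 960.0],   # left ankle
    [345.0, 290.0],   # right eye
    [375.0, 290.0],   # left eye
    [330.0, 300.0],   # right ear
    [390.0, 300.0],   # left ear
    [425.0, 1000.0],  # left big toe
    [440.0, 1000.0],  # left small toe
    [405.0, 985.0],   # left heel
    [295.0, 1000.0],  # right big toe
    [280.0, 1000.0],  # right small toe
    [315.0, 985.0],   # right heel
])

#: 21-point hand template, offsets from the wrist body keypoint (px).
HAND_TEMPLATE_XY = np.array([
    [0.0, 20.0],      # hand wrist
    [-10.0, 12.0], [-18.0, 4.0], [-24.0, -4.0], [-28.0, -10.0],      # thumb
    [-8.0, -10.0], [-10.0, -22.0], [-12.0, -32.0], [-14.0, -40.0],   # index
    [0.0, -12.0], [0.0, -26.0], [0.0, -37.0], [0.0, -46.0],          # middle
    [8.0, -10.0], [9.0, -23.0], [10.0, -33.0], [11.0, -41.0],        # ring
    [15.0, -6.0], [17.0, -16.0], [19.0, -24.0], [20.0, -30.0],       # pinky
])

GROUND_Y = 1000.0  # image y of the floor line the toe/heel strikes


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of one simulated trial.

    Defaults mirror the recording protocol the workflow was validated
    under: ~10 s self-recorded smartphone trials at ~30 frames/s, target
    frequencies of 1-4 Hz paced by a metronome.  ``noise_sd_px`` (2 px) and
    ``dropout_rate`` (5%) emulate pose-estimator jitter and detection
    failures.  With ``frame_aligned`` (default) the movement train is
    phase-shifted so the planted event times fall exactly on video frames.
    """

    task: str
    side: str = "right"
    frequency_hz: float = 2.0
    duration_s: float = 10.0
    fps: float = 30.0
    amplitude_px: float | None = None
    noise_sd_px: float = 2.0
    dropout_rate: float = 0.05
    spurious_events: int = 0
    missed_events: int = 0
    seed: int = 0
    frame_aligned: bool = True
    contact_dwell_s: float = 0.06
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ParameterError(f"unknown task {self.task!r}")
        if self.side not in SIDES:
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        if not 0 < self.frequency_hz < self.fps / 2:
            raise ParameterError(
                f"frequency {self.frequency_hz} Hz must lie in (0, Nyquist="
                f"{self.fps / 2} Hz)"
            )
        if self.duration_s <= 2.0 / self.frequency_hz:
            raise ParameterError("duration must exceed two movement periods")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.noise_sd_px < 0 or self.spurious_events < 0 or self.missed_events < 0:
            raise ParameterError("noise and injection counts must be nonnegative")

    @property
    def amplitude(self) -> float:
        return (
            self.amplitude_px
            if self.amplitude_px is not None
            else DEFAULT_AMPLITUDE_PX[self.task]
        )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass(frozen=True)
class SimulatedTrial:
    """Frames plus exact planted ground-truth events for one trial."""

    frames: list[KeypointFrame]
    truth: EventSeries
    params: SimulationParams

    def trajectories(self, confidence_threshold: float = 0.0) -> TrajectorySet:
        meta = {
            "trial_id": self.params.trial_id,
            "task": self.params.task,
            "side": self.params.side,
        }
        return assemble_trajectories(
            self.frames,
            fps=self.params.fps,
            confidence_threshold=confidence_threshold,
            meta=meta,
        )


def _cycle_layout(p: SimulationParams) -> tuple[np.ndarray, float, np.ndarray]:
    """Event times of every movement cycle, the frame-alignment shift, and
    the per-cycle amplitude scale (1 normally, 0.05 for planted misses)."""
    f = p.frequency_hz
    n_cycles = int(np.floor(p.duration_s * f + 1e-9))
    if p.spurious_events + p.missed_events >= n_cycles:
        raise ParameterError("spurious + missed events exceed available cycles")
    centers = (np.arange(n_cycles) + 0.5) / f
    delta = 0.0
    if p.frame_aligned:
        first = centers[0] * p.fps
        delta = (np.ceil(first - 1e-9) - first) / p.fps
    centers = centers + delta
    scale = np.ones(n_cycles)
    if p.missed_events:
        scale[n_cycles - p.missed_events:] = 0.05
    return centers, delta, scale


def _dip_train(
    t: np.ndarray, p: SimulationParams, delta: float, scale: np.ndarray
) -> np.ndarray:
    """Raised-cosine dip depth per frame: 0 at rest, amplitude at the event."""
    f = p.frequency_hz
    amp = p.amplitude
    tau = t - delta
    cycle = np.floor(tau * f + 1e-9).astype(int)
    in_train = (tau >= 0) & (cycle >= 0) & (cycle < scale.size)
    depth = np.zeros_like(t)
    k = cycle[in_train]
    phase = 2 * np.pi * f * (tau[in_train] - k / f)
    depth[in_train] = amp * scale[k] * (1 - np.cos(phase)) / 2
    return depth


def _contact_elevation(
    t: np.ndarray, p: SimulationParams, delta: float, scale: np.ndarray
) -> np.ndarray:
    """Elevation above ground for toe/heel tasks, with a contact dwell.

    Each full-amplitude cycle overshoots the ground line by the margin that
    makes contact last ``contact_dwell_s`` and is clamped at zero.
    """
    w = np.pi * p.frequency_hz * p.contact_dwell_s  # phase half-width of contact
    overshoot = 2.0 / (1.0 + np.cos(w)) - 1.0
    depth = _dip_train(t, p, delta, scale * (1 + overshoot))
    return np.maximum(p.amplitude - depth, 0.0)


def _pronation_elevation(
    t: np.ndarray, p: SimulationParams, delta: float, scale: np.ndarray
) -> np.ndarray:
    """Thumb-tip elevation for pronation/supination.

    Each *event* is a half oscillation, so the thumb oscillates at half the
    target event rate: up at even cycles (supination), down at odd
    (pronation).
    """
    f = p.frequency_hz
    tau = t - delta
    cycle = np.floor(tau * f + 1e-9).astype(int)
    in_train = (tau >= 0) & (cycle >= 0) & (cycle < scale.size)
    elev = np.zeros_like(t)
    k = cycle[in_train]
    elev[in_train] = (p.amplitude / 2) * scale[k] * np.sin(np.pi * f * tau[in_train])
    return elev


def _truth_from_cycles(
    p: SimulationParams, centers: np.ndarray
) -> EventSeries:
    """Ground-truth event frames for the non-spurious cycles."""
    idx = np.arange(centers.size)
    keep = idx >= p.spurious_events
    kept_idx = idx[keep]
    kept_centers = centers[keep]
    if p.task in ("toe_tapping", "leg_agility"):
        # first frame of ground contact
        frames = np.ceil((kept_centers - p.contact_dwell_s / 2) * p.fps - 1e-9)
    else:
        frames = np.rint(kept_centers * p.fps)
    frames = frames.astype(int)
    labels: tuple[str, ...] = ()
    if p.task == "pronation_supination":
        labels = tuple(
            "supination" if k % 2 == 0 else "pronation" for k in kept_idx
        )
    return EventSeries(method="truth", frames=frames, fps=p.fps, labels=labels)


def simulate_task_trial(params: SimulationParams) -> SimulatedTrial:
    """Generate one synthetic trial of keypoint frames with known events."""
    p = params
    rng = np.random.default_rng(p.seed)
    t = np.arange(p.n_frames) / p.fps
    centers, delta, scale = _cycle_layout(p)

    body = np.broadcast_to(STATIC_BODY_XY, (p.n_frames, 25, 2)).copy()
    hands = {}
    for side in SIDES:
        w = STATIC_BODY_XY[C.BODY_25[f"{side}_wrist"]]
        template = HAND_TEMPLATE_XY.copy()
        if side == "left":
            template = template * np.array([-1.0, 1.0])  # mirror thumb side
        hands[side] = np.broadcast_to(w + template, (p.n_frames, 21, 2)).copy()

    task_hand = hands[p.side]
    if p.task in ("finger_tapping", "hand_open_close"):
        depth = _dip_train(t, p, delta, scale)
        aperture = p.amplitude - depth  # open at rest, closed at the tap
        thumb = task_hand[:, C.HAND["thumb_tip"], :]
        task_hand[:, C.HAND["index_tip"], 0] = thumb[:, 0]
        task_hand[:, C.HAND["index_tip"], 1] = thumb[:, 1] - aperture
    elif p.task == "pronation_supination":
        elev = _pronation_elevation(t, p, delta, scale)
        rest_y = task_hand[0, C.HAND["thumb_tip"], 1]
        task_hand[:, C.HAND["thumb_tip"], 1] = rest_y - elev
    else:
        elev = _contact_elevation(t, p, delta, scale)
        if p.task == "toe_tapping":
            moving = [C.BIG_TOE[p.side]]
        else:
            # the whole foot lifts for a heel strike
            moving = [C.HEEL[p.side], C.BIG_TOE[p.side]]
        for idx in moving:
            body[:, idx, 1] = GROUND_Y - elev

    # pose-estimator pixel jitter on every coordinate
    if p.noise_sd_px > 0:
        body += rng.normal(0, p.noise_sd_px, body.shape)
        for side in SIDES:
            hands[side] += rng.normal(0, p.noise_sd_px, hands[side].shape)

    conf_body = rng.uniform(0.5, 0.95, (p.n_frames, 25))
    conf_hands = {s: rng.uniform(0.5, 0.95, (p.n_frames, 21)) for s in SIDES}
    if p.dropout_rate > 0:
        conf_body[rng.random((p.n_frames, 25)) < p.dropout_rate] = 0.0
        for s in SIDES:
            conf_hands[s][rng.random((p.n_frames, 21)) < p.dropout_rate] = 0.0

    frames = []
    for i in range(p.n_frames):
        def triples(xy: np.ndarray, conf: np.ndarray) -> np.ndarray:
            out = np.column_stack([xy, conf])
            out[conf <= 0.0] = 0.0  # undetected keypoints serialize as zeros
            return out

        frames.append(
            KeypointFrame(
                frame_index=i,
                body=triples(body[i], conf_body[i]),
                left_hand=triples(hands["left"][i], conf_hands["left"][i]),
                right_hand=triples(hands["right"][i], conf_hands["right"][i]),
                person_count=1,
            )
        )

    truth = _truth_from_cycles(p, centers)
    return SimulatedTrial(frames=frames, truth=truth, params=p)


def write_openpose_json(trial: SimulatedTrial, directory: str | Path,
                        prefix: str | None = None) -> list[Path]:
    """Write a trial as one OpenPose-dialect JSON file per frame.

    File names follow the OpenPose demo convention
    ``<prefix>_NNNNNNNNNNNN_keypoints.json`` with a 12-digit zero-padded
    frame index; floats are serialized at full precision so a read-back
    reproduces the trajectories exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = prefix or (trial.params.trial_id or "trial")
    paths = []
    for frame in trial.frames:
        doc = {
            "version": 1.3,
            "people": [
                {
                    C.POSE_FIELD: [float(v) for v in frame.body.ravel()],
                    C.HAND_LEFT_FIELD: [float(v) for v in frame.left_hand.ravel()],
                    C.HAND_RIGHT_FIELD: [float(v) for v in frame.right_hand.ravel()],
                }
            ],
        }
        name = f"{prefix}_{frame.frame_index:0{C.FRAME_INDEX_DIGITS}d}{C.KEYPOINT_FILE_SUFFIX}"
        path = directory / name
        path.write_text(json.dumps(doc))
        paths.append(path)
    return paths
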