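"""Task signals, movement-event detection, and frequency estimation.

Each repetitive-movement task reduces the keypoint trajectories to one
scalar signal per trial, and movement events are extrema of that signal:

======================  =============================================  =========
task                    signal                                         events
======================  =============================================  =========
finger_tapping          thumb-tip to index-tip distance (px)           minima
hand_open_close         thumb-tip to index-tip distance (px)           minima
pronation_supination    thumb-tip elevation (-y, px)                   maxima (supination) and minima (pronation)
toe_tapping             big-toe elevation (-y, px)                     minima
leg_agility             heel elevation (-y, px)                        minima
======================  =============================================  =========

Elevation is the negated image-y coordinate, so physically downward contact
events (toe or heel striking the ground) are signal minima and the code
reads like the task description.  Movement frequency is the event rate over
the first-to-last-event span, ``(n_events - 1) / span`` — unbiased for
periodic events and insensitive to idle frames before and after the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import signal as sps

from . import constants as C
from .errors import InsufficientDataError, ParameterError, TaskConfigError
from .keypoints import TrajectorySet

__all__ = [
    "TASKS",
    "TaskSpec",
    "TaskSignal",
    "EventSeries",
    "FrequencyResult",
    "PeakParams",
    "task_spec",
    "build_task_signal",
    "detect_events",
    "movement_frequency",
]

SIDES = ("left", "right")

#: polarity of the extrema that constitute events, per task
_TASK_POLARITY = {
    "finger_tapping": "minima",
    "hand_open_close": "minima",
    "pronation_supination": "both",
    "toe_tapping": "minima",
    "leg_agility": "minima",
}
TASKS = tuple(_TASK_POLARITY)


@dataclass(frozen=True)
class TaskSpec:
    """Which keypoints, reduction and event polarity define one task."""

    task: str
    side: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ParameterError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.side not in SIDES:
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def polarity(self) -> str:
        return _TASK_POLARITY[self.task]

    @property
    def is_hand_aperture(self) -> bool:
        return self.task in ("finger_tapping", "hand_open_close")


def task_spec(task: str, side: str) -> TaskSpec:
    return TaskSpec(task=task, side=side)


@dataclass(frozen=True)
class TaskSignal:
    """The scalar per-trial signal event detection operates on.

    ``values`` is in pixels: a nonnegative aperture distance for the hand
    tasks, or an elevation (negated image-y) for the vertical tasks.
    """

    values: np.ndarray
    fps: float
    spec: TaskSpec
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EventSeries:
    """Ordered event times for one trial from one method (pose or manual).

    ``frames`` are integer video frames, ``times`` their equivalents in
    seconds (``frame / fps``); ``labels`` distinguish pronation from
    supination where applicable and are empty strings otherwise.
    """

    method: str
    frames: np.ndarray
    fps: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        object.__setattr__(self, "frames", frames)
        if frames.size and np.any(np.diff(frames) <= 0):
            raise ValueError("event frames must be strictly increasing")
        if self.labels and len(self.labels) != frames.size:
            raise ValueError("labels must match number of events")

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.fps

    @property
    def n_events(self) -> int:
        return int(self.frames.size)


@dataclass(frozen=True)
class FrequencyResult:
    """Event count, first-to-last span and the implied movement frequency."""

    n_events: int
    span_s: float
    frequency_hz: float


def _hand_group(side: str) -> str:
    return "left_hand" if side == "left" else "right_hand"


def _require_observed(missing: np.ndarray, what: str) -> None:
    if (~missing).sum() < 2:
        raise TaskConfigError(
            f"keypoint {what} has fewer than 2 observed frames; "
            "cannot build task signal"
        )


def build_task_signal(traj: TrajectorySet, spec: TaskSpec) -> TaskSignal:
    """Reduce preprocessed trajectories to the task's scalar signal.

    For the hand-aperture tasks the signal is the Euclidean thumb-tip to
    index-tip distance; for the vertical tasks it is the elevation (-y) of
    the task keypoint.  Trajectories should already be gap-filled and
    filtered (:func:`posefreq.preprocessing.preprocess`).
    """
    if spec.is_hand_aperture:
        group = _hand_group(spec.side)
        tx, ty, tmiss = traj.series(group, C.HAND["thumb_tip"])
        ix, iy, imiss = traj.series(group, C.HAND["index_tip"])
        _require_observed(tmiss, f"{group}:thumb_tip")
        _require_observed(imiss, f"{group}:index_tip")
        values = np.hypot(tx - ix, ty - iy)
    elif spec.task == "pronation_supination":
        group = _hand_group(spec.side)
        _, y, miss = traj.series(group, C.HAND["thumb_tip"])
        _require_observed(miss, f"{group}:thumb_tip")
        values = -y
    else:
        index = (C.BIG_TOE if spec.task == "toe_tapping" else C.HEEL)[spec.side]
        _, y, miss = traj.series("body", index)
        _require_observed(miss, f"body[{index}]")
        values = -y
    return TaskSignal(values=values, fps=traj.fps, spec=spec, meta=dict(traj.meta))


@dataclass(frozen=True)
class PeakParams:
    """Peak-detection settings for :func:`detect_events`.

    ``min_separation_s`` — minimum spacing between same-polarity events; when
    None it is set adaptively to half the dominant period of the
    mean-subtracted signal (periodogram argmax), floored at 0.1 s.
    ``prominence_frac`` — minimum peak prominence as a fraction of the
    signal's 10th-90th percentile range, making detection invariant to the
    pixel scale of the recording.
    """

    min_separation_s: float | None = None
    prominence_frac: float = 0.2
    separation_floor_s: float = 0.1


def _dominant_period_s(values: np.ndarray, fps: float) -> float | None:
    x = values - values.mean()
    if not np.any(x):
        return None
    freqs, power = sps.periodogram(x, fs=fps)
    power[0] = 0.0
    k = int(np.argmax(power))
    if power[k] <= 0 or freqs[k] <= 0:
        return None
    return 1.0 / freqs[k]


def _find_extrema(
    values: np.ndarray, distance: int, prominence: float
) -> np.ndarray:
    """Indices of maxima; plateaus report their earliest frame."""
    peaks, props = sps.find_peaks(
        values,
        distance=max(distance, 1),
        prominence=prominence,
        plateau_size=(1, None),
    )
    return props["left_edges"].astype(int)


def detect_events(
    signal: TaskSignal, params: PeakParams | None = None, method: str = "pose"
) -> EventSeries:
    """Detect movement events as extrema of the task signal.

    Events are the local extrema of the polarity the task prescribes
    (minima for taps/closures, both for pronation-supination), reported at
    integer frame resolution — matching frame-by-frame manual inspection.
    A flat signal yields an empty series.  For ``polarity="both"`` the
    minima and maxima must interleave; where noise produces two consecutive
    same-polarity extrema, the less extreme one is dropped.
    """
    if params is None:
        params = PeakParams()
    values = np.asarray(signal.values, dtype=float)
    polarity = signal.spec.polarity

    p10, p90 = np.percentile(values, [10, 90])
    vrange = p90 - p10
    if vrange <= 0:
        return EventSeries(method=method, frames=np.array([], dtype=int), fps=signal.fps)
    prominence = params.prominence_frac * vrange

    sep_s = params.min_separation_s
    if sep_s is None:
        period = _dominant_period_s(values, signal.fps)
        sep_s = max(0.5 * period if period else params.separation_floor_s,
                    params.separation_floor_s)
    distance = int(round(sep_s * signal.fps))

    frames_list: list[tuple[int, str]] = []
    if polarity in ("minima", "both"):
        for f in _find_extrema(-values, distance, prominence):
            frames_list.append((int(f), "pronation" if polarity == "both" else ""))
    if polarity in ("maxima", "both"):
        for f in _find_extrema(values, distance, prominence):
            frames_list.append((int(f), "supination" if polarity == "both" else ""))
    frames_list.sort()

    if polarity == "both":
        frames_list = _enforce_alternation(frames_list, values)

    frames = np.array([f for f, _ in frames_list], dtype=int)
    labels = tuple(lab for _, lab in frames_list) if polarity == "both" else ()
    return EventSeries(method=method, frames=frames, fps=signal.fps, labels=labels)


def _enforce_alternation(
    frames_list: list[tuple[int, str]], values: np.ndarray
) -> list[tuple[int, str]]:
    """Drop the less extreme of any two consecutive same-label events."""
    out: list[tuple[int, str]] = []
    for frame, label in frames_list:
        if out and out[-1][1] == label:
            prev_frame = out[-1][0]
            # keep the deeper minimum / higher maximum
            if label == "pronation":
                keep_new = values[frame] < values[prev_frame]
            else:
                keep_new = values[frame] > values[prev_frame]
            if keep_new:
                out[-1] = (frame, label)
            continue
        out.append((frame, label))
    return out


def movement_frequency(
    events: EventSeries, estimator: str = "span"
) -> FrequencyResult:
    """Movement frequency from detected event times.

    The default ``"span"`` estimator is the event rate over the
    first-to-last-event interval, ``(n - 1) / (t_last - t_first)``.  The
    alternative ``"mean_rate"`` estimator averages the inverse inter-event
    intervals; it weights local rate fluctuations more heavily.
    """
    n = events.n_events
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 events to estimate a frequency, got {n}"
        )
    times = events.times
    span = float(times[-1] - times[0])
    if estimator == "span":
        freq = (n - 1) / span
    elif estimator == "mean_rate":
        freq = float(np.mean(1.0 / np.diff(times)))
    else:
        raise ParameterError(f"unknown frequency estimator {estimator!r}")
    return FrequencyResult(n_events=n, span_s=span, frequency_hz=freq)
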