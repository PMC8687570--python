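"""End-to-end convenience wrapper: trajectories -> events -> frequency.

This is the three-step workflow the package exists for — gap-fill and
filter the keypoint trajectories, reduce them to the task signal, detect
movement events, and estimate the movement frequency — bundled so the CLI,
tests and scripts all run exactly the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import (
    EventSeries,
    FrequencyResult,
    PeakParams,
    TaskSignal,
    build_task_signal,
    detect_events,
    movement_frequency,
    task_spec,
)
from .keypoints import TrajectorySet
from .preprocessing import FilterParams, preprocess

__all__ = ["TrialResult", "analyze_trajectories"]


@dataclass(frozen=True)
class TrialResult:
    """Everything one trial analysis produces."""

    signal: TaskSignal
    events: EventSeries
    frequency: FrequencyResult | None


def analyze_trajectories(
    traj: TrajectorySet,
    task: str,
    side: str,
    cutoff_hz: float = 5.0,
    filter_convention: str = "effective",
    peak_params: PeakParams | None = None,
) -> TrialResult:
    """Run preprocessing, event detection and frequency estimation.

    ``frequency`` is None when fewer than two events were detected.
    """
    params = FilterParams(
        fps=traj.fps, cutoff_hz=cutoff_hz, convention=filter_convention
    )
    clean = preprocess(traj, params)
    signal = build_task_signal(clean, task_spec(task, side))
    events = detect_events(signal, peak_params)
    freq = movement_frequency(events) if events.n_events >= 2 else None
    return TrialResult(signal=signal, events=events, frequency=freq)
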