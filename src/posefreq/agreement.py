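"""Matching pose-detected events to manual events and agreement statistics.

Validation compares event times detected from keypoint trajectories against
a manual frame-by-frame ground truth.  Because either method can detect a
few extra events (typically at the trial boundaries), the two series are
first brought to a common set of matched pairs:

* While the counts differ, the event in the longer series whose
  nearest-neighbour distance to the other series is largest is discarded
  (recomputing distances after every removal; ties go to the earliest such
  event).  Once counts are equal, the i-th events are paired.
* If, after equal counts, the first and last pairs are both separated by
  more than the unmatched-gap threshold and shifted the same way — one
  method saw an extra event at the start of the trial and the other an
  extra event at the end — both unmatched boundary events are discarded and
  the series re-paired.

The unmatched-gap threshold is half the median inter-event interval of the
manual series: unit-free, and it separates "same physical event seen by
both" from "event seen by only one method" at any movement frequency.

On the matched pairs the module reports the per-event time errors
(manual − pose), the Pearson correlation r, and single-rater intraclass
correlations: ICC(C,1) (two-way mixed, consistency) and ICC(A,1) (two-way
random, absolute agreement), with F-test p-values, from the standard
two-way ANOVA mean-squares decomposition of the n×2 (events × methods)
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .events import EventSeries

__all__ = [
    "MatchResult",
    "AgreementStats",
    "match_events",
    "event_time_errors",
    "agreement_statistics",
]


@dataclass(frozen=True)
class MatchResult:
    """Order-preserving pairing of pose and manual event times (seconds)."""

    pairs: np.ndarray  # shape (n_pairs, 2): [:, 0] pose, [:, 1] manual
    discarded_pose: np.ndarray
    discarded_manual: np.ndarray
    n_pose: int
    n_manual: int

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])

    @property
    def t_pose(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def t_manual(self) -> np.ndarray:
        return self.pairs[:, 1]


@dataclass(frozen=True)
class AgreementStats:
    """Event-time error distribution and agreement coefficients for one trial."""

    errors_s: np.ndarray  # manual - pose, per pair
    mean_error_s: float
    sd_error_s: float
    r: float
    p_r: float
    icc_c1: float
    p_c1: float
    icc_a1: float
    p_a1: float
    n_pairs: int
    degenerate: bool = False


def _greedy_equalize(
    pose: np.ndarray, manual: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[float], list[float]]:
    """Discard from the longer series until counts match.

    One event at a time: the event of the longer series most dissimilar to
    any event of the shorter series is removed, recomputing nearest-
    neighbour distances after each removal.  Ties break to the earliest
    event.
    """
    pose = list(pose)
    manual = list(manual)
    dropped_pose: list[float] = []
    dropped_manual: list[float] = []
    while len(pose) != len(manual):
        longer, shorter = (pose, manual) if len(pose) > len(manual) else (manual, pose)
        ref = np.asarray(shorter)
        dists = [np.min(np.abs(ref - t)) for t in longer]
        worst = int(np.argmax(dists))  # argmax takes the earliest on ties
        removed = longer.pop(worst)
        (dropped_pose if longer is pose else dropped_manual).append(removed)
    return np.asarray(pose), np.asarray(manual), dropped_pose, dropped_manual


def _unmatched_gap_threshold(manual: np.ndarray) -> float:
    if manual.size < 2:
        return np.inf
    return 0.5 * float(np.median(np.diff(manual)))


def match_events(
    pose: EventSeries | np.ndarray,
    manual: EventSeries | np.ndarray,
    end_shift: bool = True,
) -> MatchResult:
    """Match two event series into order-preserving pairs.

    ``pose`` and ``manual`` may be :class:`~posefreq.events.EventSeries`
    objects or plain arrays of event times in seconds.  ``end_shift``
    enables the equal-count boundary rule described in the module docstring.
    """
    t_pose = np.asarray(pose.times if isinstance(pose, EventSeries) else pose, dtype=float)
    t_manual = np.asarray(
        manual.times if isinstance(manual, EventSeries) else manual, dtype=float
    )
    if t_pose.size == 0 or t_manual.size == 0:
        raise InsufficientDataError("cannot match an empty event series")
    for name, t in (("pose", t_pose), ("manual", t_manual)):
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{name} event times must be strictly increasing")
    n_pose, n_manual = t_pose.size, t_manual.size

    p, m, dropped_pose, dropped_manual = _greedy_equalize(t_pose, t_manual)

    if end_shift and p.size >= 2:
        thr = _unmatched_gap_threshold(m)
        d_first = m[0] - p[0]
        d_last = m[-1] - p[-1]
        if abs(d_first) > thr and abs(d_last) > thr and d_first * d_last > 0:
            if d_first > 0:
                # pose has an extra leading event, manual an extra trailing one
                dropped_pose.append(p[0])
                dropped_manual.append(m[-1])
                p, m = p[1:], m[:-1]
            else:
                dropped_manual.append(m[0])
                dropped_pose.append(p[-1])
                p, m = p[:-1], m[1:]

    pairs = np.column_stack([p, m]) if p.size else np.empty((0, 2))
    return MatchResult(
        pairs=pairs,
        discarded_pose=np.asarray(sorted(dropped_pose)),
        discarded_manual=np.asarray(sorted(dropped_manual)),
        n_pose=n_pose,
        n_manual=n_manual,
    )


def event_time_errors(
    match: MatchResult, fps: float | None = None
) -> dict[str, np.ndarray | float]:
    """Per-pair event-time errors, manual minus pose.

    Returns the error series in seconds (and in frames when ``fps`` is
    given) together with its mean and standard deviation.
    """
    if match.n_pairs == 0:
        raise InsufficientDataError("no matched pairs; cannot compute errors")
    errors = match.t_manual - match.t_pose
    out: dict[str, np.ndarray | float] = {
        "errors_s": errors,
        "mean_s": float(errors.mean()),
        "sd_s": float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
    }
    if fps is not None:
        out["errors_frames"] = errors * fps
        out["mean_frames"] = float(errors.mean() * fps)
    return out


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of an n×k two-way table, one obs/cell."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_err)


def icc_from_table(table: np.ndarray) -> dict[str, float]:
    """Single-rater ICCs of an n×k table from two-way ANOVA mean squares.

    ICC(C,1), consistency, two-way mixed:
        (MS_R − MS_E) / (MS_R + (k−1)·MS_E)
    ICC(A,1), absolute agreement, two-way random:
        (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

    p-values test ICC > 0 with F = MS_R / MS_E on (n−1, (n−1)(k−1)) df.
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    if n < 3:
        raise InsufficientDataError(f"need >= 3 rows for ICC, got {n}")
    ms_r, ms_c, ms_e = _two_way_mean_squares(table)
    denom_c = ms_r + (k - 1) * ms_e
    denom_a = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    icc_c = (ms_r - ms_e) / denom_c if denom_c != 0 else np.nan
    icc_a = (ms_r - ms_e) / denom_a if denom_a != 0 else np.nan
    if ms_e > 0:
        f_stat = ms_r / ms_e
        p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    else:
        # zero residual variance: perfect consistency
        p = 0.0 if ms_r > 0 else np.nan
    return {"icc_c1": float(icc_c), "icc_a1": float(icc_a), "p_c1": p, "p_a1": p}


def agreement_statistics(match: MatchResult) -> AgreementStats:
    """Pearson r and ICCs between matched pose and manual event times."""
    if match.n_pairs < 3:
        raise InsufficientDataError(
            f"need >= 3 matched pairs for agreement statistics, got {match.n_pairs}"
        )
    t_pose, t_manual = match.t_pose, match.t_manual
    errors = t_manual - t_pose

    degenerate = np.std(t_pose) == 0 or np.std(t_manual) == 0
    if degenerate:
        r, p_r = np.nan, np.nan
    elif np.array_equal(t_pose, t_manual):
        # pearsonr warns on exactly-equal inputs; the limit is exact
        r, p_r = 1.0, 0.0
    else:
        res = stats.pearsonr(t_pose, t_manual)
        r, p_r = float(res.statistic), float(res.pvalue)

    icc = icc_from_table(match.pairs)
    return AgreementStats(
        errors_s=errors,
        mean_error_s=float(errors.mean()),
        sd_error_s=float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
        r=r,
        p_r=p_r,
        icc_c1=icc["icc_c1"],
        p_c1=icc["p_c1"],
        icc_a1=icc["icc_a1"],
        p_a1=icc["p_a1"],
        n_pairs=match.n_pairs,
        degenerate=bool(degenerate),
    )
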