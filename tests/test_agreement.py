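import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import exhaustive_min_pairing_cost, icc_sums_of_squares, match_case
from posefreq import (
    SimulationParams,
    agreement_statistics,
    analyze_trajectories,
    event_time_errors,
    match_events,
    simulate_task_trial,
)
from posefreq.agreement import icc_from_table
from posefreq.errors import InsufficientDataError


class TestMatchEvents:
    def test_identical_series_all_paired(self):
        t = np.array([0.5, 1.0, 1.5, 2.0])
        m = match_events(t, t.copy())
        assert m.n_pairs == 4
        assert m.discarded_pose.size == 0 and m.discarded_manual.size == 0
        assert np.array_equal(m.t_pose, m.t_manual)

    def test_extra_leading_pose_event_discarded(self):
        m = match_events(np.array([0.10, 1.00, 2.00]), np.array([1.02, 1.98]))
        assert m.discarded_pose.tolist() == [0.10]
        assert np.allclose(m.pairs, [[1.00, 1.02], [2.00, 1.98]])

    def test_both_ends_case_discards_two_boundary_events(self):
        m = match_events(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        assert m.discarded_pose.tolist() == [0.0]
        assert m.discarded_manual.tolist() == [3.0]
        assert np.allclose(m.pairs, [[1.0, 1.0], [2.0, 2.0]])

    def test_both_ends_case_reversed_direction(self):
        m = match_events(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))
        assert m.discarded_pose.tolist() == [3.0]
        assert m.discarded_manual.tolist() == [0.0]

    def test_empty_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            match_events(np.array([]), np.array([1.0]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_no_crossings(self, seed):
        rng = np.random.default_rng(seed)
        pose, manual = match_case(rng)
        pose, manual = np.unique(pose), np.unique(manual)
        m = match_events(pose, manual)
        assert m.n_pairs + m.discarded_pose.size == m.n_pose
        assert m.n_pairs + m.discarded_manual.size == m.n_manual
        assert m.n_pairs <= min(m.n_pose, m.n_manual)
        # order-preserving: both pair columns strictly increasing
        if m.n_pairs > 1:
            assert np.all(np.diff(m.t_pose) > 0)
            assert np.all(np.diff(m.t_manual) > 0)
        # every event accounted for exactly once
        assert np.allclose(np.sort(np.r_[m.t_pose, m.discarded_pose]), pose)
        assert np.allclose(np.sort(np.r_[m.t_manual, m.discarded_manual]), manual)

    def test_greedy_matches_exhaustive_on_boundary_extras(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            pose, manual = match_case(rng)
            if abs(len(pose) - len(manual)) > 2:
                continue
            m = match_events(pose, manual, end_shift=False)
            got = float(np.abs(m.t_pose - m.t_manual).sum())
            assert got == pytest.approx(
                exhaustive_min_pairing_cost(pose, manual), abs=1e-9
            )

    def test_planted_spurious_leading_event_is_discarded(self):
        params = SimulationParams(
            task="finger_tapping", frequency_hz=2.0, seed=21, spurious_events=1
        )
        trial = simulate_task_trial(params)
        res = analyze_trajectories(trial.trajectories(), "finger_tapping", "right")
        m = match_events(res.events, trial.truth)
        assert m.discarded_manual.size == 0
        assert m.discarded_pose.size == 1
        # the discarded detection is the false start before the first true event
        assert m.discarded_pose[0] < trial.truth.times[0]


class TestEventTimeErrors:
    def test_identical_times_zero_errors(self):
        m = match_events(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        out = event_time_errors(m, fps=30.0)
        assert np.allclose(out["errors_s"], 0.0)
        assert out["mean_s"] == 0.0

    def test_constant_one_frame_shift(self):
        pose = np.array([1.0, 2.0, 3.0])
        m = match_events(pose, pose + 1 / 30)
        out = event_time_errors(m, fps=30.0)
        assert np.allclose(out["errors_s"], 1 / 30)
        assert np.allclose(out["errors_frames"], 1.0)

    def test_simulated_detection_jitter_stays_within_two_frames(self, rng):
        # pose = manual + ±1 frame of jitter, the error scale the method attains
        manual = 0.5 + np.arange(20) * 0.5
        pose = manual + rng.integers(-1, 2, manual.size) / 30.0
        out = event_time_errors(match_events(pose, manual), fps=30.0)
        assert np.mean(np.abs(out["errors_frames"])) <= 2.0


class TestAgreementStatistics:
    def test_identity_gives_ceiling_values(self):
        t = 0.5 + np.arange(10) * 0.5
        stats = agreement_statistics(match_events(t, t.copy()))
        assert stats.r == pytest.approx(1.0)
        assert stats.icc_c1 == pytest.approx(1.0)
        assert stats.icc_a1 == pytest.approx(1.0)
        assert stats.p_r < 0.001 and stats.p_c1 < 0.001

    def test_constant_offset_degrades_agreement_not_consistency(self):
        # end_shift off: a half-second offset with half-second event spacing
        # would otherwise legitimately trigger the boundary-discard rule
        t = 0.5 + np.arange(10) * 0.5
        stats = agreement_statistics(match_events(t, t + 0.5, end_shift=False))
        assert stats.r == pytest.approx(1.0)
        assert stats.icc_c1 == pytest.approx(1.0)
        assert stats.icc_a1 < 1.0

    def test_icc_matches_sums_of_squares_oracle(self, rng):
        for _ in range(50):
            table = rng.normal(5, 2, size=(int(rng.integers(3, 30)), 2))
            got = icc_from_table(table)
            want_c, want_a = icc_sums_of_squares(table)
            assert got["icc_c1"] == pytest.approx(want_c, abs=1e-10)
            assert got["icc_a1"] == pytest.approx(want_a, abs=1e-10)

    def test_icc_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        table = rng.normal(10, 3, size=(12, 2))
        df = pd.DataFrame(
            {
                "target": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": table.ravel(),
            }
        )
        res = pingouin.intraclass_corr(
            df, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
        got = icc_from_table(table)
        assert got["icc_a1"] == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-8)
        assert got["icc_c1"] == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-8)
        assert got["p_c1"] == pytest.approx(res.loc["ICC(C,1)", "pval"], abs=1e-8)

    def test_consistency_invariant_to_offset_agreement_decreasing(self, rng):
        t = 0.5 + np.arange(15) * 0.4 + rng.normal(0, 0.01, 15)
        base_c = agreement_statistics(match_events(t, t + 0.0)).icc_c1
        prev_a = np.inf
        for offset in (0.02, 0.05, 0.1, 0.15):
            stats = agreement_statistics(match_events(t, t + offset))
            assert stats.icc_c1 == pytest.approx(base_c, abs=1e-9)
            assert stats.icc_a1 < prev_a
            prev_a = stats.icc_a1

    def test_too_few_pairs_raises(self):
        m = match_events(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(InsufficientDataError):
            agreement_statistics(m)

    def test_degenerate_variance_flagged(self):
        pairs = np.column_stack([np.full(5, 2.0), np.arange(5.0)])
        from posefreq.agreement import MatchResult

        m = MatchResult(pairs=pairs, discarded_pose=np.array([]),
                        discarded_manual=np.array([]), n_pose=5, n_manual=5)
        stats = agreement_statistics(m)
        assert stats.degenerate
        assert np.isnan(stats.r)
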