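"""Operant event-log metrics: counts, intervals, bursts, extinction, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfstim import (
    AgentSpec,
    EventLog,
    InputError,
    OperantSessionModel,
    count_pokes,
    cumulative_curve,
    detect_bursts,
    exclusion_qc,
    extinction_metrics,
    interpoke_intervals,
    simulate_operant_session,
)


def make_log(active=(), inactive=(), duration=1800.0, lockout=0.0,
             laser_paired=True, sid="s"):
    events = sorted([(t, "active") for t in active]
                    + [(t, "inactive") for t in inactive])
    return EventLog(sid, duration, tuple(events),
                    laser_duration=max(lockout, 1e-9),
                    laser_paired=laser_paired)


def brute_force_bursts(times, gap, min_pokes=2):
    """Oracle: test every contiguous subsequence for the burst property
    and maximality."""
    times = list(times)
    out = []
    n = len(times)
    for i in range(n):
        for j in range(i + min_pokes - 1, n):
            gaps = [times[k + 1] - times[k] for k in range(i, j)]
            internal_ok = all(g < gap for g in gaps)
            left_max = i == 0 or times[i] - times[i - 1] >= gap
            right_max = j == n - 1 or times[j + 1] - times[j] >= gap
            if internal_ok and left_max and right_max:
                out.append((times[i], times[j], j - i + 1))
    return out


class TestLogAndCounts:
    def test_empty_log(self):
        log = make_log()
        assert count_pokes(log) == (0, 0)
        assert log.n_events == 0

    def test_direct_count(self):
        log = make_log(active=[1, 3], inactive=[2])
        assert count_pokes(log) == (2, 1)

    def test_lockout_violation_rejected(self):
        with pytest.raises(InputError):
            make_log(active=[1.0, 1.5], lockout=1.0)

    def test_simultaneous_events_rejected(self):
        with pytest.raises(InputError):
            make_log(active=[1.0], inactive=[1.0])

    def test_unknown_side_rejected(self):
        with pytest.raises(InputError):
            EventLog("s", 100.0, ((1.0, "left"),))

    def test_counts_match_simulator_tally(self):
        log, truth = simulate_operant_session(AgentSpec(), seed=8)
        assert count_pokes(log) == (truth["n_active"], truth["n_inactive"])


class TestIntervals:
    def test_direct_intervals(self):
        log = make_log(active=[10, 12, 15])
        intervals, mean = interpoke_intervals(log, "active")
        np.testing.assert_allclose(intervals, [2, 3])
        assert mean == pytest.approx(2.5)

    def test_single_event_mean_absent(self):
        log = make_log(active=[10])
        intervals, mean = interpoke_intervals(log, "active")
        assert intervals.size == 0
        assert mean is None

    def test_random_logs_match_pairwise_oracle(self, rng):
        times = np.unique(np.round(rng.uniform(0, 1700, 60), 3))
        log = make_log(active=times)
        intervals, _ = interpoke_intervals(log, "active")
        expected = [times[i + 1] - times[i] for i in range(len(times) - 1)]
        np.testing.assert_allclose(intervals, expected)


class TestBursts:
    def test_stated_example(self):
        log = make_log(active=[0, 1, 1.5, 10, 11, 30])
        bs = detect_bursts(log, "active", 2.0)
        assert bs.n_bursts == 2
        assert [n for _, _, n in bs.bursts] == [3, 2]
        assert bs.mean_pokes_per_burst == pytest.approx(2.5)
        # the isolated poke at 30 s is not a burst
        assert all(not (start <= 30 <= end) for start, end, _ in bs.bursts)

    def test_single_poke_no_burst(self):
        bs = detect_bursts(make_log(active=[5.0]), "active", 2.0)
        assert bs.n_bursts == 0
        assert bs.mean_pokes_per_burst is None

    def test_gap_exactly_at_threshold_splits(self):
        bs = detect_bursts(make_log(active=[0, 2.0, 4.0]), "active", 2.0)
        assert bs.n_bursts == 0  # all gaps >= threshold

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 40))
        times = np.cumsum(rng.exponential(3.0, n)) if n else np.array([])
        log = make_log(active=times, duration=float(times[-1] + 1) if n else 10.0)
        for gap in (2.0, 6.0):
            bs = detect_bursts(log, "active", gap)
            assert list(bs.bursts) == brute_force_bursts(times, gap)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_6s_bursts_contain_2s_bursts(self, seed):
        """Every 2 s burst lies inside some 6 s burst; membership is
        monotone in the threshold."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        times = np.cumsum(rng.exponential(3.0, n))
        log = make_log(active=times, duration=float(times[-1] + 1))
        tight = detect_bursts(log, "active", 2.0).bursts
        loose = detect_bursts(log, "active", 6.0).bursts
        for s, e, _ in tight:
            assert any(ls <= s and e <= le for ls, le, _ in loose)

    def test_partition_consistency(self, rng):
        times = np.cumsum(rng.exponential(2.0, 50))
        log = make_log(active=times, duration=float(times[-1] + 1))
        bs = detect_bursts(log, "active", 2.0)
        in_burst = np.zeros(len(times), dtype=int)
        for s, e, n in bs.bursts:
            members = np.flatnonzero((times >= s) & (times <= e))
            assert len(members) == n
            in_burst[members] += 1
        assert in_burst.max() <= 1  # each poke in at most one burst


class TestCumulative:
    def test_monotone_with_final_count(self):
        log = make_log(active=np.arange(10, 1500, 37.0))
        grid, counts = cumulative_curve(log)
        assert np.all(np.diff(counts) >= 0)
        assert counts[-1] == count_pokes(log)[0]
        assert counts[0] == 0


class TestExtinction:
    def test_ratio_arithmetic(self):
        train = make_log(active=np.arange(0, 300, 10.0))
        ext = make_log(active=np.arange(0, 300, 10.0),
                       inactive=np.arange(5, 65, 10.0),
                       duration=900.0, laser_paired=False)
        rec = extinction_metrics(train, ext)
        assert rec["n_prev_active"] == 30
        assert rec["n_other"] == 6
        assert rec["preference_ratio"] == pytest.approx(30 / 36)
        assert not rec["indeterminate"]

    def test_empty_extinction_flagged(self):
        train = make_log(active=[1.0])
        ext = make_log(duration=900.0, laser_paired=False)
        rec = extinction_metrics(train, ext)
        assert rec["preference_ratio"] == 0.5
        assert rec["indeterminate"]

    def test_training_log_rejected_as_extinction(self):
        train = make_log(active=[1.0])
        with pytest.raises(InputError):
            extinction_metrics(train, train)


class TestExclusionQC:
    def _logs(self, counts, duration=1800.0):
        return [
            make_log(active=np.arange(c) * (duration - 1) / max(c, 1),
                     duration=duration, sid=f"day{i + 1}")
            for i, c in enumerate(counts)
        ]

    @pytest.mark.parametrize(
        "counts,excluded",
        [
            ([100, 90, 80, 45], True),   # day-4 decline beyond 50%
            ([100, 90, 80, 50], False),  # exactly 50% is retained
            ([20, 20, 20, 20], True),    # 0.667/min on average
            ([60, 70, 80, 90], False),
            ([40, 40, 40, 40], False),   # 1.33/min, no decline
        ],
    )
    def test_stated_rules(self, counts, excluded):
        assert exclusion_qc(self._logs(counts))["excluded"] is excluded

    def test_enumerated_truth_table(self):
        """Exhaustive small grid: QC decision equals the rule evaluated
        independently."""
        grid = [0, 20, 45, 50, 100]
        for d1 in grid:
            for d4 in grid:
                counts = [d1, 60, 60, d4]
                out = exclusion_qc(self._logs(counts))
                expect = (d4 < 0.5 * d1) or (sum(counts) / 120.0 < 1.0)
                assert out["excluded"] == expect, counts

    def test_wrong_session_count_rejected(self):
        with pytest.raises(InputError):
            exclusion_qc(self._logs([10, 10, 10]))


class TestSessionModel:
    def test_summary_and_metrics(self):
        log, truth = simulate_operant_session(AgentSpec(), seed=2)
        res = OperantSessionModel(log).fit()
        assert res.metrics.n_active == truth["n_active"]
        assert res.metrics.active_rate == pytest.approx(truth["n_active"] / 30.0)
        assert set(res.bursts) == {2.0, 6.0}
        assert f"Active pokes:   {truth['n_active']}" in res.summary()

    def test_empty_session_no_crash(self):
        res = OperantSessionModel(make_log()).fit()
        assert res.metrics.n_active == 0
        assert res.metrics.mean_ipi is None
        assert res.bursts[2.0].n_bursts == 0
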