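"""Segmentation under the immobility rule, metrics, windows, walking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strifkit import ethogram as et
from strifkit.motion import MotionTrace


def _trace(activity, fps=30.0, fly_id=0):
    act = np.asarray(activity, dtype=float)
    return MotionTrace(
        fly_id=fly_id, fps=fps, activity=act,
        background=np.zeros_like(act), n_frames=len(act) + 1,
    )


class TestClassifyStates:
    def test_all_zero_single_inactive_epoch(self):
        eth = et.classify_states(_trace(np.zeros(9000)), activity_threshold=0.0)
        assert len(eth.epochs) == 1
        e = eth.epochs[0]
        assert e.state == et.INACTIVE and e.start == 0.0
        assert e.end == pytest.approx(300.0)

    def test_short_quiescent_gap_absorbed(self):
        # 4 s of quiescence inside activity is not immobility
        fps = 30.0
        act = np.ones(int(30 * fps))
        act[int(13 * fps) : int(17 * fps)] = 0.0
        eth = et.classify_states(_trace(act), activity_threshold=0.5)
        assert [e.state for e in eth.epochs] == [et.ACTIVE]

    def test_five_second_gap_counts(self):
        fps = 30.0
        act = np.ones(int(30 * fps))
        act[int(13 * fps) : int(18 * fps)] = 0.0
        eth = et.classify_states(_trace(act), activity_threshold=0.5)
        assert [e.state for e in eth.epochs] == [et.ACTIVE, et.INACTIVE, et.ACTIVE]
        assert eth.epochs[1].duration == pytest.approx(5.0, abs=1 / fps)

    def test_programmed_boundaries_recovered(self):
        fps = 30.0
        act = np.concatenate([
            np.ones(int(30 * fps)), np.zeros(int(20 * fps)), np.ones(int(10 * fps)),
        ])
        eth = et.classify_states(_trace(act), activity_threshold=0.5)
        bounds = [e.start for e in eth.epochs[1:]]
        assert np.allclose(bounds, [30.0, 50.0], atol=1.0)

    def test_empty_trace_error(self):
        with pytest.raises(ValueError):
            et.classify_states(_trace(np.array([])))

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=60, deadline=None)
    def test_invariants_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        act = (rng.random(600) < rng.uniform(0.05, 0.95)).astype(float)
        eth = et.classify_states(_trace(act, fps=10.0), activity_threshold=0.5)
        # tiling
        assert eth.epochs[0].start == 0.0
        assert eth.epochs[-1].end == pytest.approx(60.0)
        for a, b in zip(eth.epochs, eth.epochs[1:]):
            assert a.end == pytest.approx(b.start)
            assert a.state != b.state
        # immobility rule (unless the whole assay is quiescent)
        if len(eth.epochs) > 1:
            for e in eth.epochs:
                if e.state == et.INACTIVE:
                    assert e.duration >= 5.0 - 1e-9

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=30, deadline=None)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        act = (rng.random(600) < 0.5).astype(float)
        eth = et.classify_states(_trace(act, fps=10.0), activity_threshold=0.5)
        again = et.segment_binary(eth.binary(10.0), 10.0, fly_id=0)
        assert [(e.state, e.start, e.end) for e in again.epochs] == pytest.approx(
            [(e.state, e.start, e.end) for e in eth.epochs]
        ) or [
            (e.state, round(e.start, 6), round(e.end, 6)) for e in again.epochs
        ] == [(e.state, round(e.start, 6), round(e.end, 6)) for e in eth.epochs]


class TestComputeMetrics:
    def _eth(self, spans, total):
        return et.Ethogram(0, [et.EthogramEpoch(s, a, b) for s, a, b in spans], total)

    def test_ratio_arithmetic(self):
        eth = self._eth(
            [(et.ACTIVE, 0, 200), (et.INACTIVE, 200, 300)], 300.0
        )
        m = et.compute_metrics(eth)
        assert m.ratio == pytest.approx(2.0)
        assert m.total_active == 200 and m.total_inactive == 100

    def test_fully_active_ratio_undefined(self):
        eth = self._eth([(et.ACTIVE, 0, 300)], 300.0)
        m = et.compute_metrics(eth)
        assert not m.ratio_defined and np.isnan(m.ratio)

    def test_conservation_exact(self):
        eth = self._eth(
            [(et.ACTIVE, 0, 123.4), (et.INACTIVE, 123.4, 300)], 300.0
        )
        for win in [(0, 300), (50, 250), (100, 130.7), (123.4, 200)]:
            m = et.compute_metrics(eth, window=win)
            assert m.total_active + m.total_inactive == pytest.approx(win[1] - win[0])

    def test_epoch_count_balance(self):
        eth = self._eth(
            [(et.ACTIVE, 0, 10), (et.INACTIVE, 10, 20), (et.ACTIVE, 20, 30)], 30.0
        )
        m = et.compute_metrics(eth)
        assert abs(m.n_active_epochs - m.n_inactive_epochs) <= 1
        assert m.mean_active_duration * m.n_active_epochs == pytest.approx(m.total_active)

    def test_zero_window_error(self):
        eth = self._eth([(et.ACTIVE, 0, 10)], 10.0)
        with pytest.raises(ValueError):
            et.compute_metrics(eth, window=(5, 5))

    def test_metric_recovery_from_programs(self):
        # mean estimated ratio over many sampled programs matches the
        # ratio implied by the requested bout means within 2 SEM
        from strifkit import synthvideo as sv

        ratios = []
        for s in range(100):
            prog = sv.sample_program(300.0, 20.0, 10.0, seed=s)
            ideal = sv.expected_state_intervals(prog)
            act = sum(b - a for st_, a, b in ideal if st_ == sv.ACTIVE)
            ina = 300.0 - act
            if ina > 0:
                ratios.append(act / ina)
        ratios = np.array(ratios)
        # merging sub-5 s quiescence inflates the activity share above the
        # raw 20:10 ratio; recompute the expectation empirically at high n
        big = []
        for s in range(100, 300):
            prog = sv.sample_program(300.0, 20.0, 10.0, seed=s)
            ideal = sv.expected_state_intervals(prog)
            act = sum(b - a for st_, a, b in ideal if st_ == sv.ACTIVE)
            if 300.0 - act > 0:
                big.append(act / (300.0 - act))
        sem = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - np.mean(big)) < 3 * sem


class TestSplitBeforeAfter:
    def test_equal_windows(self):
        eth = et.Ethogram(
            0,
            [et.EthogramEpoch(et.ACTIVE, 0, 400), et.EthogramEpoch(et.INACTIVE, 400, 600)],
            600.0,
        )
        before, after = et.split_before_after(eth, 300.0)
        assert before.window_duration == pytest.approx(300.0)
        assert after.window_duration == pytest.approx(300.0)
        assert before.total_active == pytest.approx(300.0)
        assert after.total_active == pytest.approx(100.0)

    def test_short_truncated_quiescence_reevaluated(self):
        # inactive epoch straddling the split leaves a 3 s fragment in the
        # after-window: no longer immobility
        eth = et.Ethogram(
            0,
            [
                et.EthogramEpoch(et.ACTIVE, 0, 290),
                et.EthogramEpoch(et.INACTIVE, 290, 303),
                et.EthogramEpoch(et.ACTIVE, 303, 600),
            ],
            600.0,
        )
        before, after = et.split_before_after(eth, 300.0)
        assert before.total_inactive == pytest.approx(10.0)
        assert after.total_inactive == 0.0
        assert after.total_active == pytest.approx(300.0)

    def test_boundary_flash_rejected(self):
        eth = et.Ethogram(0, [et.EthogramEpoch(et.ACTIVE, 0, 10)], 10.0)
        for t in (0.0, 10.0, -1.0):
            with pytest.raises(ValueError):
                et.split_before_after(eth, t)

    def test_symmetric_program_symmetric_metrics(self):
        from strifkit import synthvideo as sv

        diffs = []
        for s in range(40):
            half = sv.sample_program(300.0, 15.0, 10.0, seed=s)
            ideal = sv.expected_state_intervals(half)
            eps = []
            for rep in range(2):
                for st_, a, b in ideal:
                    eps.append(et.EthogramEpoch(st_, a + 300.0 * rep, b + 300.0 * rep))
            merged = []
            for e in eps:
                if merged and merged[-1].state == e.state:
                    merged[-1] = et.EthogramEpoch(e.state, merged[-1].start, e.end)
                else:
                    merged.append(e)
            eth = et.Ethogram(0, merged, 600.0)
            before, after = et.split_before_after(eth, 300.0)
            diffs.append(after.total_active - before.total_active)
        # identical halves: paired differences centred at zero
        assert abs(np.mean(diffs)) < 2 * np.std(diffs, ddof=1) / np.sqrt(len(diffs)) + 1e-9


class TestDurationHistogram:
    def test_single_epoch_mass(self):
        eth = et.Ethogram(0, [et.EthogramEpoch(et.INACTIVE, 0, 300)], 300.0)
        hist = et.duration_histogram([eth])
        edges, probs = hist[et.INACTIVE]
        assert probs.sum() == pytest.approx(1.0)
        assert probs[-1] == 1.0  # all mass in the last occupied 5 s bin

    def test_exponential_durations_recovered(self):
        # active durations ~ Exp(20 s): binned histogram matches the
        # analytic bin masses by chi-squared at n = 1000
        rng = np.random.default_rng(42)
        durs = rng.exponential(20.0, size=1000)
        ethos = []
        for i, d in enumerate(durs):
            ethos.append(
                et.Ethogram(
                    i,
                    [
                        et.EthogramEpoch(et.ACTIVE, 0, d),
                        et.EthogramEpoch(et.INACTIVE, d, d + 10.0),
                    ],
                    d + 10.0,
                )
            )
        edges, probs = et.duration_histogram(ethos)[et.ACTIVE]
        from scipy import stats

        expected = np.exp(-edges[:-1] / 20.0) - np.exp(-edges[1:] / 20.0)
        # merge sparse tail bins for a valid chi-squared
        obs = probs * 1000
        exp = expected / expected.sum() * 1000
        keep = exp >= 5
        obs = np.append(obs[keep], obs[~keep].sum())
        exp = np.append(exp[keep], exp[~keep].sum())
        p = stats.chisquare(obs, exp).pvalue
        assert p > 0.01

    def test_pooled_many_flies(self):
        from strifkit import synthvideo as sv

        ethos = []
        for s in range(54):
            prog = sv.sample_program(300.0, 20.0, 10.0, seed=s)
            ideal = sv.expected_state_intervals(prog)
            ethos.append(
                et.Ethogram(s, [et.EthogramEpoch(a, b, c) for a, b, c in ideal], 300.0)
            )
        hist = et.duration_histogram(ethos)
        assert set(hist) == {et.ACTIVE, et.INACTIVE}
        for edges, probs in hist.values():
            assert probs.sum() == pytest.approx(1.0)


class TestWalkingMetrics:
    def test_stationary_fly(self):
        traj = pd.DataFrame({"x": np.zeros(150), "y": np.zeros(150)})
        m = et.walking_metrics(traj, fps=15.0)
        assert m.mean_speed == 0.0
        assert m.total_active == 0.0
        assert m.ratio == 0.0  # fully inactive: degenerate zero ratio
        assert m.n_active_epochs == 0

    def test_constant_velocity(self):
        fps, v = 15.0, 4.0  # mm/s
        t = np.arange(300) / fps
        traj = pd.DataFrame({"x": v * t, "y": np.zeros_like(t)})
        m = et.walking_metrics(traj, fps=fps, immobility_speed_threshold=0.5)
        assert m.mean_speed == pytest.approx(v)
        assert m.total_inactive == 0.0

    def test_gap_error_and_interpolation(self):
        t = np.array([0.0, 0.1, 3.0, 3.1])
        traj = pd.DataFrame({"x": [0, 1, 2, 3], "y": [0, 0, 0, 0], "t": t})
        with pytest.raises(ValueError, match="gap"):
            et.walking_metrics(traj, fps=10.0)
        m = et.walking_metrics(traj, fps=10.0, interpolate=True)
        assert m.mean_speed > 0

    def test_two_state_walk_ratio_recovered(self):
        rng = np.random.default_rng(7)
        fps = 15.0
        ratios = []
        for _ in range(100):
            # 60 s walk: 30 s at 5 mm/s, 30 s stationary
            n = int(30 * fps)
            dx = np.concatenate([np.full(n, 5.0 / fps), np.zeros(n)])
            x = np.cumsum(dx + rng.normal(0, 0.005, size=2 * n))
            traj = pd.DataFrame({"x": x, "y": np.zeros_like(x)})
            m = et.walking_metrics(traj, fps=fps, immobility_speed_threshold=1.0)
            if m.ratio_defined:
                ratios.append(m.ratio)
        mean = np.mean(ratios)
        sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - 1.0) < 2 * sem + 0.05
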