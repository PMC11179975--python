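"""Trigger policies: percentile primitive, dynamic/static/periodic runs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vnssim
from vnssim.triggering import percentile_threshold


def gated(values, fs=60.0, movement_minimum=0.0):
    values = np.asarray(values, dtype=float)
    roc = vnssim.RocSignal(np.arange(len(values)) / fs, values)
    return vnssim.gate_noise(roc, movement_minimum)


class TestPercentileThreshold:
    def test_interpolated_order_statistic(self):
        assert percentile_threshold(range(1, 101), 95) == pytest.approx(95.05)

    def test_degenerate_distribution(self):
        assert percentile_threshold([3.3] * 10, 72.0) == pytest.approx(3.3)

    def test_midpoint_interpolation(self):
        assert percentile_threshold([0.0, 10.0], 50) == pytest.approx(5.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold([1.0], 50)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=300),
        st.floats(0.01, 99.99),
    )
    def test_matches_numpy_oracle(self, values, q):
        assert percentile_threshold(values, q) == pytest.approx(
            float(np.percentile(values, q)), abs=1e-9, rel=1e-9
        )


class TestDynamicStep:
    def params(self, **kw):
        defaults = dict(percentile=95.0, buffer_size=100, min_isi=5.0, min_buffer_fill=5)
        defaults.update(kw)
        return vnssim.DynamicParams(**defaults)

    def test_constant_stream_never_triggers(self):
        # a value never strictly exceeds its own percentile (tie rule)
        params = self.params()
        state = vnssim.DynamicState(params)
        for i in range(200):
            state, event = vnssim.dynamic_step(state, (i / 60.0, 2.0, True), params)
            assert event is None

    def test_novel_maximum_triggers_exactly_once(self):
        values = [0.5] * 100 + [5.0]
        params = self.params()
        state = vnssim.DynamicState(params)
        events = []
        for i, v in enumerate(values):
            state, event = vnssim.dynamic_step(state, (i / 60.0, v, True), params)
            if event:
                events.append(event)
        assert len(events) == 1
        assert events[0].time == pytest.approx(100 / 60.0)
        assert events[0].paired_value == 5.0

    def test_isi_gate_suppresses_second_peak(self):
        # two supra-threshold peaks 2 s apart, min_isi 5 s -> one trigger
        fs = 60.0
        values = np.ones(int(8 * fs))
        values[int(3 * fs)] = 10.0
        values[int(5 * fs)] = 12.0
        params = self.params()
        state = vnssim.DynamicState(params)
        events = []
        for i, v in enumerate(values):
            state, event = vnssim.dynamic_step(state, (i / fs, float(v), True), params)
            if event:
                events.append(event)
        assert len(events) == 1
        assert events[0].time == pytest.approx(3.0)

    def test_out_of_order_timestamp_rejected(self):
        params = self.params()
        state = vnssim.DynamicState(params)
        vnssim.dynamic_step(state, (1.0, 0.5, True), params)
        with pytest.raises(ValueError, match="out-of-order"):
            vnssim.dynamic_step(state, (0.5, 0.5, True), params)

    def test_no_triggers_before_movement_initiation(self):
        params = self.params(include_subminimum=True, min_buffer_fill=2)
        state = vnssim.DynamicState(params)
        rng = np.random.default_rng(1)
        # all samples flagged sub-minimum: buffer fills but nothing may fire
        for i, v in enumerate(rng.uniform(0, 1, 50)):
            state, event = vnssim.dynamic_step(state, (i / 60.0, float(v), False), params)
            assert event is None
        assert not state.movement_initiated
        assert len(state.buffer) == 50


class TestRunDynamic:
    def test_every_trigger_strictly_exceeds_its_threshold(self, default_session, movement_minimum):
        _, roc, _ = default_session
        events, _ = vnssim.run_dynamic(roc, vnssim.DynamicParams())
        assert events
        for ev in events:
            assert abs(ev.paired_value) > abs(ev.threshold_at_trigger)

    def test_batch_equals_streaming_fold(self, default_session):
        _, roc, _ = default_session
        params = vnssim.DynamicParams(percentile=85.0)
        events, trace = vnssim.run_dynamic(roc, params)
        state = vnssim.DynamicState(params)
        folded = []
        for t, v, s in zip(roc.timestamps, roc.values, roc.supra_minimum):
            state, event = vnssim.dynamic_step(state, (t, v, s), params)
            if event:
                folded.append(event)
        assert [e.time for e in folded] == [e.time for e in events]
        assert [e.paired_value for e in folded] == [e.paired_value for e in events]

    def test_threshold_trace_matches_trailing_window_oracle(self, default_session):
        # the published threshold equals np.percentile of the supra-minimum
        # magnitudes in the trailing window of <= buffer_size samples
        _, roc, _ = default_session
        params = vnssim.DynamicParams(percentile=95.0, buffer_size=500)
        _, trace = vnssim.run_dynamic(roc, params)
        mags = np.abs(roc.values)
        supra_idx = np.flatnonzero(roc.supra_minimum)
        for i in (2000, 4000, len(roc) - 1):
            window = [mags[j] for j in supra_idx if j <= i][-500:]
            if len(window) >= 2:
                assert trace["threshold_pos"][i] == pytest.approx(
                    float(np.percentile(window, 95)), abs=1e-9
                )

    def test_buffer_capacity_invariant(self):
        rng = np.random.default_rng(3)
        roc = gated(rng.uniform(0.1, 1.0, 2000))
        params = vnssim.DynamicParams(buffer_size=64, min_buffer_fill=2, min_isi=0.0)
        state = vnssim.DynamicState(params)
        for i, (t, v) in enumerate(zip(roc.timestamps, roc.values)):
            state, _ = vnssim.dynamic_step(state, (t, v, True), params)
            assert len(state.buffer) <= 64
            if i >= 63:
                assert len(state.buffer) == 64

    def test_rate_limited_by_min_isi(self, default_session):
        _, roc, _ = default_session
        params = vnssim.DynamicParams(percentile=45.0, min_isi=5.0)
        events, _ = vnssim.run_dynamic(roc, params)
        assert len(events) <= math.floor(roc.duration / 5.0) + 1

    def test_stationary_signal_exceeds_threshold_about_5pct(self):
        # on an iid stream at p95 with no ISI gate, ~5% of samples trigger
        rng = np.random.default_rng(11)
        n = 50_000
        roc = gated(rng.uniform(0.1, 1.0, n))
        params = vnssim.DynamicParams(percentile=95.0, min_isi=0.0)
        events, _ = vnssim.run_dynamic(roc, params)
        assert 0.045 < len(events) / n < 0.055

    def test_trigger_count_monotone_in_percentile(self, default_session):
        _, roc, _ = default_session
        counts = [
            len(vnssim.run_dynamic(roc, vnssim.DynamicParams(percentile=p, min_isi=0.0))[0])
            for p in (45, 55, 65, 75, 85, 95)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_isi_invariant(self, default_session):
        _, roc, _ = default_session
        events, _ = vnssim.run_dynamic(roc, vnssim.DynamicParams(min_isi=5.0))
        times = [e.time for e in events]
        assert all(b - a >= 5.0 for a, b in zip(times, times[1:]))


class TestDirectionality:
    def _asymmetric_roc(self):
        rng = np.random.default_rng(21)
        v = rng.uniform(0.2, 1.0, 4000) * rng.choice([1.0, -1.0], 4000)
        v[rng.uniform(size=4000) < 0.3] *= 3.0  # some large excursions both ways
        return gated(v)

    def test_positive_only_never_fires_on_negative_movement(self):
        roc = self._asymmetric_roc()
        params = vnssim.DynamicParams(directionality="positive_only", min_isi=0.0)
        events, _ = vnssim.run_dynamic(roc, params)
        assert events
        assert all(ev.paired_value > 0 for ev in events)

    def test_bidirectional_thresholds_use_disjoint_sign_sets(self):
        roc = self._asymmetric_roc()
        params = vnssim.DynamicParams(directionality="bidirectional", min_isi=0.0)
        state = vnssim.DynamicState(params)
        for t, v, s in zip(roc.timestamps, roc.values, roc.supra_minimum):
            state, _ = vnssim.dynamic_step(state, (t, v, s), params)
        pos = state.buffer.snapshot()
        neg = state.buffer_negative.snapshot()
        assert np.all(pos > 0) and np.all(neg > 0)
        pos_count = int(np.sum((roc.values > 0) & roc.supra_minimum))
        assert len(pos) == min(pos_count, params.buffer_size)

    def test_bidirectional_triggers_both_directions(self):
        roc = self._asymmetric_roc()
        params = vnssim.DynamicParams(directionality="bidirectional", min_isi=0.0)
        events, _ = vnssim.run_dynamic(roc, params)
        directions = {ev.direction for ev in events}
        assert directions == {"positive", "negative"}
        for ev in events:
            assert (ev.threshold_at_trigger > 0) == (ev.direction == "positive")


class TestRunStatic:
    def test_constant_below_threshold_never_triggers(self):
        roc = gated(np.full(600, 10.0))
        events = vnssim.run_static(roc, vnssim.StaticParams(multiplier=32, movement_minimum=1.0))
        assert events == []

    def test_single_excursion_triggers_once(self):
        v = np.full(600, 10.0)
        v[300] = 40.0
        events = vnssim.run_static(gated(v), vnssim.StaticParams(multiplier=32, movement_minimum=1.0))
        assert len(events) == 1
        assert events[0].time == pytest.approx(5.0)
        assert events[0].threshold_at_trigger == pytest.approx(32.0)

    def test_sustained_plateau_retriggers_every_min_isi(self):
        # 12 s above threshold with a 5 s gate: onset, +5 s, +10 s
        fs = 60.0
        v = np.full(int(20 * fs), 1.0)
        v[int(2 * fs): int(14 * fs)] = 40.0
        events = vnssim.run_static(
            gated(v, fs), vnssim.StaticParams(multiplier=32, movement_minimum=1.0, min_isi=5.0)
        )
        assert [e.time for e in events] == pytest.approx([2.0, 7.0, 12.0])

    def test_per_crossing_mode_fires_once_per_plateau(self):
        fs = 60.0
        v = np.full(int(20 * fs), 1.0)
        v[int(2 * fs): int(14 * fs)] = 40.0
        events = vnssim.run_static(
            gated(v, fs),
            vnssim.StaticParams(multiplier=32, movement_minimum=1.0, min_isi=5.0,
                                retrigger="per_crossing"),
        )
        assert [e.time for e in events] == pytest.approx([2.0])

    def test_zero_movement_minimum_rejected(self):
        with pytest.raises(ValueError, match="degenerates"):
            vnssim.run_static(gated([1.0, 2.0]), vnssim.StaticParams(multiplier=2, movement_minimum=0.0))

    def test_trigger_count_monotone_in_multiplier(self, default_session, movement_minimum):
        _, roc, _ = default_session
        counts = [
            len(vnssim.run_static(roc, vnssim.StaticParams(multiplier=m, movement_minimum=movement_minimum)))
            for m in (1, 2, 4, 8, 16, 32)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRunPeriodic:
    def test_60s_session_at_12s_gives_5_triggers(self):
        events = vnssim.run_periodic((0.0, 60.0), vnssim.PeriodicParams(12.0))
        assert [e.time for e in events] == pytest.approx([12, 24, 36, 48, 60])

    @pytest.mark.parametrize("end, expected", [(30.0, 2), (11.9, 0)])
    def test_partial_intervals_are_dropped(self, end, expected):
        assert len(vnssim.run_periodic((0.0, end), vnssim.PeriodicParams(12.0))) == expected

    def test_nonpositive_span_rejected(self):
        with pytest.raises(ValueError):
            vnssim.run_periodic((10.0, 10.0), vnssim.PeriodicParams(12.0))
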