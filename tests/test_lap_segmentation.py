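import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swimu import (
    SegmentationParams,
    SessionSpec,
    detect_events,
    generate_session,
    lap_time_outliers,
    recover_missed_turns,
    refine_boundaries,
    scaled_mad,
    segment_laps,
    segment_session,
)
from swimu.lap_segmentation import MotionEvent
from swimu.synthetic_session import default_lap

FS = 100.0


def _pulse(t, t0, dur, amp):
    out = np.zeros_like(t)
    m = (t >= t0) & (t < t0 + dur)
    out[m] = amp * 0.5 * (1 - np.cos(2 * np.pi * (t[m] - t0) / dur))
    return out


class TestDetectEvents:
    def test_flat_swim_pitch_yields_no_events(self):
        assert detect_events(np.full(3000, 5.0), FS) == []

    def test_short_excursion_is_a_turn(self):
        t = np.arange(0, 30, 1 / FS)
        events = detect_events(_pulse(t, 10.0, 1.5, 88.0), FS)
        assert [e.kind for e in events] == ["turn"]
        assert events[0].apex_t == pytest.approx(10.75, abs=0.05)

    def test_separated_extrema_make_a_stop(self):
        # descend to -90 at t=10, local max -72 at t=15: extrema 5 s apart
        t = np.arange(0, 30, 1 / FS)
        p = np.zeros_like(t)
        for t0, t1, v0, v1 in [(8, 10, 0, -90), (10, 15, -90, -72),
                               (15, 17, -72, -88), (17, 19, -88, 0)]:
            m = (t >= t0) & (t < t1)
            p[m] = v0 + (v1 - v0) * (t[m] - t0) / (t1 - t0)
        events = detect_events(p, FS)
        assert [e.kind for e in events] == ["stop"]

    def test_long_plateau_is_a_stop(self):
        t = np.arange(0, 30, 1 / FS)
        p = np.zeros_like(t)
        m = (t >= 10) & (t < 16)
        p[m] = -85.0
        assert [e.kind for e in detect_events(p, FS)] == ["stop"]

    def test_turn_stop_boundary_monotone_in_stop_min_s(self):
        t = np.arange(0, 30, 1 / FS)
        p = _pulse(t, 10.0, 2.5, 88.0)
        base = SegmentationParams()
        kinds = []
        for stop_min in (0.1, 0.5, 1.0, 2.0, 5.0):
            params = SegmentationParams(
                stop_min_s=stop_min, swim_band_deg=base.swim_band_deg
            )
            kinds.append(detect_events(p, FS, params)[0].kind)
        # stops for small thresholds, then turns: a single switch point
        assert kinds == sorted(kinds, key=lambda k: k == "turn")


def _brute_force_refine(pitch, fs, apex_idx, params):
    """Literal scan of every window position, the oracle for refinement."""
    w = int(round(params.refine_window_s * fs))
    n = len(pitch)
    start = 0
    for i in range(apex_idx, -1, -1):
        lo = max(i - w + 1, 0)
        if abs(np.mean(pitch[lo : i + 1])) <= params.swim_band_deg:
            start = i
            break
    end = n - 1
    for i in range(apex_idx, n):
        hi = min(i + w, n)
        if abs(np.mean(pitch[i:hi])) <= params.swim_band_deg:
            end = i
            break
    return start / fs, end / fs


class TestRefineBoundaries:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 40, 1 / FS)
        pitch = rng.normal(0, 2.0, len(t))
        t0 = rng.uniform(8, 25)
        pitch += _pulse(t, t0, rng.uniform(1.0, 3.0), 88.0)
        params = SegmentationParams()
        ev = detect_events(pitch, FS, params)[0]
        ref = refine_boundaries(pitch, FS, ev, params)
        bs, be = _brute_force_refine(pitch, FS, int(round(ev.apex_t * FS)), params)
        assert ref.start_t == pytest.approx(bs)
        assert ref.end_t == pytest.approx(be)

    def test_square_excursion_offsets_fixed_by_window_mean(self):
        # 0 -> 90 at t=10, back to 0 at t=12; leading mean re-enters the
        # +/-20 band when only ~0.11 s of the excursion remains in the window
        pitch = np.zeros(3000)
        pitch[1000:1200] = 90.0
        ev = detect_events(pitch, FS)[0]
        ref = refine_boundaries(pitch, FS, ev)
        bs, be = _brute_force_refine(pitch, FS, int(round(ev.apex_t * FS)), SegmentationParams())
        assert ref.start_t == pytest.approx(bs)
        assert ref.end_t == pytest.approx(be)
        assert be == pytest.approx(11.89, abs=0.02)

    def test_event_at_signal_start_clips_to_zero(self):
        pitch = np.concatenate([np.full(100, 88.0), np.zeros(2000)])
        ev = MotionEvent("turn", apex_t=0.2, start_t=0, end_t=0, apex_pitch=88.0)
        ref = refine_boundaries(pitch, FS, ev)
        assert ref.start_t == 0.0

    def test_band_never_reentered_clips_to_signal_end(self):
        pitch = np.concatenate([np.zeros(1000), np.full(500, 88.0)])
        ev = MotionEvent("turn", apex_t=12.0, start_t=0, end_t=0, apex_pitch=88.0)
        ref = refine_boundaries(pitch, FS, ev)
        assert ref.end_t == pytest.approx((len(pitch) - 1) / FS)


class TestScaledMad:
    def test_hand_computed_values(self):
        assert scaled_mad([1, 1, 1, 1]) == 0.0
        assert scaled_mad([1, 2, 3, 4, 5]) == pytest.approx(1.4826)
        assert scaled_mad([7.0]) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            scaled_mad([])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        st.floats(-100, 100),
        st.floats(-10, 10).filter(lambda a: abs(a) > 1e-3),
    )
    def test_translation_invariant_scale_equivariant(self, xs, b, a):
        base = scaled_mad(xs)
        shifted = scaled_mad([a * x + b for x in xs])
        assert shifted == pytest.approx(abs(a) * base, rel=1e-9, abs=1e-9)


class TestLapTimeOutliers:
    def test_single_long_lap_flagged(self):
        assert lap_time_outliers([20, 21, 20, 22, 61]) == {4}

    def test_two_long_laps_flagged(self):
        assert lap_time_outliers([20, 21, 20, 22, 41, 20, 62]) == {4, 6}

    def test_all_equal_yields_no_outliers(self):
        assert lap_time_outliers([25.0] * 6) == set()

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(1, 100), min_size=3, max_size=20),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    def test_flags_invariant_under_affine_rescaling(self, xs, a, b):
        assert lap_time_outliers(xs) == lap_time_outliers([a * x + b for x in xs])


class TestSegmentLaps:
    def _session(self, n=3000):
        import pandas as pd
        from swimu.imu_io import COLUMNS, ImuSession

        df = pd.DataFrame(0.0, index=range(n), columns=list(COLUMNS))
        df["t_ms"] = np.arange(n) * 10
        return ImuSession.from_dataframe(df)

    def test_no_events_one_lap(self):
        laps = segment_laps(self._session(), [])
        assert len(laps) == 1
        assert laps[0].start_t == 0.0

    def test_three_turns_four_laps(self):
        evs = [
            MotionEvent("turn", a, a - 0.5, a + 0.5, 85.0) for a in (6.0, 12.0, 18.0)
        ]
        assert len(segment_laps(self._session(), evs)) == 4

    def test_boundary_arithmetic_excludes_event_span(self):
        ev = MotionEvent("turn", 11.0, 10.2, 12.1, 85.0)
        laps = segment_laps(self._session(), [ev])
        assert laps[0].start_t == 0.0
        assert laps[0].end_t == pytest.approx(10.2)
        assert laps[1].start_t == pytest.approx(12.1)
        assert laps[1].end_t == pytest.approx(29.99)

    def test_overlapping_events_rejected(self):
        evs = [
            MotionEvent("turn", 10.0, 9.0, 11.0, 85.0),
            MotionEvent("turn", 10.5, 10.2, 12.0, 85.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            segment_laps(self._session(), evs)


class TestMissedTurnRecovery:
    def test_bucket_turn_recovered_and_outlier_resolved(self):
        spec = SessionSpec(
            laps=[default_lap("backstroke") for _ in range(4)],
            turn_types=["tumble", "bucket", "tumble"],
            seed=21,
        )
        sess, truth = generate_session(spec)
        params = SegmentationParams()
        events, laps = segment_session(sess, params)
        assert len(laps) == len(truth.laps) == 4
        times = [l.lap_time for l in laps]
        assert lap_time_outliers(times, params.mad_scale) == set()

    def test_outlier_lap_without_reversal_returns_none(self):
        spec = SessionSpec(
            laps=[default_lap("backstroke") for _ in range(3)], seed=22
        )
        sess, _ = generate_session(spec)
        _, laps = segment_session(sess)
        heading = np.full(len(sess), 90.0)  # constant: no reversal anywhere
        assert (
            recover_missed_turns(laps[0], sess.pitch, heading, sess.fs) is None
        )
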