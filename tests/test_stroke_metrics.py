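import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swimu import (
    CountingParams,
    LapSpec,
    band_mask,
    build_mean_wave,
    count_strokes,
    detect_pitch_cycles,
    detect_roll_strokes,
    dtw_distance,
    generate_lap,
    generate_lap_corpus,
    reject_outlier_cycles,
)
from swimu.stroke_metrics import CYCLE_RESAMPLE_N, StrokeCycle

FS = 100.0


def _roll_lap(n_strokes=10, amplitude=30.0, duration=12.0):
    spec = LapSpec(
        style="front_crawl",
        n_strokes=n_strokes,
        duration_s=duration,
        roll_amplitude=amplitude,
    )
    ch, truth = generate_lap(spec, FS, np.random.default_rng(0))
    return ch["roll"], truth


def _pitch_lap(style="breaststroke", n=8, duration=24.0, artifact=False):
    spec = LapSpec(
        style=style, n_strokes=n, duration_s=duration, turn_artifact=artifact
    )
    ch, truth = generate_lap(spec, FS, np.random.default_rng(0))
    return ch["pitch"], truth


class TestBandMask:
    def test_gaussian_series_about_5pct_outside_at_k2(self, rng):
        x = rng.normal(0, 1, 200_000)
        frac = np.mean(band_mask(x, 2.0))
        assert frac == pytest.approx(0.0455, abs=0.005)

    def test_constant_series_has_no_candidates(self):
        assert not band_mask(np.full(50, 3.0), 2.0).any()

    def test_k_zero_flags_every_offmean_sample(self):
        x = np.array([1.0, 2.0, 3.0])
        assert list(band_mask(x, 0.0)) == [True, False, True]


class TestDetectRollStrokes:
    def test_pulse_train_counts_maxima_and_minima(self):
        roll, truth = _roll_lap(n_strokes=20, amplitude=30.0, duration=24.0)
        events = detect_roll_strokes(roll, FS, "front_crawl")
        assert len(events) == 20 == len(truth["stroke_times"])
        # both polarities present: maxima on one side, minima on the other
        assert {e.polarity for e in events} == {"max", "min"}

    def test_small_rotation_below_20_deg_rejected(self):
        roll, _ = _roll_lap(n_strokes=10, amplitude=10.0)
        assert detect_roll_strokes(roll, FS, "front_crawl") == []

    def test_single_blip_counts_once(self):
        t = np.arange(0, 20, 1 / FS)
        roll = np.zeros_like(t)
        m = (t >= 10) & (t < 11)
        roll[m] = 35.0 * 0.5 * (1 - np.cos(2 * np.pi * (t[m] - 10)))
        events = detect_roll_strokes(roll, FS, "front_crawl")
        assert len(events) == 1
        assert events[0].polarity == "max"

    def test_wrong_style_rejected(self):
        with pytest.raises(ValueError):
            detect_roll_strokes(np.zeros(500), FS, "butterfly")


class TestDetectPitchCycles:
    def test_clean_lap_yields_spec_count_of_cycles(self):
        pitch, truth = _pitch_lap(n=8)
        cycles = detect_pitch_cycles(pitch, FS, "breaststroke")
        assert len(cycles) == 8 == len(truth["stroke_times"])

    def test_every_cycle_resampled_to_200(self):
        pitch, _ = _pitch_lap(n=5)
        for c in detect_pitch_cycles(pitch, FS, "breaststroke"):
            assert len(c.resampled) == CYCLE_RESAMPLE_N

    def test_monotone_pitch_yields_no_cycles(self):
        pitch = np.linspace(-10, 10, 3000)
        assert detect_pitch_cycles(pitch, FS, "butterfly") == []


class TestMeanWave:
    def _cycle(self, wave):
        wave = np.asarray(wave, dtype=float)
        return StrokeCycle(0.0, 1.0, float(wave.min()), float(wave.max()), wave)

    def test_identical_cycles_mean_is_any_central(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 200))
        cycles = [self._cycle(w)] * 3
        tpl = build_mean_wave(cycles)
        np.testing.assert_allclose(tpl.wave, w[50:150])

    def test_mirrored_cycles_cancel(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 200))
        tpl = build_mean_wave([self._cycle(w), self._cycle(-w)])
        np.testing.assert_allclose(tpl.wave, 0.0, atol=1e-12)

    def test_template_is_central_half(self):
        tpl = build_mean_wave([self._cycle(np.arange(200.0))])
        assert len(tpl.wave) == 100
        np.testing.assert_allclose(tpl.wave, np.arange(50.0, 150.0))

    def test_zero_cycles_rejected(self):
        with pytest.raises(ValueError):
            build_mean_wave([])


def _dtw_oracle(a, b):
    """Exhaustive enumeration of every monotone warping path."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j):
        c = (a[i] - b[j]) ** 2
        if i == 0 and j == 0:
            return c
        opts = []
        if i > 0:
            opts.append(best(i - 1, j))
        if j > 0:
            opts.append(best(i, j - 1))
        if i > 0 and j > 0:
            opts.append(best(i - 1, j - 1))
        return c + min(opts)

    return float(np.sqrt(best(len(a) - 1, len(b) - 1)))


class TestDtwDistance:
    def test_identity_is_zero(self):
        x = np.sin(np.linspace(0, 5, 80))
        assert dtw_distance(x, x) == 0.0

    def test_hand_enumerated_value(self):
        assert dtw_distance([0.0, 0.0], [1.0, 1.0]) == pytest.approx(np.sqrt(2))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
    )
    def test_symmetric_and_matches_path_enumeration(self, a, b):
        d = dtw_distance(a, b)
        assert d == pytest.approx(dtw_distance(b, a))
        assert d == pytest.approx(_dtw_oracle(tuple(a), tuple(b)))


class TestRejectOutlierCycles:
    def _cycles_with_artifact(self):
        pitch, _ = _pitch_lap(style="butterfly", n=8, artifact=False)
        cycles = detect_pitch_cycles(pitch, FS, "butterfly")
        # corrupt one cycle into a half-amplitude, phase-shifted artifact
        bad = cycles[3]
        w = np.roll(0.5 * bad.resampled, 40)
        cycles[3] = StrokeCycle(
            bad.start_t, bad.end_t, float(w.min()), float(w.max()), w
        )
        return cycles

    def test_identical_cycles_all_kept(self):
        pitch, _ = _pitch_lap(n=6)
        cycles = detect_pitch_cycles(pitch, FS, "breaststroke")
        tpl = build_mean_wave(cycles)
        kept, rejected = reject_outlier_cycles(cycles, tpl)
        assert len(kept) == len(cycles) and rejected == []

    def test_corrupted_cycle_alone_discarded(self):
        cycles = self._cycles_with_artifact()
        tpl = build_mean_wave(cycles)
        kept, rejected = reject_outlier_cycles(cycles, tpl)
        assert len(rejected) == 1
        assert rejected[0].start_t == cycles[3].start_t

    def test_infinite_threshold_keeps_everything(self):
        cycles = self._cycles_with_artifact()
        tpl = build_mean_wave(cycles, dtw_reject_threshold=np.inf)
        kept, rejected = reject_outlier_cycles(cycles, tpl)
        assert len(kept) == len(cycles) and rejected == []


class TestCountStrokes:
    @pytest.mark.parametrize(
        "style", ["front_crawl", "backstroke", "breaststroke", "butterfly"]
    )
    def test_noise_free_counts_exact(self, style):
        sess, truth = generate_lap_corpus(
            style, 1, seed=31, noise_sd_deg=0.0, noise_sd_g=0.0, artifacts=False
        )[0]
        res = count_strokes(sess.pitch, sess.roll, sess.fs, style)
        assert res.count == truth.laps[0].stroke_count

    def test_empty_lap_counts_zero(self):
        res = count_strokes(np.array([]), np.array([]), FS, "front_crawl")
        assert res.count == 0

    def test_detected_times_near_truth(self):
        sess, truth = generate_lap_corpus("front_crawl", 1, seed=32)[0]
        res = count_strokes(sess.pitch, sess.roll, sess.fs, "front_crawl")
        errs = np.abs(
            np.array(res.detected_times) - np.array(truth.laps[0].stroke_times)
        )
        assert np.max(errs) < 0.3

    @pytest.mark.parametrize("style", ["front_crawl", "backstroke"])
    def test_count_monotone_in_min_rotation(self, style):
        sess, _ = generate_lap_corpus(style, 1, seed=33)[0]
        counts = []
        for mr in (5.0, 20.0, 35.0, 50.0):
            p = CountingParams(min_rotation_deg=mr)
            counts.append(count_strokes(sess.pitch, sess.roll, sess.fs, style, p).count)
        assert counts == sorted(counts, reverse=True)
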