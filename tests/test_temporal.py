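import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_runs
from fatiguekit.temporal import (
    DetectorConfig, Event, EventLog, detect_events, detect_eye_state,
    ewma_smooth, init_ear_threshold, scale_partial_window, segment_windows,
    window_summary,
)


class TestEwma:
    def test_hand_recursion(self):
        np.testing.assert_allclose(ewma_smooth([1.0, 2.0], 0.2), [1.0, 1.2])

    def test_constant_fixed_point(self):
        np.testing.assert_allclose(ewma_smooth([3.0] * 5, 0.7), [3.0] * 5)

    def test_alpha_one_identity(self):
        x = [0.1, 0.9, 0.4]
        np.testing.assert_allclose(ewma_smooth(x, 1.0), x)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ewma_smooth([], 0.2)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=60),
           st.floats(0.01, 1.0))
    def test_matches_loop_oracle_and_stays_bounded(self, values, alpha):
        out = ewma_smooth(values, alpha)
        acc = values[0]
        for t, v in enumerate(values):
            if t > 0:
                acc = alpha * v + (1 - alpha) * acc
            assert abs(out[t] - acc) <= 1e-12
            assert min(values[: t + 1]) - 1e-9 <= out[t] <= max(values[: t + 1]) + 1e-9


class TestEarThreshold:
    def test_baseline_caps_large_personal_mean(self):
        assert init_ear_threshold([0.30, 0.30, 0.29]) == 0.25

    def test_personal_mean_when_smaller(self):
        assert init_ear_threshold([0.18, 0.22, 0.3]) == pytest.approx(0.20)

    def test_single_frame_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            init_ear_threshold([0.3])

    def test_nan_frames_skipped(self):
        assert init_ear_threshold([np.nan, 0.18, 0.22]) == pytest.approx(0.20)


class TestEyeState:
    def test_always_open(self):
        assert not detect_eye_state([0.3] * 10, 0.25, 0.02).any()

    def test_v_dip_gives_one_closed_run(self):
        ear = [0.3, 0.3, 0.2, 0.2, 0.2, 0.3, 0.3]
        closed = detect_eye_state(ear, 0.25, 0.02)
        assert brute_force_runs(closed) == [(2, 4)]

    def test_hysteresis_band_keeps_closed(self):
        # after closing, oscillation inside (thr, thr+h] must not reopen
        ear = [0.3, 0.2, 0.26, 0.27, 0.26, 0.27]
        closed = detect_eye_state(ear, 0.25, 0.02)
        assert closed[1:].all()

    def test_reopen_requires_exceeding_threshold_plus_h(self):
        ear = [0.3, 0.2, 0.271, 0.28]
        closed = detect_eye_state(ear, 0.25, 0.02)
        assert list(closed) == [False, True, False, False]


class TestDetectEvents:
    cfg = DetectorConfig()

    def test_flat_series_no_events(self):
        n = 200
        log = detect_events(np.full(n, 0.34), np.zeros(n, bool), self.cfg,
                            smoothed_pitch=np.zeros(n))
        assert log.counts() == (0, 0, 0)

    def test_scripted_counts_match_run_length_oracle(self):
        rng = np.random.default_rng(5)
        n = 3000
        eye = rng.random(n) < 0.1
        mar = np.where(rng.random(n) < 0.05, 0.9, 0.3)
        # long deterministic yawn and nod plateaus
        mar[500:580] = 0.9
        pitch = np.zeros(n)
        pitch[1000:1040] = 15.0
        log = detect_events(mar, eye, self.cfg, smoothed_pitch=pitch, fps=30)
        blinks = [r for r in brute_force_runs(eye)
                  if r[1] - r[0] + 1 >= self.cfg.min_blink_frames]
        yawns = [r for r in brute_force_runs(mar > 0.75)
                 if r[1] - r[0] + 1 >= self.cfg.min_yawn_frames]
        nods = [r for r in brute_force_runs(np.abs(pitch) > 10)
                if r[1] - r[0] + 1 >= self.cfg.min_nod_frames]
        assert [(e.start_frame, e.end_frame) for e in log.of_kind("blink")] == blinks
        assert [(e.start_frame, e.end_frame) for e in log.of_kind("yawn")] == yawns
        assert [(e.start_frame, e.end_frame) for e in log.of_kind("nod")] == nods

    def test_short_mar_plateau_filtered(self):
        n = 200
        mar = np.full(n, 0.3)
        mar[50:90] = 0.9        # 40 frames < 50
        log = detect_events(mar, np.zeros(n, bool), self.cfg,
                            smoothed_pitch=np.zeros(n))
        assert log.counts() == (0, 0, 0)

    def test_missing_pitch_skips_nods(self):
        n = 100
        log = detect_events(np.full(n, 0.3), np.zeros(n, bool), self.cfg,
                            smoothed_pitch=None)
        assert log.of_kind("nod") == []

    def test_nod_uses_deviation_from_calibrated_neutral(self):
        n = 400
        pitch = np.full(n, 8.0)          # non-zero resting pose
        pitch[200:240] = 20.0            # 12 deg above neutral
        log = detect_events(None, np.zeros(n, bool), self.cfg,
                            smoothed_pitch=pitch, fps=30)
        assert len(log.of_kind("nod")) == 1


class TestWindows:
    def test_1800_frames_gives_7_full_windows(self):
        wins = segment_windows(1800, 900, 150)
        assert len(wins) == 7
        assert [w[0] for w in wins] == [0, 150, 300, 450, 600, 750, 900]
        assert all(not w[2] for w in wins)

    def test_exact_window_single(self):
        assert segment_windows(900, 900, 150) == [(0, 900, False)]

    def test_trailing_partial(self):
        wins = segment_windows(1000, 900, 150)
        assert wins == [(0, 900, False), (900, 100, True)]

    def test_short_series_single_partial(self):
        assert segment_windows(100, 900, 150) == [(0, 100, True)]

    def test_summary_counts_and_perclos(self):
        eye = np.zeros(900, bool)
        eye[:90] = True
        log = EventLog(events=[Event("blink", 10, 20), Event("blink", 100, 105),
                               Event("blink", 880, 899), Event("yawn", 200, 260),
                               Event("blink", 950, 960)],
                       eye_state=eye)
        s = window_summary(log, (0, 900, False), fps=30.0)
        assert (s.bf, s.yf, s.nf) == (3, 1, 0)
        assert s.perclos == pytest.approx(0.1)
        assert s.bf_per_min == pytest.approx(6.0)   # 3 events in 30 s

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_summary(EventLog(), (0, 0, False))

    def test_partial_scaling_extrapolates_counts_only(self):
        eye = np.zeros(450, bool)
        eye[:90] = True
        log = EventLog(events=[Event("blink", i, i + 3) for i in (0, 100, 200)],
                       eye_state=eye)
        s = window_summary(log, (0, 450, True), fps=30.0)
        scaled = scale_partial_window(s, 900)
        assert scaled.bf == pytest.approx(6.0)
        assert scaled.perclos == pytest.approx(s.perclos)
        assert scaled.partial

    def test_partial_rate_only_mode_keeps_counts(self):
        log = EventLog(events=[Event("blink", 0, 3)],
                       eye_state=np.zeros(450, bool))
        s = window_summary(log, (0, 450, True))
        assert scale_partial_window(s, 900, mode="rate-only").bf == 1

    def test_zero_events_scale_to_zero(self):
        s = window_summary(EventLog(eye_state=np.zeros(450, bool)),
                           (0, 450, True))
        assert scale_partial_window(s, 900).bf == 0

    @given(st.integers(901, 5000))
    def test_stride_equals_T_counts_are_additive(self, n):
        rng = np.random.default_rng(n)
        starts = np.sort(rng.choice(n - 5, size=8, replace=False))
        log = EventLog(events=[Event("blink", int(s), int(s) + 2) for s in starts],
                       eye_state=np.zeros(n, bool))
        total = sum(window_summary(log, w).bf
                    for w in segment_windows(n, 900, 900))
        assert total == 8

    def test_perclos_of_concatenation_is_frame_weighted_mean(self):
        rng = np.random.default_rng(0)
        eye = rng.random(1300) < 0.3
        log = EventLog(eye_state=eye)
        a = window_summary(log, (0, 900, False))
        b = window_summary(log, (900, 400, True))
        whole = window_summary(log, (0, 1300, False))
        assert whole.perclos == pytest.approx(
            (a.perclos * 900 + b.perclos * 400) / 1300)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [{"alpha": 0.0}, {"alpha": 1.5},
                                    {"stride_S": 0}, {"stride_S": 1000},
                                    {"min_yawn_frames": 0},
                                    {"hysteresis_h": -0.1}])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            DetectorConfig(**kw)
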