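"""Baseline statistics, contraction calling, attribution, habituation."""

import numpy as np
import pytest

from helpers_oracles import scan_contraction_runs
from wormpulse.events import (
    BaselineStats,
    InsufficientDataError,
    attribute_to_stimuli,
    baseline_stats,
    call_contractions,
    chance_attribution_rate,
    habituation_metrics,
    overlay_silhouettes,
)
from wormpulse.posture import PostureTrace
from wormpulse.protocols import LightSchedule


def make_trace(ecc, frame_rate=1.0, valid=None, light=None):
    ecc = np.asarray(ecc, float)
    n = len(ecc)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    return PostureTrace(
        times=np.arange(n) / frame_rate,
        eccentricity=ecc,
        htol=np.full(n, np.nan),
        length_px=np.full(n, np.nan),
        centroid_row=np.zeros(n),
        centroid_col=np.zeros(n),
        valid=valid,
        light_on=np.zeros(n, bool) if light is None else np.asarray(light, bool),
        frame_rate=frame_rate,
    )


class TestBaseline:
    def test_printed_control_statistics_give_0956(self):
        baseline = BaselineStats(mean_ecc=0.978, sd_ecc=0.022, n_worms=5)
        assert baseline.threshold == pytest.approx(0.956, abs=1e-12)

    def test_constant_trace_threshold_equals_mean(self):
        baseline = baseline_stats([make_trace([0.9] * 20)])
        assert baseline.threshold == pytest.approx(0.9)
        assert baseline.sd_ecc == pytest.approx(0.0)

    def test_pooled_two_level_sample(self):
        # half the frames at 0.9, half at 1.0: mean 0.95, SD ~0.05 with the
        # sample (n-1) convention at large n, threshold ~0.90
        n = 500
        baseline = baseline_stats(
            [make_trace([0.9] * n), make_trace([1.0] * n)]
        )
        assert baseline.mean_ecc == pytest.approx(0.95)
        assert baseline.sd_ecc == pytest.approx(0.05, abs=1e-3)
        assert baseline.threshold == pytest.approx(0.90, abs=1e-3)
        assert baseline.n_worms == 2

    def test_no_valid_frames_rejected(self):
        with pytest.raises(InsufficientDataError):
            baseline_stats([make_trace([0.9] * 5, valid=[False] * 5)])


class TestCallContractions:
    BASELINE = BaselineStats(mean_ecc=0.978, sd_ecc=0.022)

    def test_two_separate_dips(self):
        trace = make_trace([0.98, 0.93, 0.98, 0.94, 0.98])
        events = call_contractions(trace, self.BASELINE, merge_window=0.0)
        assert len(events) == 2
        assert events[0].trough_time == 1.0
        assert events[1].trough_time == 3.0
        assert events[0].magnitude == pytest.approx(0.978 - 0.93)

    def test_all_supra_threshold_gives_no_events(self):
        trace = make_trace([0.98, 0.97, 0.99, 0.975])
        assert call_contractions(trace, self.BASELINE) == []

    def test_merge_window_joins_nearby_runs(self):
        trace = make_trace([0.93, 0.98, 0.93, 0.98, 0.98, 0.98, 0.93],
                           frame_rate=1.0)
        merged = call_contractions(trace, self.BASELINE, merge_window=1.5)
        assert len(merged) == 2  # 1-frame gap merges, 3-frame gap does not
        split = call_contractions(trace, self.BASELINE, merge_window=0.0)
        assert len(split) == 3

    def test_invalid_gap_only_splits_when_long(self):
        ecc = [0.93, np.nan, 0.93, 0.98, 0.98, 0.98, 0.98, 0.93]
        valid = [True, False, True, True, True, True, True, True]
        trace = make_trace(ecc, valid=valid)
        events = call_contractions(trace, self.BASELINE, merge_window=1.5)
        assert len(events) == 2

    def test_trough_tie_breaks_to_earliest(self):
        trace = make_trace([0.93, 0.95, 0.93, 0.98])
        (event,) = call_contractions(trace, self.BASELINE, merge_window=5.0)
        assert event.trough_time == 0.0

    def test_matches_brute_force_scanner_on_random_traces(self):
        rng = np.random.default_rng(42)
        baseline = BaselineStats(mean_ecc=0.97, sd_ecc=0.02)
        for _ in range(100):
            n = rng.integers(5, 200)
            ecc = np.clip(rng.normal(0.97, 0.03, n), 0.0, 1.0)
            valid = rng.random(n) > 0.1
            fps = float(rng.choice([1.0, 5.0, 10.0]))
            merge = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            trace = make_trace(ecc, frame_rate=fps, valid=valid)
            events = call_contractions(trace, baseline, merge_window=merge)
            oracle = scan_contraction_runs(
                ecc, valid, trace.times, baseline.threshold, merge, fps
            )
            assert len(events) == len(oracle)
            for ev, ref in zip(events, oracle):
                assert ev.onset_time == pytest.approx(ref["onset_frame"] / fps)
                assert ev.trough_time == pytest.approx(ref["trough_frame"] / fps)
                assert ev.trough_ecc == pytest.approx(ref["trough_ecc"])


class TestAttribution:
    SCHEDULE = LightSchedule.from_intervals([(5.0, 6.0), (14.0, 15.0)], 60.0)

    def test_fast_onset_attributed_with_latency(self):
        trace = make_trace(
            [0.98] * 508 + [0.90] * 20 + [0.98] * 100, frame_rate=100.0
        )
        baseline = BaselineStats(0.978, 0.022)
        events = attribute_to_stimuli(
            call_contractions(trace, baseline), self.SCHEDULE
        )
        assert events[0].stimulus_index == 0
        assert events[0].latency == pytest.approx(0.08)

    def test_event_far_from_any_pulse_unattributed(self):
        trace = make_trace([0.98] * 30 + [0.90] * 3 + [0.98] * 27)  # t=30 s
        baseline = BaselineStats(0.978, 0.022)
        (event,) = attribute_to_stimuli(
            call_contractions(trace, baseline), self.SCHEDULE
        )
        assert event.stimulus_index is None
        assert event.latency is None

    def test_one_event_per_pulse_is_bijective(self):
        ecc = np.full(200, 0.98)
        ecc[51:56] = 0.9  # dip after the 5 s pulse
        ecc[141:146] = 0.9  # dip after the 14 s pulse
        trace = make_trace(ecc, frame_rate=10.0)
        baseline = BaselineStats(0.978, 0.022)
        events = attribute_to_stimuli(
            call_contractions(trace, baseline), self.SCHEDULE
        )
        assert [e.stimulus_index for e in events] == [0, 1]

    def test_negative_windows_rejected(self):
        with pytest.raises(ValueError):
            attribute_to_stimuli([], self.SCHEDULE, max_latency=-1.0)


class TestHabituation:
    def _events(self, magnitudes):
        from wormpulse.events import ContractionEvent

        return [
            ContractionEvent(
                onset_time=float(k),
                trough_time=float(k),
                trough_ecc=0.9,
                magnitude=m,
                duration=1.0,
                stimulus_index=k,
                latency=0.05,
            )
            for k, m in enumerate(magnitudes)
        ]

    def test_linear_decline_slope(self):
        result = habituation_metrics(self._events([0.10, 0.07, 0.04]))
        assert result.slope == pytest.approx(-0.03)
        assert result.magnitudes == (0.10, 0.07, 0.04)

    def test_equal_magnitudes_slope_zero(self):
        assert habituation_metrics(self._events([0.08, 0.08, 0.08])).slope == (
            pytest.approx(0.0)
        )

    def test_too_few_events_signalled(self):
        with pytest.raises(InsufficientDataError):
            habituation_metrics(self._events([0.1]))


class TestChanceRate:
    def test_no_events_gives_zero(self):
        schedule = LightSchedule.from_intervals([(5.0, 6.0)], 60.0)
        assert chance_attribution_rate([], schedule) == 0.0


class TestOverlay:
    def test_linear_spacing_over_31_frames(self):
        masks = np.zeros((31, 8, 8), bool)
        masks[:, 2, 2] = True
        image = overlay_silhouettes(masks, n_overlay=11)
        assert image.shape == (8, 8, 3)
        # the last (white) frame wins at a static pixel
        np.testing.assert_allclose(image[2, 2], [1.0, 1.0, 1.0])

    def test_uses_all_frames_when_counts_match(self):
        masks = np.zeros((11, 6, 6), bool)
        for i in range(11):
            masks[i, i % 6, 0] = True
        image = overlay_silhouettes(masks, n_overlay=11)
        assert (image.sum(axis=2) > 0).sum() == 6

    def test_color_progression_dark_to_light(self):
        masks = np.zeros((11, 4, 4), bool)
        masks[0, 0, 0] = True  # only in the first frame
        masks[10, 3, 3] = True  # only in the last frame
        image = overlay_silhouettes(masks, n_overlay=11)
        assert image[0, 0].sum() < image[3, 3].sum()
        assert image[0, 0, 0] > 0.3 and image[0, 0, 2] < 0.1  # dark red

    def test_too_few_frames_or_n_rejected(self):
        with pytest.raises(ValueError):
            overlay_silhouettes(np.zeros((5, 4, 4), bool), n_overlay=11)
        with pytest.raises(ValueError):
            overlay_silhouettes(np.zeros((5, 4, 4), bool), n_overlay=1)
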