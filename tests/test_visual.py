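"""EAR smoothing, closure detection, PERCLOS, and episode scoring."""

import numpy as np
import pytest

from drowsecov.config import SimulationConfig, VisualScoringParams
from drowsecov.synthetic import generate_ear, generate_timeline
from drowsecov.types import DROWSY, WAKEFUL, ClosureEvent, EarTrace, Episode, EpisodeTimeline
from drowsecov.visual import (
    compute_perclos,
    detect_closures,
    read_episode_csv,
    score_episodes,
    smooth_ear,
    write_episode_csv,
)

FPS = 30.0


def trace(values):
    return EarTrace(FPS, np.asarray(values, dtype=float))


class TestSmoothing:
    def test_constant_trace_preserved(self, scoring_params):
        t = trace(np.full(300, 0.3))
        out = smooth_ear(t, scoring_params)
        assert np.allclose(out.values, 0.3)

    def test_isolated_spike_removed(self, scoring_params):
        v = np.full(300, 0.3)
        v[150] = 1.5
        out = smooth_ear(trace(v), scoring_params)
        # median window 5 rejects the single-frame outlier entirely;
        # the moving average then leaves the constant level
        assert np.all(out.values < 0.35)

    def test_step_output_monotone(self, scoring_params):
        v = np.concatenate([np.full(150, 0.1), np.full(150, 0.3)])
        out = smooth_ear(trace(v), scoring_params)
        assert np.all(np.diff(out.values) >= -1e-12)

    def test_moving_average_matches_direct_convolution(self):
        # oracle: edge-repeating (symmetric) pad then flat-kernel convolution
        params = VisualScoringParams(median_window=1, ma_window=5)
        rng = np.random.default_rng(0)
        v = 0.3 + 0.05 * rng.standard_normal(200)
        out = smooth_ear(trace(v), params)
        k = 5
        padded = np.pad(v, k // 2, mode="symmetric")
        expected = np.convolve(padded, np.ones(k) / k, mode="valid")
        assert np.allclose(out.values, expected)

    def test_window_longer_than_trace_errors(self, scoring_params):
        with pytest.raises(ValueError):
            smooth_ear(trace(np.full(3, 0.3)), scoring_params)


class TestClosureDetection:
    def test_never_below_threshold_empty(self, scoring_params):
        assert detect_closures(trace(np.full(600, 0.3)), scoring_params) == []

    def test_single_dip_one_event(self, scoring_params):
        # baseline 0.30, threshold 0.7 x baseline = 0.21; 15-frame dip to 0.05
        v = np.full(1200, 0.30)
        v[600:615] = 0.05
        events = detect_closures(trace(v), scoring_params)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_frame, ev.end_frame) == (600, 614)
        assert np.isclose(ev.duration, 15 / FPS)

    def test_dips_split_by_single_open_frame_not_merged(self, scoring_params):
        v = np.full(1200, 0.30)
        v[600:610] = 0.05
        v[610] = 0.30  # one open frame between dips
        v[611:621] = 0.05
        events = detect_closures(trace(v), scoring_params)
        assert len(events) == 2

    def test_runs_shorter_than_min_blink_discarded(self):
        params = VisualScoringParams(min_blink_frames=5)
        v = np.full(600, 0.30)
        v[300:303] = 0.05  # 3 frames < 5
        assert detect_closures(trace(v), params) == []


class TestPerclos:
    def test_no_closures_all_zero(self):
        out = compute_perclos([], window=30.0, fps=FPS, n_frames=1800)
        assert np.allclose(out, 0.0)

    def test_fully_closed_window_is_one(self):
        out = compute_perclos(
            [ClosureEvent(0, 1799, 1800 / FPS)], window=60.0, fps=FPS, n_frames=1800
        )
        assert np.allclose(out, 1.0)

    def test_fraction_is_count_ratio(self):
        # 360 closed frames in an 1800-frame window -> 0.2
        out = compute_perclos(
            [ClosureEvent(0, 359, 360 / FPS)], window=60.0, fps=FPS, n_frames=1800
        )
        assert np.allclose(out, [0.2])

    def test_bounds(self):
        out = compute_perclos(
            [ClosureEvent(100, 700, 601 / FPS)], window=10.0, fps=FPS, n_frames=3000
        )
        assert np.all((out >= 0) & (out <= 1))

    def test_subframe_window_errors(self):
        with pytest.raises(ValueError):
            compute_perclos([], window=0.001, fps=FPS, n_frames=100)


class TestScoring:
    def test_fully_open_trace_single_wakeful_episode(self, scoring_params):
        tl = score_episodes(trace(np.full(30 * 120, 0.3)), scoring_params)
        assert len(tl) == 1
        assert tl.episodes[0].label == WAKEFUL

    def test_empty_trace_errors(self, scoring_params):
        with pytest.raises(ValueError):
            score_episodes(EarTrace(FPS, np.array([])), scoring_params)

    @pytest.mark.parametrize("seed", [1, 8])
    def test_output_alternates_and_covers_trace(self, scoring_params, seed):
        cfg = SimulationConfig(
            session_length=420.0,
            episode_duration_range_wakeful=(60.0, 90.0),
            episode_duration_range_drowsy=(45.0, 75.0),
            seed=seed,
        )
        tl = generate_timeline(cfg)
        ear = generate_ear(tl, cfg)
        scored = score_episodes(ear, scoring_params)
        labels = scored.labels
        assert np.all(labels[1:] != labels[:-1])
        assert scored.start == 0.0
        assert np.isclose(scored.end, ear.duration, atol=1.0)

    def test_recovers_generated_labels_within_window(self, scoring_params):
        cfg = SimulationConfig(
            session_length=420.0,
            episode_duration_range_wakeful=(60.0, 90.0),
            episode_duration_range_drowsy=(45.0, 75.0),
            seed=2,
        )
        tl = generate_timeline(cfg)
        scored = score_episodes(generate_ear(tl, cfg), scoring_params)
        # every generated episode midpoint carries the right label, and
        # boundaries are off by at most one PERCLOS window
        for e in tl:
            mid = (e.start + e.end) / 2
            assert scored.label_at(mid) == e.label
        gen_bounds = [e.start for e in tl][1:]
        for b in gen_bounds:
            nearest = min(abs(b - x.start) for x in scored.episodes[1:])
            assert nearest <= scoring_params.perclos_window


class TestEpisodeCsv:
    def timeline(self):
        return EpisodeTimeline([
            Episode(0, 60, 1), Episode(60, 90, 0),
            Episode(90, 150, 1), Episode(150, 180, 0),
        ])

    def test_round_trip_identity(self, tmp_path):
        tl = self.timeline()
        p = tmp_path / "episodes.csv"
        write_episode_csv(tl, p)
        back = read_episode_csv(p)
        assert [(e.start, e.end, e.label) for e in back] == [
            (e.start, e.end, e.label) for e in tl
        ]

    def test_rows_follow_odd_wakeful_convention(self, tmp_path):
        p = tmp_path / "episodes.csv"
        write_episode_csv(self.timeline(), p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 5  # header + 4 episodes
        assert [ln.split(",")[2] for ln in lines[1:]] == ["1", "0", "1", "0"]

    def test_drowsy_first_rejected(self, tmp_path):
        tl = EpisodeTimeline([Episode(0, 30, 0), Episode(30, 90, 1)])
        with pytest.raises(ValueError, match="wakeful"):
            write_episode_csv(tl, tmp_path / "bad.csv")

    def test_malformed_csv_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_episode_csv(p)
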