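"""Visual-based episode scoring from eye-aspect-ratio traces.

The scoring chain mirrors the standard PERCLOS/CLOSDUR practice:
median-filter the EAR trace, smooth with a moving average, threshold
adaptively against a rolling-median baseline, extract maximal closure
runs, then label non-overlapping windows drowsy when PERCLOS exceeds a
cutoff *and* the window contains a long-enough closure. The output is
an alternating wakeful/drowsy timeline — the reference labels for all
EEG stages.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import VisualScoringParams
from .types import DROWSY, WAKEFUL, ClosureEvent, EarTrace, Episode, EpisodeTimeline


def smooth_ear(trace: EarTrace, params: VisualScoringParams) -> EarTrace:
    """Median filter then centred moving average (reflect padding)."""
    n = len(trace)
    if params.median_window >= n or params.ma_window >= n:
        raise ValueError("smoothing window must be shorter than the trace")
    x = ndimage.median_filter(trace.values, size=params.median_window, mode="reflect")
    x = ndimage.uniform_filter1d(x, size=params.ma_window, mode="reflect")
    return EarTrace(trace.fps, np.clip(x, 0.0, None))


def adaptive_threshold(trace: EarTrace, params: VisualScoringParams) -> np.ndarray:
    """Per-frame threshold: a fraction of the rolling open-eye baseline.

    The baseline is the rolling maximum, over ``adaptive_baseline_window``,
    of a short rolling median (``adaptive_median_s``). The short median
    rejects individual blink dips; the maximum then tracks the open-eye
    level even through spans where the eye is closed more than half the
    time, where a plain long-window median would collapse to the closed
    level.
    """
    med_win = int(round(params.adaptive_median_s * trace.fps))
    med_win = max(3, min(med_win, len(trace)))
    win = int(round(params.adaptive_baseline_window * trace.fps))
    win = max(3, min(win, len(trace)))
    med = ndimage.median_filter(trace.values, size=med_win, mode="reflect")
    baseline = ndimage.maximum_filter1d(med, size=win, mode="reflect")
    return params.adaptive_fraction * baseline


def detect_closures(trace: EarTrace, params: VisualScoringParams) -> list[ClosureEvent]:
    """Maximal runs of frames strictly below the adaptive threshold.

    Runs shorter than ``min_blink_frames`` are discarded; runs separated
    by even a single above-threshold frame are never merged.
    """
    thr = adaptive_threshold(trace, params)
    below = trace.values < thr
    if not below.any():
        return []
    padded = np.concatenate([[False], below, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1  # inclusive
    events = []
    for s, e in zip(starts, ends):
        if e - s + 1 >= params.min_blink_frames:
            events.append(ClosureEvent(int(s), int(e), (e - s + 1) / trace.fps))
    return events


def closed_frame_mask(closures: list[ClosureEvent], n_frames: int) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for ev in closures:
        mask[ev.start_frame:ev.end_frame + 1] = True
    return mask


def compute_perclos(closures: list[ClosureEvent], window: float, fps: float,
                    n_frames: int | None = None) -> np.ndarray:
    """Fraction of closed frames per non-overlapping window.

    ``n_frames`` fixes the trace length; when omitted it is inferred
    from the last closure.
    """
    wlen = int(round(window * fps))
    if wlen < 1:
        raise ValueError("PERCLOS window shorter than one frame")
    if n_frames is None:
        n_frames = max((ev.end_frame + 1 for ev in closures), default=wlen)
    mask = closed_frame_mask(closures, n_frames)
    n_windows = max(1, int(np.ceil(n_frames / wlen)))
    out = np.empty(n_windows)
    for i in range(n_windows):
        chunk = mask[i * wlen:(i + 1) * wlen]
        out[i] = chunk.mean() if len(chunk) else 0.0
    return out


def score_episodes(trace: EarTrace, params: VisualScoringParams) -> EpisodeTimeline:
    """Emit an alternating wakeful/drowsy timeline covering the trace.

    A window is candidate-drowsy when PERCLOS >= the cutoff AND it
    contains at least one closure of duration >= ``closdur_min``.
    Adjacent same-label windows merge; episodes shorter than
    ``min_episode_duration`` are absorbed into a neighbour.
    """
    if len(trace) == 0:
        raise ValueError("cannot score an empty trace")
    smoothed = smooth_ear(trace, params)
    closures = detect_closures(smoothed, params)
    fps = trace.fps
    n = len(trace)
    wlen = int(round(params.perclos_window * fps))
    perclos = compute_perclos(closures, params.perclos_window, fps, n_frames=n)

    long_starts = np.array(
        [ev.start_frame for ev in closures if ev.duration >= params.closdur_min],
        dtype=int,
    )
    n_windows = len(perclos)
    window_labels = np.full(n_windows, WAKEFUL, dtype=int)
    for i in range(n_windows):
        lo, hi = i * wlen, min((i + 1) * wlen, n)
        has_long = np.any((long_starts >= lo) & (long_starts < hi))
        if perclos[i] >= params.perclos_drowsy_cutoff and has_long:
            window_labels[i] = DROWSY

    # windows -> merged intervals
    intervals: list[list] = []  # [start_s, end_s, label]
    for i, lab in enumerate(window_labels):
        start_s = i * wlen / fps
        end_s = min((i + 1) * wlen, n) / fps
        if intervals and intervals[-1][2] == lab:
            intervals[-1][1] = end_s
        else:
            intervals.append([start_s, end_s, int(lab)])

    # absorb too-short intervals into the longer neighbour
    def absorb(iv: list[list]) -> list[list]:
        while len(iv) > 1:
            durations = [e - s for s, e, _ in iv]
            i = int(np.argmin(durations))
            if durations[i] >= params.min_episode_duration - 1e-6:
                break
            if i == 0:
                iv[1][0] = iv[0][0]
                del iv[0]
            elif i == len(iv) - 1:
                iv[-2][1] = iv[-1][1]
                del iv[-1]
            else:
                prev_d = iv[i - 1][1] - iv[i - 1][0]
                next_d = iv[i + 1][1] - iv[i + 1][0]
                if prev_d >= next_d:
                    iv[i - 1][1] = iv[i][1]
                else:
                    iv[i + 1][0] = iv[i][0]
                del iv[i]
            # merge newly adjacent same-label intervals
            j = 0
            while j < len(iv) - 1:
                if iv[j][2] == iv[j + 1][2]:
                    iv[j][1] = iv[j + 1][1]
                    del iv[j + 1]
                else:
                    j += 1
        return iv

    intervals = absorb(intervals)
    return EpisodeTimeline([Episode(s, e, lab) for s, e, lab in intervals])


# ---------------------------------------------------------------------------
# Episode CSV dialect
# ---------------------------------------------------------------------------
# One row per episode, columns start_s, end_s, label; label 1 (wakeful)
# on odd 1-based data rows, 0 (drowsy) on even rows.

def write_episode_csv(timeline: EpisodeTimeline, path: str | Path) -> None:
    if timeline.episodes[0].label != WAKEFUL:
        raise ValueError("episode CSV convention requires a wakeful first episode")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "label"])
        for ep in timeline:
            w.writerow([f"{ep.start:.6f}", f"{ep.end:.6f}", ep.label])


def read_episode_csv(path: str | Path) -> EpisodeTimeline:
    episodes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"start_s", "end_s", "label"} <= set(reader.fieldnames):
            raise ValueError(f"malformed episode CSV {path}: missing columns")
        for row in reader:
            episodes.append(
                Episode(float(row["start_s"]), float(row["end_s"]), int(row["label"]))
            )
    if not episodes:
        raise ValueError(f"episode CSV {path} contains no episodes")
    return EpisodeTimeline(episodes)
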