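"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes:
alternating wakeful/drowsy episodes of variable duration; six-channel
EEG built from band-limited Gaussian noise whose delta/theta/alpha/beta
powers shift with the behavioural state (theta rises, alpha falls when
drowsy); and eye-aspect-ratio traces in which blink rate and closure
duration rise during drowsy episodes.

Everything is a pure function of ``(config, subject index)``: each
operation draws from its own `numpy` Generator seeded from
``[config.seed, subject, stream]`` so cohorts are bit-reproducible.

Two mechanisms make channels imperfect and distinguishable:

* broadband white noise of sd ``noise_sd * channel_noise_scale[ch]``;
* a per-episode lognormal jitter on every band weight with log-sd
  ``band_weight_jitter * noise_sd * channel_noise_scale[ch]``.

With ``noise_sd = 0`` both vanish and every drowsy episode's
theta/alpha ratio exceeds both neighbours' by construction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .config import BANDS, CHANNELS, SimulationConfig
from .types import DROWSY, WAKEFUL, EarTrace, EegRecording, Episode, EpisodeTimeline

_STREAM_TIMELINE, _STREAM_EEG, _STREAM_EAR = 0, 1, 2

_STATE_NAME = {WAKEFUL: "wakeful", DROWSY: "drowsy"}


def _rng(config: SimulationConfig, subject: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, subject, stream])


# ---------------------------------------------------------------------------
# Episode timeline
# ---------------------------------------------------------------------------

def generate_timeline(config: SimulationConfig, subject: int = 0) -> EpisodeTimeline:
    """Alternating wakeful/drowsy episodes covering [0, session_length].

    Durations are drawn uniformly from the per-state ranges; when the
    remaining session time could not fit the next state's minimum
    duration, the current episode is extended to the session end, so
    the timeline partitions the session exactly and every episode
    respects its state's minimum duration.
    """
    ranges = {
        WAKEFUL: config.episode_duration_range_wakeful,
        DROWSY: config.episode_duration_range_drowsy,
    }
    min_pair = ranges[WAKEFUL][0] + ranges[DROWSY][0]
    if config.session_length < min_pair:
        raise ValueError(
            f"session_length {config.session_length} s is shorter than one "
            f"minimal wakeful+drowsy episode pair ({min_pair} s)"
        )
    rng = _rng(config, subject, _STREAM_TIMELINE)
    label = WAKEFUL if config.first_label == "wakeful" else DROWSY
    episodes: list[Episode] = []
    t = 0.0
    while t < config.session_length:
        lo, hi = ranges[label]
        other_lo = ranges[WAKEFUL if label == DROWSY else DROWSY][0]
        dur = float(rng.uniform(lo, hi))
        end = t + dur
        if config.session_length - end < other_lo:
            end = config.session_length
        episodes.append(Episode(t, end, label))
        t = end
        label = WAKEFUL if label == DROWSY else DROWSY
    return EpisodeTimeline(episodes)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (zero-phase)."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_envelope(step: np.ndarray, fs: float, crossfade_s: float) -> np.ndarray:
    """Smooth a piecewise-constant envelope with a Hann kernel (<= crossfade)."""
    width = int(round(crossfade_s * fs))
    if width < 2:
        return step
    win = np.hanning(width + 2)[1:-1]
    win /= win.sum()
    padded = np.pad(step, width, mode="edge")
    return np.convolve(padded, win, mode="same")[width:-width]


def generate_eeg(timeline: EpisodeTimeline, config: SimulationConfig,
                 subject: int = 0) -> EegRecording:
    """Six-channel EEG whose band powers follow the episode states.

    Each channel sums four band-limited noise components, amplitude-
    scaled per episode by sqrt of the state's (jittered) band weight,
    cross-faded over <= 1 s at episode boundaries, plus broadband noise;
    a per-channel gain perturbation makes channels differ in scale.
    """
    for state, weights in config.band_power_profile.items():
        if all(w == 0 for w in weights.values()):
            raise ValueError(f"band power weights for state {state!r} are all zero")

    fs = config.eeg_fs
    n = int(round(timeline.end * fs))
    rng = _rng(config, subject, _STREAM_EEG)
    bounds = [int(round(e.start * fs)) for e in timeline] + [n]

    data = np.empty((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        nscale = config.noise_scale(ch)
        sigma = config.band_weight_jitter * config.noise_sd * nscale
        x = np.zeros(n)
        for band_name, band in BANDS.items():
            carrier = _band_noise(rng, n, fs, band)
            step = np.empty(n)
            for ei, ep in enumerate(timeline):
                w = config.band_power_profile[_STATE_NAME[ep.label]].get(band_name, 0.0)
                if sigma > 0 and w > 0:
                    w = w * float(np.exp(rng.normal(0.0, sigma)))
                step[bounds[ei]:bounds[ei + 1]] = np.sqrt(w)
            env = _smooth_envelope(step, fs, config.crossfade_s)
            x += env * carrier
        if config.noise_sd > 0:
            x += config.noise_sd * nscale * rng.standard_normal(n)
        gain = 1.0 + config.channel_gain_sd * float(rng.standard_normal())
        data[ci] = config.eeg_scale_uv * gain * x
    return EegRecording(list(CHANNELS), fs, data)


# ---------------------------------------------------------------------------
# Eye aspect ratio
# ---------------------------------------------------------------------------

def generate_ear(timeline: EpisodeTimeline, config: SimulationConfig,
                 subject: int = 0) -> EarTrace:
    """EAR trace with state-dependent blink rate and closure duration.

    Blinks are trapezoidal dips (fall ~100 ms, hold = closure duration,
    rise ~100 ms) from the open-eye baseline to the closed level.
    Blink trains are quasi-periodic: the per-episode count is the
    expected rate x duration with mild lognormal variation, and centres
    are evenly spaced with jitter, as in real blinking — so an
    episode's blink statistics express its state's profile reliably.
    When ``min_drowsy_closure_s`` is set, every drowsy episode contains
    at least one closure of that duration.
    """
    fps = config.ear_fps
    n = int(round(timeline.end * fps))
    rng = _rng(config, subject, _STREAM_EAR)
    open_values = config.ear_baseline + config.ear_jitter_sd * rng.standard_normal(n)
    depth = np.zeros(n)  # 0 open .. 1 closed
    ramp = max(1, int(round(config.blink_ramp_s * fps)))

    def insert(center_f: float, hold_frames: int) -> None:
        half = hold_frames / 2
        lo = int(round(center_f - half))
        hi = lo + hold_frames  # [lo, hi) fully closed
        prof_lo = lo - ramp
        idx = np.arange(prof_lo, hi + ramp)
        prof = np.ones(len(idx))
        prof[:ramp] = np.linspace(0, 1, ramp + 1)[1:]
        prof[-ramp:] = np.linspace(1, 0, ramp + 1)[:-1]
        valid = (idx >= 0) & (idx < n)
        np.maximum.at(depth, idx[valid], prof[valid])

    for ep in timeline:
        prof = config.blink_profile[_STATE_NAME[ep.label]]
        rate = float(prof["rate_per_min"])
        mean_s = float(prof["closure_mean_s"])
        sd_s = float(prof.get("closure_sd_s", 0.0))
        if rate * mean_s / 60.0 > 1.0:
            raise ValueError(
                f"blink rate x closure duration exceeds episode length for "
                f"state {_STATE_NAME[ep.label]!r}"
            )
        lam = rate * ep.duration / 60.0
        count = int(round(lam * float(np.exp(rng.normal(0.0, 0.15))))) if rate > 0 else 0
        durs = np.clip(rng.normal(mean_s, sd_s, size=count), 2.0 / fps, None)
        if (
            ep.label == DROWSY
            and config.min_drowsy_closure_s is not None
            and ep.duration > 2 * config.min_drowsy_closure_s
        ):
            if count == 0:
                durs = np.array([config.min_drowsy_closure_s])
            elif durs.max() < config.min_drowsy_closure_s:
                durs[np.argmax(durs)] = config.min_drowsy_closure_s
        n_blinks = len(durs)
        for k, d in enumerate(durs):
            margin = d / 2 + config.blink_ramp_s
            lo_t, hi_t = ep.start + margin, ep.end - margin
            if hi_t <= lo_t:
                continue
            spacing = ep.duration / n_blinks
            center = ep.start + (k + 0.5) * spacing + float(
                rng.uniform(-0.3, 0.3)
            ) * spacing
            center = float(np.clip(center, lo_t, hi_t))
            insert(center * fps, max(1, int(round(d * fps))))

    values = open_values * (1 - depth) + config.ear_closed * depth
    return EarTrace(fps, np.clip(values, 0.0, None))


# ---------------------------------------------------------------------------
# Subject / cohort convenience and EAR CSV dialect
# ---------------------------------------------------------------------------

def generate_subject(config: SimulationConfig, subject: int = 0):
    """(timeline, eeg, ear) triple for one subject."""
    timeline = generate_timeline(config, subject)
    return timeline, generate_eeg(timeline, config, subject), generate_ear(
        timeline, config, subject
    )


def write_ear_csv(trace: EarTrace, path: str | Path) -> None:
    idx = np.arange(len(trace))
    pd.DataFrame(
        {"frame_index": idx, "time_s": idx / trace.fps, "ear": trace.values}
    ).to_csv(path, index=False)


def read_ear_csv(path: str | Path) -> EarTrace:
    df = pd.read_csv(path)
    for col in ("frame_index", "time_s", "ear"):
        if col not in df.columns:
            raise ValueError(f"EAR CSV missing column {col!r}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("EAR CSV must contain at least two frames")
    # round away float noise in the reconstructed frame interval
    fps = round(1.0 / float(np.median(np.diff(t))), 3)
    return EarTrace(fps, df["ear"].to_numpy(dtype=float))
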