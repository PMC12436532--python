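"""Simulation and scoring configuration.

All tunables of the synthetic cohort generator and the visual-scoring
stage live here so that an analysis run is fully described by one YAML
(or JSON) file plus a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: The six unipolar channels of the recording montage (10-20 system,
#: referenced to the mastoids), in canonical order.
CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "O1", "O2")

#: EEG frequency bands (Hz) used throughout.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.5),
    "alpha": (7.5, 15.0),
    "beta": (15.0, 30.0),
}


def _default_band_power_profile() -> dict:
    # Drowsiness raises theta (x2) and lowers alpha (x0.5) relative to
    # wakefulness; delta rises mildly, beta is unchanged.
    return {
        "wakeful": {"delta": 0.6, "theta": 0.4, "alpha": 1.0, "beta": 0.3},
        "drowsy": {"delta": 0.8, "theta": 0.8, "alpha": 0.5, "beta": 0.3},
    }


def _default_blink_profile() -> dict:
    # Wakeful: frequent short blinks; drowsy: slower, long closures.
    return {
        "wakeful": {"rate_per_min": 15.0, "closure_mean_s": 0.15, "closure_sd_s": 0.05},
        "drowsy": {"rate_per_min": 10.0, "closure_mean_s": 2.5, "closure_sd_s": 0.8},
    }


@dataclass
class SimulationConfig:
    """Conditions under which a synthetic cohort is generated.

    Defaults emulate the acquisition setup of the study design this
    package implements: 50-min sessions, 200 Hz six-channel EEG, 30 fps
    eye-aspect-ratio traces, and alternating wakeful/drowsy episodes at
    roughly 18 episodes per 50 minutes.
    """

    n_subjects: int = 10
    session_length: float = 3000.0  # seconds (50-min session)
    episode_duration_range_wakeful: tuple[float, float] = (90.0, 240.0)
    episode_duration_range_drowsy: tuple[float, float] = (60.0, 180.0)
    eeg_fs: float = 200.0  # Hz
    ear_fps: float = 30.0  # frames/s
    band_power_profile: dict = field(default_factory=_default_band_power_profile)
    blink_profile: dict = field(default_factory=_default_blink_profile)
    noise_sd: float = 1.0  # dimensionless overall noise level
    #: Log-scale sd of the per-episode, per-band lognormal weight jitter,
    #: expressed per unit noise_sd; drives imperfect channel coverage.
    band_weight_jitter: float = 0.6
    #: Per-channel multiplier on both the broadband noise and the weight
    #: jitter; < 1 means a cleaner (higher-SNR) channel.
    channel_noise_scale: dict = field(default_factory=dict)
    #: Per-channel multiplicative gain perturbation sd (channels differ).
    channel_gain_sd: float = 0.05
    seed: int = 0
    first_label: str = "wakeful"
    # EAR morphology
    ear_baseline: float = 0.30
    ear_closed: float = 0.05
    ear_jitter_sd: float = 0.01
    blink_ramp_s: float = 0.1  # trapezoid fall/rise time
    #: When set, every drowsy episode is guaranteed at least one closure
    #: of this duration (seconds); None disables the guarantee.
    min_drowsy_closure_s: float | None = 1.0
    #: Amplitude scale mapping unit-variance synthetic EEG to microvolts.
    eeg_scale_uv: float = 20.0
    crossfade_s: float = 1.0

    def __post_init__(self) -> None:
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")
        for rng in (self.episode_duration_range_wakeful, self.episode_duration_range_drowsy):
            lo, hi = rng
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid episode duration range {rng!r}")
        if self.eeg_fs <= 0 or self.ear_fps <= 0:
            raise ValueError("sampling rates must be positive")
        for state, weights in self.band_power_profile.items():
            for band, w in weights.items():
                if w < 0:
                    raise ValueError(f"negative band power weight {state}/{band}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.first_label not in ("wakeful", "drowsy"):
            raise ValueError("first_label must be 'wakeful' or 'drowsy'")

    def noise_scale(self, channel: str) -> float:
        return float(self.channel_noise_scale.get(channel, 1.0))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("episode_duration_range_wakeful", "episode_duration_range_drowsy"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class VisualScoringParams:
    """Parameters of the eye-aspect-ratio scoring chain.

    The chain is: median filter -> moving average -> adaptive threshold
    (a fraction of a rolling-median baseline) -> closure run detection
    -> PERCLOS / CLOSDUR windowing -> alternating episode output.
    """

    median_window: int = 5  # frames, odd
    ma_window: int = 5  # frames
    #: Span of the rolling open-eye baseline estimate. The baseline is
    #: the rolling maximum, over this window, of a short rolling median
    #: (``adaptive_median_s``): the short median rejects blink dips and
    #: the max recovers the open-eye level even in spans where the eye
    #: is closed most of the time.
    adaptive_baseline_window: float = 60.0  # seconds
    adaptive_median_s: float = 2.0  # seconds
    adaptive_fraction: float = 0.7  # of rolling baseline
    min_blink_frames: int = 3
    perclos_window: float = 30.0  # seconds
    perclos_drowsy_cutoff: float = 0.15
    closdur_min: float = 1.0  # seconds
    min_episode_duration: float = 30.0  # seconds

    def __post_init__(self) -> None:
        if self.median_window <= 0 or self.median_window % 2 == 0:
            raise ValueError("median_window must be a positive odd frame count")
        if self.ma_window <= 0 or self.min_blink_frames <= 0:
            raise ValueError("windows must be positive")
        if self.adaptive_baseline_window <= 0 or self.perclos_window <= 0:
            raise ValueError("windows must be positive")
        if not 0 < self.adaptive_fraction < 1:
            raise ValueError("adaptive_fraction must be in (0, 1)")
        if not 0 < self.perclos_drowsy_cutoff < 1:
            raise ValueError("perclos_drowsy_cutoff must be in (0, 1)")
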