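"""Core containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WAKEFUL = 1
DROWSY = 0


@dataclass(frozen=True)
class Episode:
    start: float  # seconds
    end: float  # seconds
    label: int  # 1 wakeful, 0 drowsy

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"episode end {self.end} <= start {self.start}")
        if self.label not in (WAKEFUL, DROWSY):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EpisodeTimeline:
    """Ordered, contiguous, strictly alternating wakeful/drowsy intervals."""

    episodes: list[Episode]

    def __post_init__(self) -> None:
        eps = self.episodes
        if not eps:
            raise ValueError("timeline must contain at least one episode")
        for a, b in zip(eps, eps[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError(f"episodes not contiguous at {a.end} / {b.start}")
            if a.label == b.label:
                raise ValueError("episode labels must strictly alternate")

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.episodes], dtype=int)

    @property
    def start(self) -> float:
        return self.episodes[0].start

    @property
    def end(self) -> float:
        return self.episodes[-1].end

    def label_at(self, t: float) -> int:
        """State label at time ``t`` (end-inclusive for the last episode)."""
        for e in self.episodes:
            if e.start <= t < e.end:
                return e.label
        if np.isclose(t, self.end):
            return self.episodes[-1].label
        raise ValueError(f"time {t} outside timeline [{self.start}, {self.end}]")


@dataclass
class EegRecording:
    """Multichannel EEG; ``data`` is (n_channels, n_samples) in microvolts."""

    channel_names: list[str]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None
        return self.data[idx]


@dataclass
class EarTrace:
    """Eye-aspect-ratio series; dimensionless, open-eye baseline near 0.3."""

    fps: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("EAR values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.fps


@dataclass(frozen=True)
class ClosureEvent:
    """A maximal run of frames with the eye closed."""

    start_frame: int
    end_frame: int  # inclusive
    duration: float  # seconds, (end - start + 1) / fps

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("closure end before start")


@dataclass
class EpochSet:
    """Per subject x channel: EEG segments aligned to scored episodes."""

    subject_id: str
    channel_name: str
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    samples: list[np.ndarray] = field(default_factory=list)
    durations: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __len__(self) -> int:
        return len(self.samples)
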