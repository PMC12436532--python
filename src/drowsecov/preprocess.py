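"""EEG preprocessing: EDF reading, FIR band-limiting, epoch segmentation.

The band-limiting stage chains an equiripple high-pass (1 Hz cutoff,
rejecting eye-blink drift) and low-pass (30 Hz cutoff, rejecting EMG),
each of order 25 and applied forward-backward so episode timestamps are
not shifted. At 200 Hz an order-25 FIR cannot make a sub-hertz
transition steep; the designed response is gentle there, which the
feature stage tolerates because all downstream logic uses within-epoch
power *contrasts*, not absolute low-frequency attenuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .config import CHANNELS
from .types import EegRecording, EpisodeTimeline, EpochSet


@dataclass
class FilterSpec:
    """Equiripple FIR pair: high-pass then low-pass, zero phase."""

    order: int = 25
    hp_cutoff: float = 1.0
    lp_cutoff: float = 30.0
    hp_stop_edge: float = 0.5
    lp_stop_edge: float = 35.0
    #: (stopband, passband) remez weights; the high-pass weighting keeps
    #: the passband flat despite the narrow transition.
    hp_weight: tuple[float, float] = (1.0, 20.0)
    lp_weight: tuple[float, float] = (10.0, 1.0)

    def validate(self, fs: float) -> None:
        if not 0 < self.hp_stop_edge < self.hp_cutoff < self.lp_cutoff < self.lp_stop_edge < fs / 2:
            raise ValueError("filter edges must satisfy 0 < hp_stop < hp < lp < lp_stop < fs/2")

    def _numtaps(self) -> int:
        nt = self.order + 1
        # a high-pass needs a type-I (odd-tap) FIR; bump like firpm does
        return nt + 1 if nt % 2 == 0 else nt

    def design(self, fs: float) -> tuple[np.ndarray, np.ndarray]:
        """(high-pass taps, low-pass taps) for sampling rate ``fs``."""
        self.validate(fs)
        nt = self._numtaps()
        hp = signal.remez(
            nt, [0, self.hp_stop_edge, self.hp_cutoff, fs / 2], [0, 1],
            weight=list(self.hp_weight), fs=fs,
        )
        lp = signal.remez(
            nt, [0, self.lp_cutoff, self.lp_stop_edge, fs / 2], [1, 0],
            weight=list(self.lp_weight), fs=fs,
        )
        return hp, lp


def read_edf(path: str | Path) -> EegRecording:
    """Read an EDF and normalize channels to F3,F4,C3,C4,O1,O2 order.

    Channel matching is case-insensitive and tolerates reference
    suffixes ("F4-M1") and "EEG " prefixes. Samples are returned in
    microvolts.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # unreadable file
        raise ValueError(f"could not read EDF {path}: {exc}") from exc

    def canonical(label: str) -> str:
        lab = label.upper().strip()
        if lab.startswith("EEG"):
            lab = lab[3:].strip()
        return lab.split("-")[0].strip()

    lookup: dict[str, str] = {}
    for name in raw.ch_names:
        lookup.setdefault(canonical(name), name)
    missing = [ch for ch in CHANNELS if ch not in lookup]
    if missing:
        raise ValueError(f"EDF {path} is missing channel(s): {', '.join(missing)}")

    fs = float(raw.info["sfreq"])
    data = np.vstack([raw.get_data(picks=[lookup[ch]])[0] for ch in CHANNELS])
    return EegRecording(list(CHANNELS), fs, data * 1e6)  # volts -> microvolts


def bandlimit(recording: EegRecording, spec: FilterSpec | None = None) -> EegRecording:
    """Apply the high-pass/low-pass FIR pair forward-backward per channel."""
    spec = spec or FilterSpec()
    if recording.fs <= 2 * spec.lp_cutoff:
        raise ValueError(
            f"sampling rate {recording.fs} Hz too low for a {spec.lp_cutoff} Hz low-pass"
        )
    hp, lp = spec.design(recording.fs)
    out = np.empty_like(recording.data)
    for i, x in enumerate(recording.data):
        y = signal.filtfilt(hp, [1.0], x)
        out[i] = signal.filtfilt(lp, [1.0], y)
    return EegRecording(list(recording.channel_names), recording.fs, out)


def segment_epochs(recording: EegRecording, timeline: EpisodeTimeline,
                   subject_id: str = "S0") -> dict[str, EpochSet]:
    """Cut each channel into one epoch per episode.

    Episode (start, end) maps to samples [floor(start*fs), floor(end*fs))
    — 0-based, half-open, so contiguous episodes partition the recording
    with no duplicated samples.
    """
    fs = recording.fs
    if timeline.end > recording.duration + 0.5 / fs:
        raise ValueError(
            f"timeline extends to {timeline.end} s past recording end "
            f"({recording.duration} s)"
        )
    out: dict[str, EpochSet] = {}
    for ch in recording.channel_names:
        x = recording.channel(ch)
        samples, durations, labels = [], [], []
        for ep in timeline:
            lo = int(np.floor(ep.start * fs))
            hi = int(np.floor(ep.end * fs))
            hi = min(hi, recording.n_samples)
            if ep.duration < 1.0:
                warnings.warn(
                    f"epoch [{ep.start}, {ep.end}) shorter than 1 s; retained",
                    stacklevel=2,
                )
            samples.append(x[lo:hi])
            durations.append(ep.duration)
            labels.append(ep.label)
        out[ch] = EpochSet(
            subject_id=subject_id,
            channel_name=ch,
            labels=np.array(labels, dtype=int),
            samples=samples,
            durations=np.array(durations),
        )
    return out
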