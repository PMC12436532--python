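"""Minimal EDF (European Data Format) writer.

Writes continuous multichannel recordings as standard 16-bit EDF with
one-second data records, enough for any EDF reader to consume the
synthetic cohort. Physical units are microvolts; per-channel physical
ranges are fitted to the data, so round-trip error is bounded by the
16-bit quantization step.
"""

from __future__ import annotations

import datetime
import math
from pathlib import Path

import numpy as np

from .types import EegRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(recording: EegRecording, path: str | Path,
              patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write ``recording`` to ``path`` as 16-bit EDF with 1-s records.

    Requires an integer sampling rate; the last partial record, if any,
    is zero-padded.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal
    ns = len(recording.channel_names)
    n = recording.n_samples
    n_records = max(1, math.ceil(n / spr))

    # physical range per channel, symmetric and non-degenerate
    phys_max = np.maximum(np.abs(recording.data).max(axis=1), 1e-3)
    phys_min = -phys_max

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _ascii("0", 8),
        _ascii(patient_id, 80),
        _ascii(recording_id, 80),
        _ascii(now.strftime("%d.%m.%y"), 8),
        _ascii(now.strftime("%H.%M.%S"), 8),
        _ascii(str(256 * (ns + 1)), 8),
        _ascii("", 44),
        _ascii(str(n_records), 8),
        _ascii("1", 8),
        _ascii(str(ns), 4),
    ])

    def field(values: list[str], width: int) -> bytes:
        return b"".join(_ascii(v, width) for v in values)

    labels = [f"EEG {ch}" for ch in recording.channel_names]
    header += field(labels, 16)
    header += field([""] * ns, 80)  # transducer
    header += field(["uV"] * ns, 8)
    header += field([f"{v:.6g}" for v in phys_min], 8)
    header += field([f"{v:.6g}" for v in phys_max], 8)
    header += field([str(_DIG_MIN)] * ns, 8)
    header += field([str(_DIG_MAX)] * ns, 8)
    header += field([""] * ns, 80)  # prefiltering
    header += field([str(spr)] * ns, 8)
    header += field([""] * ns, 32)

    padded = np.zeros((ns, n_records * spr))
    padded[:, :n] = recording.data
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records are interleaved: all samples of signal 0, then 1, ...
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
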