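"""Epoch classification, accuracy, comparative matching, and coverage.

Two independent agreement measures against the visual-scoring labels:

* **Accuracy** — each epoch's normalized feature value is compared to a
  threshold; the direction of the comparison is feature-specific (e.g.
  a high theta/alpha ratio indicates drowsiness, a high PSD alpha
  indicates wakefulness). Accuracy is the percentage of epochs whose
  predicted state equals the visual label.

* **Coverage** — a comparative criterion that needs no threshold: a
  drowsy episode's feature value is compared against its two flanking
  wakeful episodes. If it exceeds both (for an "above is drowsy"
  feature; mirrored otherwise), all three epochs match the visual
  scoring; if it beats only one neighbour, the other neighbour is
  unmatched; if it beats neither, all three are unmatched. Coverage is
  the percentage of matched epochs.

Merging channels takes the epoch-wise logical OR of the matched flags,
so six-channel coverage dominates every single channel by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURES, EpochFeatureMatrix
from .types import DROWSY, WAKEFUL

ABOVE_IS_DROWSY = "above_is_drowsy"
BELOW_IS_DROWSY = "below_is_drowsy"

#: Feature-specific classification direction.
DIRECTIONS: dict[str, str] = {
    "theta_alpha": ABOVE_IS_DROWSY,
    "delta_alpha": ABOVE_IS_DROWSY,
    "delta_theta": ABOVE_IS_DROWSY,
    "psd_theta": ABOVE_IS_DROWSY,
    "psd_delta": ABOVE_IS_DROWSY,
    "spectral_spread": ABOVE_IS_DROWSY,
    "psd_alpha": BELOW_IS_DROWSY,
    "spectral_entropy": BELOW_IS_DROWSY,
    "spectral_centroid": BELOW_IS_DROWSY,
    "spectral_rolloff": BELOW_IS_DROWSY,
}


def classify(matrix: EpochFeatureMatrix, thresholds: pd.Series | pd.DataFrame,
             technique: str | None = None,
             directions: dict[str, str] | None = None,
             tie: str = "wakeful") -> pd.DataFrame:
    """Per-epoch, per-feature correctness flags of threshold classification.

    ``thresholds`` is either a Series indexed by feature or the full
    feature x technique table together with ``technique``. A value
    exactly equal to its threshold is classified per ``tie`` (default
    wakeful, matching the strict inequality of the drowsy branch).
    """
    if isinstance(thresholds, pd.DataFrame):
        if technique is None:
            raise ValueError("technique required with a threshold table")
        thresholds = thresholds[technique]
    directions = directions or DIRECTIONS
    labels = np.asarray(matrix.labels)
    out = {}
    for feature in FEATURES:
        if feature not in thresholds.index:
            raise KeyError(f"missing threshold for feature {feature!r}")
        thr = float(thresholds[feature])
        v = matrix.normalized[feature].to_numpy(dtype=float)
        if directions[feature] == ABOVE_IS_DROWSY:
            drowsy = v > thr
            wake = v < thr
        else:
            drowsy = v < thr
            wake = v > thr
        predicted = np.where(drowsy, DROWSY, np.where(wake, WAKEFUL,
                             WAKEFUL if tie == "wakeful" else DROWSY))
        out[feature] = (predicted == labels).astype(int)
    return pd.DataFrame(out, columns=list(FEATURES))


def accuracy(flags: np.ndarray | pd.Series) -> float:
    """100 x correct / total."""
    flags = np.asarray(flags)
    if flags.size == 0:
        raise ValueError("accuracy undefined for zero epochs")
    return 100.0 * float(np.mean(flags))


def accuracy_from_counts(correct: int, total: int) -> float:
    """Accuracy of an individual channel from agreement counts."""
    if total <= 0:
        raise ValueError("accuracy undefined for zero epochs")
    return 100.0 * correct / total


def comparative_match(matrix: EpochFeatureMatrix,
                      directions: dict[str, str] | None = None,
                      wakeful_combine: str = "and") -> pd.DataFrame:
    """Per-epoch, per-feature matched flags under the comparative criterion.

    Labels must strictly alternate. A wakeful epoch flanked by two
    drowsy episodes receives a verdict from each; verdicts combine by
    AND by default (``wakeful_combine="or"`` switches). A drowsy episode
    at the session boundary is judged on its single available
    comparison. Ties (value equal to a neighbour) fall on the
    non-matching side, as the criterion's <= / >= branches dictate.
    """
    if wakeful_combine not in ("and", "or"):
        raise ValueError("wakeful_combine must be 'and' or 'or'")
    directions = directions or DIRECTIONS
    labels = np.asarray(matrix.labels)
    n = len(labels)
    if n > 1 and np.any(labels[1:] == labels[:-1]):
        raise ValueError("comparative criterion requires strictly alternating labels")

    out = {}
    for feature in FEATURES:
        v = matrix.normalized[feature].to_numpy(dtype=float)
        sign = 1.0 if directions[feature] == ABOVE_IS_DROWSY else -1.0
        verdicts: list[list[int]] = [[] for _ in range(n)]
        for i in np.flatnonzero(labels == DROWSY):
            prev_ok = sign * (v[i] - v[i - 1]) > 0 if i > 0 else None
            next_ok = sign * (v[i] - v[i + 1]) > 0 if i < n - 1 else None
            if prev_ok is None and next_ok is None:
                verdicts[i].append(0)  # isolated drowsy episode: unmatched
            elif prev_ok is None or next_ok is None:
                ok = int(prev_ok if next_ok is None else next_ok)
                j = i - 1 if next_ok is None else i + 1
                verdicts[i].append(ok)
                verdicts[j].append(ok)
            elif prev_ok and next_ok:
                verdicts[i - 1].append(1)
                verdicts[i].append(1)
                verdicts[i + 1].append(1)
            elif prev_ok:
                verdicts[i - 1].append(1)
                verdicts[i].append(1)
                verdicts[i + 1].append(0)
            elif next_ok:
                verdicts[i - 1].append(0)
                verdicts[i].append(1)
                verdicts[i + 1].append(1)
            else:
                verdicts[i - 1].append(0)
                verdicts[i].append(0)
                verdicts[i + 1].append(0)
        combine = all if wakeful_combine == "and" else any
        out[feature] = np.array(
            [int(combine(vs)) if vs else 0 for vs in verdicts], dtype=int
        )
    return pd.DataFrame(out, columns=list(FEATURES))


def coverage(matched: np.ndarray | pd.Series) -> float:
    """100 x matched / total for one feature column."""
    matched = np.asarray(matched)
    if matched.size == 0:
        raise ValueError("coverage undefined for zero epochs")
    return 100.0 * float(np.mean(matched))


def six_channel_coverage(matched_by_channel: dict[str, pd.DataFrame],
                         feature: str) -> float:
    """Coverage after merging channels: an epoch is unmatched only if
    unmatched on every channel (logical OR across channels)."""
    shapes = {df.shape for df in matched_by_channel.values()}
    if len(shapes) != 1:
        raise ValueError("channel match matrices are misaligned")
    merged = np.zeros(next(iter(shapes))[0], dtype=bool)
    for df in matched_by_channel.values():
        merged |= df[feature].to_numpy(dtype=bool)
    return 100.0 * float(np.mean(merged))


def per_class_accuracy(flags: np.ndarray | pd.Series,
                       labels: np.ndarray) -> dict[str, float]:
    """Accuracy tallied separately over wakeful and drowsy epochs."""
    flags = np.asarray(flags)
    labels = np.asarray(labels)
    return {
        "wakeful": accuracy(flags[labels == WAKEFUL]),
        "drowsy": accuracy(flags[labels == DROWSY]),
    }
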