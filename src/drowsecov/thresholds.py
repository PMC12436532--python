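"""Subject- and feature-specific threshold techniques.

For each feature the normalized values are split by the visual-scoring
label into wakeful and drowsy classes; a per-class statistic is
computed and the threshold is the average of the two class statistics.
Seven techniques are provided:

====  ====================================================
AM    arithmetic mean per class
Std   standard deviation per class (population-normalized)
M     median per class
TM    trimean (Q1 + 2*median + Q3)/4 per class
MAD   median absolute deviation per class
IQR   interquartile range per class
RS    robust scaling (median - Q1)/IQR per class
====  ====================================================

Std, MAD, IQR and RS are spread/scale statistics, yet downstream they
are compared against feature *values* exactly as defined; the semantic
oddity is intentional and preserved (it is what the technique
comparison evaluates), not corrected.

Quartiles use linear interpolation (the common "type 7" convention).
The normalization flags are switchable: ``std_population`` toggles
N vs N-1 normalization and ``mad_median`` toggles median- vs
mean-centred absolute deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURES, EpochFeatureMatrix
from .types import DROWSY, WAKEFUL

TECHNIQUES: tuple[str, ...] = ("AM", "Std", "M", "TM", "MAD", "IQR", "RS")


@dataclass
class ClassSplit:
    """Normalized values of one feature, partitioned by visual label."""

    wakeful: np.ndarray
    drowsy: np.ndarray

    def __post_init__(self) -> None:
        if len(self.wakeful) == 0 or len(self.drowsy) == 0:
            raise ValueError(
                "both classes must be non-empty to compute a threshold"
            )


def split_by_label(matrix: EpochFeatureMatrix, feature: str) -> ClassSplit:
    """Exact partition of a feature column by the visual-scoring label."""
    if feature not in matrix.normalized.columns:
        raise KeyError(f"unknown feature {feature!r}")
    values = matrix.normalized[feature].to_numpy(dtype=float)
    labels = np.asarray(matrix.labels)
    return ClassSplit(values[labels == WAKEFUL], values[labels == DROWSY])


def _class_stat(x: np.ndarray, technique: str, *, std_population: bool,
                mad_median: bool) -> float:
    if technique == "AM":
        return float(np.mean(x))
    if technique == "Std":
        return float(np.std(x, ddof=0 if std_population else 1))
    if technique == "M":
        return float(np.median(x))
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    if technique == "TM":
        return float((q1 + 2 * med + q3) / 4)
    if technique == "MAD":
        if mad_median:
            return float(np.median(np.abs(x - np.median(x))))
        return float(np.mean(np.abs(x - np.mean(x))))
    if technique == "IQR":
        return float(q3 - q1)
    if technique == "RS":
        iqr = q3 - q1
        if iqr == 0:
            raise ValueError(
                "robust-scaling threshold undefined: class IQR is zero "
                "(feature nearly constant within a class; use another "
                "technique or pool more epochs)"
            )
        return float((med - q1) / iqr)
    raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")


def threshold(split: ClassSplit, technique: str, *, std_population: bool = True,
              mad_median: bool = True) -> float:
    """Average of the wakeful and drowsy class statistics."""
    kw = dict(std_population=std_population, mad_median=mad_median)
    return 0.5 * (
        _class_stat(split.wakeful, technique, **kw)
        + _class_stat(split.drowsy, technique, **kw)
    )


def threshold_table(matrix: EpochFeatureMatrix, *, std_population: bool = True,
                    mad_median: bool = True,
                    on_error: str = "raise") -> pd.DataFrame:
    """10 features x 7 techniques thresholds for one subject x channel.

    Returns a DataFrame indexed by feature with one column per technique.
    ``on_error="nan"`` records NaN (with a warning) where a technique is
    undefined — e.g. robust scaling when a quantized feature such as
    spectral rolloff has zero IQR within a class — instead of raising;
    downstream classification then predicts wakeful for every epoch of
    that feature/technique cell.
    """
    import warnings

    if on_error not in ("raise", "nan"):
        raise ValueError("on_error must be 'raise' or 'nan'")
    rows = {}
    for feature in FEATURES:
        split = split_by_label(matrix, feature)
        row = {}
        for tech in TECHNIQUES:
            try:
                row[tech] = threshold(
                    split, tech, std_population=std_population, mad_median=mad_median
                )
            except ValueError:
                if on_error == "raise":
                    raise
                warnings.warn(
                    f"{tech} threshold undefined for feature {feature!r}; "
                    "recorded as NaN", stacklevel=2,
                )
                row[tech] = float("nan")
        rows[feature] = row
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        list(FEATURES), list(TECHNIQUES)
    ]
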