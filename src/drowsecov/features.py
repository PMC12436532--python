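"""Per-epoch EEG features after db2 wavelet denoising.

Each epoch is denoised by a 3-level db2 discrete wavelet transform
(reconstruction from A3 + D3 only, i.e. roughly 0-25 Hz content at
200 Hz), then ten features are computed: three Welch band powers
(alpha, theta, delta), their three ratios, and four spectral shape
descriptors (entropy, spread, centroid, rolloff) over the 1-30 Hz
band. Features are min-max normalized per subject x channel x feature
across all epochs of a session, mapping each feature column onto [0, 1].

Band powers are obtained by integrating the Welch PSD of the denoised
signal over the band edges rather than from wavelet subband energies:
the analysis bands (e.g. theta 4-7.5 Hz) do not align with dyadic db2
subbands at 200 Hz, and PSD integration honours both the denoising
step and the stated band limits. See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .config import BANDS
from .types import EpochSet

#: Canonical feature order; all matrices use these column names.
FEATURES: tuple[str, ...] = (
    "psd_alpha",
    "psd_theta",
    "psd_delta",
    "theta_alpha",
    "delta_alpha",
    "delta_theta",
    "spectral_entropy",
    "spectral_spread",
    "spectral_centroid",
    "spectral_rolloff",
)

SPECTRAL_BAND = (1.0, 30.0)


def dwt_denoise(x: np.ndarray, wavelet: str = "db2", level: int = 3) -> np.ndarray:
    """Reconstruct from A3 and D3 only, zeroing the D1/D2 details.

    At 200 Hz this retains ~0-25 Hz and suppresses the top two octaves.
    Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 ** level:
        raise ValueError(f"epoch of {len(x)} samples too short for level-{level} DWT")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    # coeffs = [A3, D3, D2, D1]; zero the two finest detail levels
    for i in range(2, len(coeffs)):
        coeffs[i] = np.zeros_like(coeffs[i])
    rec = pywt.waverec(coeffs, wavelet)
    return rec[: len(x)]


def _welch(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(int(2 * fs), len(x))
    return signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Welch PSD integrated over [lo, hi] by the trapezoid rule."""
    lo, hi = band
    if lo >= hi:
        raise ValueError(f"empty band {band!r}")
    f, p = _welch(x, fs)
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band!r} spans fewer than two PSD bins")
    return float(np.trapezoid(p[mask], f[mask]))


def spectral_features(x: np.ndarray, fs: float,
                      band: tuple[float, float] = SPECTRAL_BAND,
                      rolloff_frac: float = 0.85) -> tuple[float, float, float, float]:
    """(entropy, spread, centroid, rolloff) of the PSD over ``band``.

    With p_k the PSD normalized over the band: centroid = sum f_k p_k;
    spread = sqrt(sum (f_k - centroid)^2 p_k); entropy is the Shannon
    entropy of p_k normalized by log(n_bins) into [0, 1]; rolloff is
    the smallest frequency below which ``rolloff_frac`` of the band
    power lies.
    """
    f, p = _welch(x, fs)
    mask = (f >= band[0]) & (f <= band[1])
    f, p = f[mask], p[mask]
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero PSD over the analysis band")
    pk = p / total
    centroid = float(np.sum(f * pk))
    spread = float(np.sqrt(np.sum((f - centroid) ** 2 * pk)))
    nz = pk[pk > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(len(pk))) if len(pk) > 1 else 0.0
    rolloff = float(f[np.searchsorted(np.cumsum(pk), rolloff_frac)])
    return entropy, spread, centroid, rolloff


def epoch_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """The ten features of one (already segmented) epoch."""
    den = dwt_denoise(x)
    pa = band_power(den, fs, BANDS["alpha"])
    pt = band_power(den, fs, BANDS["theta"])
    pdlt = band_power(den, fs, BANDS["delta"])
    eps = np.finfo(float).tiny
    entropy, spread, centroid, rolloff = spectral_features(den, fs)
    return {
        "psd_alpha": pa,
        "psd_theta": pt,
        "psd_delta": pdlt,
        "theta_alpha": pt / max(pa, eps),
        "delta_alpha": pdlt / max(pa, eps),
        "delta_theta": pdlt / max(pt, eps),
        "spectral_entropy": entropy,
        "spectral_spread": spread,
        "spectral_centroid": centroid,
        "spectral_rolloff": rolloff,
    }


@dataclass
class EpochFeatureMatrix:
    """epochs x 10 features for one subject x channel, raw and normalized."""

    subject_id: str
    channel_name: str
    raw: pd.DataFrame
    normalized: pd.DataFrame
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self) -> int:
        return len(self.raw)


def minmax_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - min)/(max - min); constant columns map to 0.5."""
    out = {}
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi > lo:
            out[col] = (x - lo) / (hi - lo)
        else:
            warnings.warn(
                f"feature {col!r} is constant across epochs; normalized to 0.5",
                stacklevel=2,
            )
            out[col] = np.full_like(x, 0.5)
    return pd.DataFrame(out, index=raw.index)


def compute_feature_matrix(epochs: EpochSet, fs: float) -> EpochFeatureMatrix:
    """Raw and min-max normalized feature matrix for one subject x channel."""
    if len(epochs) < 2:
        raise ValueError("need at least two epochs to normalize features")
    rows = [epoch_features(x, fs) for x in epochs.samples]
    raw = pd.DataFrame(rows, columns=list(FEATURES))
    return EpochFeatureMatrix(
        subject_id=epochs.subject_id,
        channel_name=epochs.channel_name,
        raw=raw,
        normalized=minmax_normalize(raw),
        labels=epochs.labels.copy(),
    )


def matrix_from_frame(df: pd.DataFrame) -> EpochFeatureMatrix:
    """Inverse of :func:`feature_matrix_frame` for one subject x channel."""
    subjects = df["subject"].unique()
    channels = df["channel"].unique()
    if len(subjects) != 1 or len(channels) != 1:
        raise ValueError("frame must contain exactly one subject x channel")
    df = df.sort_values("epoch")
    raw = df[[f"raw_{c}" for c in FEATURES]].to_numpy()
    norm = df[[f"norm_{c}" for c in FEATURES]].to_numpy()
    return EpochFeatureMatrix(
        subject_id=str(subjects[0]),
        channel_name=str(channels[0]),
        raw=pd.DataFrame(raw, columns=list(FEATURES)),
        normalized=pd.DataFrame(norm, columns=list(FEATURES)),
        labels=df["label"].to_numpy(dtype=int),
    )


def feature_matrix_frame(m: EpochFeatureMatrix) -> pd.DataFrame:
    """Flat CSV-ready frame: subject, channel, label, 10 raw, 10 normalized."""
    df = pd.DataFrame({
        "subject": m.subject_id,
        "channel": m.channel_name,
        "epoch": np.arange(len(m)),
        "label": m.labels,
    })
    for col in FEATURES:
        df[f"raw_{col}"] = m.raw[col].to_numpy()
    for col in FEATURES:
        df[f"norm_{col}"] = m.normalized[col].to_numpy()
    return df
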