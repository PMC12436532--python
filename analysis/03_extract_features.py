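"""EEG feature extraction: EDF -> band-limited, episode-aligned epochs ->
ten wavelet/spectral features per epoch, raw and min-max normalized.

Reads the EDFs from scratch/ and the scored episode CSVs from results/,
writes one flat features table (one row per subject x channel x epoch).

Usage: python analysis/03_extract_features.py
"""

import argparse
from pathlib import Path

import pandas as pd

from drowsecov.config import CHANNELS
from drowsecov.features import compute_feature_matrix, feature_matrix_frame
from drowsecov.preprocess import bandlimit, read_edf, segment_epochs
from drowsecov.visual import read_episode_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", default="scratch/cohort")
    ap.add_argument("--episodes", default="results/episodes")
    ap.add_argument("--out", default="scratch/features.csv")
    args = ap.parse_args()

    frames = []
    for edf_path in sorted(Path(args.scratch).glob("*.edf")):
        sid = edf_path.stem
        recording = bandlimit(read_edf(edf_path))
        timeline = read_episode_csv(Path(args.episodes) / f"{sid}_episodes.csv")
        epoch_sets = segment_epochs(recording, timeline, subject_id=sid)
        for ch in CHANNELS:
            m = compute_feature_matrix(epoch_sets[ch], recording.fs)
            frames.append(feature_matrix_frame(m))
        print(f"{sid}: {len(timeline)} epochs x {len(CHANNELS)} channels")

    table = pd.concat(frames, ignore_index=True)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"\n{len(table)} feature rows -> {args.out}")


if __name__ == "__main__":
    main()
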