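"""Visual-based scoring: EAR traces -> alternating episode CSVs.

Reads the frame-level EAR CSVs produced by 01_simulate.py, runs the
PERCLOS/CLOSDUR scoring chain, and writes one episode CSV per subject
(the reference labels for the EEG analysis). Also reports how well the
scored episodes recover the generating timelines.

Usage: python analysis/02_score_visual.py
"""

import argparse
from pathlib import Path

from drowsecov.config import VisualScoringParams
from drowsecov.synthetic import read_ear_csv
from drowsecov.types import DROWSY
from drowsecov.visual import read_episode_csv, score_episodes, write_episode_csv


def jaccard(a, b) -> float:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0.0, hi - lo)
    return inter / ((a[1] - a[0]) + (b[1] - b[0]) - inter)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", default="scratch/cohort")
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/episodes")
    args = ap.parse_args()

    params = VisualScoringParams()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    total = recovered = 0
    for ear_path in sorted(Path(args.scratch).glob("*_ear.csv")):
        sid = ear_path.name.split("_")[0]
        scored = score_episodes(read_ear_csv(ear_path), params)
        write_episode_csv(scored, out / f"{sid}_episodes.csv")
        truth = read_episode_csv(Path(args.cohort) / f"{sid}_true_episodes.csv")
        scored_drowsy = [(e.start, e.end) for e in scored if e.label == DROWSY]
        hits = 0
        n_true = 0
        for e in truth:
            if e.label == DROWSY:
                n_true += 1
                if any(jaccard((e.start, e.end), s) > 0.5 for s in scored_drowsy):
                    hits += 1
        total += n_true
        recovered += hits
        print(f"{sid}: {len(scored)} scored episodes, "
              f"{hits}/{n_true} true drowsy episodes recovered")

    print(f"\nDrowsy-episode recovery (Jaccard > 0.5): "
          f"{recovered}/{total} = {100 * recovered / max(total, 1):.1f}%")
    print(f"Episode CSVs -> {out}")


if __name__ == "__main__":
    main()
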