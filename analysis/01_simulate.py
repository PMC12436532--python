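"""Generate the synthetic cohort: EEG to EDF, EAR traces and ground-truth
episode timelines to CSV.

EDF recordings and the (large) frame-level EAR CSVs go under scratch/;
the per-subject ground-truth timelines and a cohort manifest go under
results/.

Usage: python analysis/01_simulate.py [--config analysis/config.yaml]
"""

import argparse
from pathlib import Path

import pandas as pd

from drowsecov.config import SimulationConfig
from drowsecov.edf import write_edf
from drowsecov.synthetic import generate_subject, write_ear_csv
from drowsecov.visual import write_episode_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", default="analysis/config.yaml")
    ap.add_argument("--scratch", default="scratch/cohort")
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()

    config = SimulationConfig.from_file(args.config)
    scratch = Path(args.scratch)
    out = Path(args.out)
    scratch.mkdir(parents=True, exist_ok=True)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for s in range(config.n_subjects):
        sid = f"S{s:02d}"
        timeline, eeg, ear = generate_subject(config, s)
        write_edf(eeg, scratch / f"{sid}.edf", patient_id=sid)
        write_ear_csv(ear, scratch / f"{sid}_ear.csv")
        write_episode_csv(timeline, out / f"{sid}_true_episodes.csv")
        n_drowsy = int((timeline.labels == 0).sum())
        rows.append({
            "subject": sid,
            "n_episodes": len(timeline),
            "n_drowsy": n_drowsy,
            "n_wakeful": len(timeline) - n_drowsy,
            "edf": str(scratch / f"{sid}.edf"),
            "ear_csv": str(scratch / f"{sid}_ear.csv"),
        })
        print(f"{sid}: {len(timeline)} episodes ({n_drowsy} drowsy), "
              f"{eeg.duration:.0f} s EEG at {eeg.fs:.0f} Hz")

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    total = manifest["n_episodes"].sum()
    print(f"\nCohort: {config.n_subjects} subjects, {total} episodes total "
          f"({manifest['n_drowsy'].sum()} drowsy / {manifest['n_wakeful'].sum()} wakeful).")
    print(f"Manifest -> {out / 'manifest.csv'}")


if __name__ == "__main__":
    main()
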