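"""Threshold classification and comparative matching.

For every subject x channel: compute the 10 x 7 threshold table, the
per-epoch correctness flags for each of the seven techniques, and the
comparative-criterion match flags. Writes the threshold tables and the
flat flag matrices used by the cohort report.

Usage: python analysis/04_analyze.py
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from drowsecov.features import FEATURES, matrix_from_frame
from drowsecov.metrics import classify, comparative_match
from drowsecov.thresholds import TECHNIQUES, threshold_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", default="scratch/features.csv")
    ap.add_argument("--out", default="scratch")
    args = ap.parse_args()

    table = pd.read_csv(args.features)
    out = Path(args.out)
    thr_rows, flag_rows = [], []
    for (sid, ch), group in table.groupby(["subject", "channel"]):
        m = matrix_from_frame(group)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thresholds = threshold_table(m, on_error="nan")
        for feat in FEATURES:
            for tech in TECHNIQUES:
                thr_rows.append({"subject": sid, "channel": ch, "feature": feat,
                                 "technique": tech,
                                 "value": thresholds.loc[feat, tech]})
        matched = comparative_match(m)
        for tech in TECHNIQUES:
            correct = classify(m, thresholds, tech)
            for i in range(len(m)):
                for feat in FEATURES:
                    flag_rows.append({
                        "subject": sid, "channel": ch, "epoch": i,
                        "label": int(m.labels[i]), "feature": feat,
                        "technique": tech,
                        "correct": int(correct.loc[i, feat]),
                        "matched": int(matched.loc[i, feat]),
                    })
        print(f"{sid} {ch}: {len(m)} epochs, 70 thresholds")

    pd.DataFrame(thr_rows).to_csv(out / "thresholds.csv", index=False)
    flags = pd.DataFrame(flag_rows)
    flags.to_csv(out / "flags.csv", index=False)
    # quick narrative: per-channel mean coverage/accuracy (median technique)
    med = flags[flags.technique == "M"]
    summary = med.groupby("channel")[["correct", "matched"]].mean() * 100
    print("\nPer-channel mean over features (median technique):")
    print(summary.rename(columns={"correct": "accuracy_%", "matched": "coverage_%"})
          .round(1).to_string())
    print(f"\nThresholds -> {out / 'thresholds.csv'}; flags -> {out / 'flags.csv'}")


if __name__ == "__main__":
    main()
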