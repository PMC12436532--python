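"""Cohort report: pair combination, channel ranking, technique comparison.

Rebuilds the per-subject flag matrices, averages the 45 feature pairs
across subjects, ranks channels against the six-channel single-feature
reference, and writes the summary tables plus bar-chart figures
(channel coverage, top pairs, technique comparison).

Usage: python analysis/05_report.py
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from drowsecov.config import CHANNELS
from drowsecov.features import FEATURES
from drowsecov.pairing import (
    SubjectResult,
    cohort_average,
    select_optimal_channel,
    technique_comparison,
)
from drowsecov.thresholds import TECHNIQUES


def rebuild_results(flags: pd.DataFrame) -> list[SubjectResult]:
    results = []
    for sid, sub in flags.groupby("subject"):
        labels = (
            sub[(sub.channel == CHANNELS[0]) & (sub.technique == "M")]
            .drop_duplicates("epoch").sort_values("epoch")["label"].to_numpy()
        )
        correct, matched = {}, {}
        for ch, chsub in sub.groupby("channel"):
            correct[ch] = {}
            for tech, tsub in chsub.groupby("technique"):
                correct[ch][tech] = tsub.pivot(
                    index="epoch", columns="feature", values="correct"
                )[list(FEATURES)].reset_index(drop=True)
            msub = chsub[chsub.technique == "M"]
            matched[ch] = msub.pivot(
                index="epoch", columns="feature", values="matched"
            )[list(FEATURES)].reset_index(drop=True)
        correct = {ch: correct[ch] for ch in CHANNELS}
        matched = {ch: matched[ch] for ch in CHANNELS}
        results.append(SubjectResult(sid, labels, correct, matched))
    return results


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--flags", default="scratch/flags.csv")
    ap.add_argument("--out", default="results")
    ap.add_argument("--figures", default="scratch/figures")
    args = ap.parse_args()

    out = Path(args.out)
    figdir = Path(args.figures)
    figdir.mkdir(parents=True, exist_ok=True)

    results = rebuild_results(pd.read_csv(args.flags))
    summary = cohort_average(results, technique="M")
    sel = select_optimal_channel(summary)

    sel.ranking.to_csv(out / "channel_ranking.csv", index=False)
    summary.spearman.to_csv(out / "spearman.csv", index=False)
    pd.concat(
        {ch: df for ch, df in summary.pair_stats.items()}, names=["channel", "pair"]
    ).to_csv(out / "pair_stats.csv")
    summary.six_channel_by_feature.rename("avg_combined_coverage").to_csv(
        out / "six_channel_by_feature.csv"
    )

    best = sel.ranking.iloc[0]
    print("Channel ranking by best-pair average combined coverage:")
    print(sel.ranking.round(2).to_string(index=False))
    print(f"\nSix-channel reference: {summary.six_channel_best_coverage:.1f}% "
          f"(single best feature: {summary.six_channel_best_feature})")
    print(f"Optimal channel(s): {sel.optimal_channels or 'none'} — "
          f"{best.channel} best pair {best.best_pair} at {best.best_coverage:.1f}% "
          f"({best.relative_improvement_pct:+.2f}% vs six channels)")

    tc = technique_comparison(results, str(best.channel))
    tc.rename("best_pair_avg_combined_accuracy").to_csv(
        out / "technique_comparison.csv"
    )
    print("\nBest-pair average combined accuracy by technique "
          f"(channel {best.channel}):")
    print(tc.round(2).to_string())

    # figures: per-channel coverage, top-3 pairs, technique comparison
    fig, ax = plt.subplots(figsize=(6, 4))
    r = sel.ranking
    ax.bar(r.channel, r.best_coverage, color="tab:blue")
    ax.axhline(summary.six_channel_best_coverage, color="k", ls="--",
               label="six channels, best single feature")
    ax.set_ylabel("avg combined coverage (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "channel_coverage.png", dpi=120)

    top = summary.pair_stats[str(best.channel)].nlargest(3, "combined_coverage")
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(top))
    ax.bar(x - 0.2, top.combined_coverage, 0.4, yerr=top.coverage_ci,
           label="coverage", color="tab:green")
    ax.bar(x + 0.2, top.combined_accuracy, 0.4, yerr=top.accuracy_ci,
           label="accuracy (median threshold)", color="tab:orange")
    ax.set_xticks(x, top.index, rotation=20, ha="right")
    ax.set_ylabel("percent")
    ax.set_title(f"Top pairs, channel {best.channel}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "top_pairs.png", dpi=120)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(list(tc.index), tc.to_numpy(), color="tab:purple")
    ax.set_ylabel("best-pair avg combined accuracy (%)")
    fig.tight_layout()
    fig.savefig(figdir / "technique_comparison.png", dpi=120)

    print(f"\nTables -> {out}; figures -> {figdir}")


if __name__ == "__main__":
    main()
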