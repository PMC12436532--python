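"""Feature-pair combination and cohort-level channel selection.

Each of the C(10,2) = 45 unordered feature pairs is combined by an
epoch-wise logical OR of the per-feature agreement flags: an epoch
counts if *either* feature agrees with the visual scoring. Combined
coverage/accuracy are averaged across subjects; channels are ranked by
their best pair's average combined coverage and compared with the
six-channel system evaluated on its single best feature. A channel is
"optimal" when its best-pair coverage meets or exceeds the six-channel
single-feature value.

Note the combined accuracy is an agreement-with-reference OR, an
evaluation device quantifying how much a second feature adds — not a
deployable two-feature classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURES


def enumerate_pairs(features: tuple[str, ...] = FEATURES) -> list[tuple[str, str]]:
    """All unordered feature pairs in deterministic order."""
    if len(set(features)) != len(features):
        raise ValueError("feature list contains duplicates")
    return list(combinations(features, 2))


def combine_flags(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"flag length mismatch: {a.shape} vs {b.shape}")
    return (a.astype(bool) | b.astype(bool)).astype(int)


def combine_pair(a: np.ndarray, b: np.ndarray) -> float:
    """100 x mean(a OR b): the pair's combined agreement percentage."""
    return 100.0 * float(np.mean(combine_flags(a, b)))


@dataclass
class SubjectResult:
    """Per-subject agreement flags, one matrix per channel.

    ``correct``: channel -> technique -> (epochs x features) 0/1 frame.
    ``matched``: channel -> (epochs x features) 0/1 frame.
    """

    subject_id: str
    labels: np.ndarray
    correct: dict[str, dict[str, pd.DataFrame]]
    matched: dict[str, pd.DataFrame]

    @property
    def n_epochs(self) -> int:
        return len(self.labels)


@dataclass
class CohortSummary:
    technique: str
    n_subjects: int
    channels: list[str]
    #: channel -> frame indexed by "featA+featB" with columns
    #: combined_coverage, combined_accuracy, coverage_ci, accuracy_ci
    pair_stats: dict[str, pd.DataFrame]
    #: channel -> frame indexed by feature with columns coverage, accuracy
    feature_stats: dict[str, pd.DataFrame]
    #: average six-channel merged coverage per feature
    six_channel_by_feature: pd.Series
    six_channel_best_feature: str
    six_channel_best_coverage: float
    #: across-subject Spearman correlations per channel (best pair)
    spearman: pd.DataFrame


def pair_key(pair: tuple[str, str]) -> str:
    return f"{pair[0]}+{pair[1]}"


def _ci_halfwidth(values: np.ndarray) -> float:
    """Two-sided 95% t-interval half-width across subjects."""
    n = len(values)
    if n < 2 or np.std(values, ddof=1) == 0:
        return 0.0
    return float(stats.t.ppf(0.975, n - 1) * np.std(values, ddof=1) / np.sqrt(n))


def cohort_average(results: list[SubjectResult], technique: str = "M") -> CohortSummary:
    """Average combined/individual metrics across subjects.

    Subjects with zero epochs are excluded with a warning. Averages are
    plain arithmetic means over subjects; a 95% t-interval half-width
    accompanies each pair average.
    """
    import warnings

    usable = []
    for r in results:
        if r.n_epochs == 0:
            warnings.warn(f"subject {r.subject_id} has zero epochs; excluded",
                          stacklevel=2)
        else:
            usable.append(r)
    if len(usable) < 2:
        raise ValueError("cohort averaging requires at least two usable subjects")

    channels = list(usable[0].matched.keys())
    pairs = enumerate_pairs()
    pair_stats: dict[str, pd.DataFrame] = {}
    feature_stats: dict[str, pd.DataFrame] = {}
    spearman_rows = []

    # per-subject epoch counts (episodes derived from visual scoring)
    episode_counts = np.array([r.n_epochs for r in usable], dtype=float)

    for ch in channels:
        cov = np.empty((len(usable), len(pairs)))
        acc = np.empty((len(usable), len(pairs)))
        matched_counts = np.empty((len(usable), len(pairs)))
        correct_counts = np.empty((len(usable), len(pairs)))
        for si, r in enumerate(usable):
            m = r.matched[ch]
            c = r.correct[ch][technique]
            for pi, (fa, fb) in enumerate(pairs):
                mo = combine_flags(m[fa].to_numpy(), m[fb].to_numpy())
                co = combine_flags(c[fa].to_numpy(), c[fb].to_numpy())
                cov[si, pi] = 100.0 * mo.mean()
                acc[si, pi] = 100.0 * co.mean()
                matched_counts[si, pi] = mo.sum()
                correct_counts[si, pi] = co.sum()
        idx = [pair_key(p) for p in pairs]
        pair_stats[ch] = pd.DataFrame(
            {
                "combined_coverage": cov.mean(axis=0),
                "combined_accuracy": acc.mean(axis=0),
                "coverage_ci": [_ci_halfwidth(cov[:, i]) for i in range(len(pairs))],
                "accuracy_ci": [_ci_halfwidth(acc[:, i]) for i in range(len(pairs))],
            },
            index=idx,
        )
        fcov = np.empty((len(usable), len(FEATURES)))
        facc = np.empty((len(usable), len(FEATURES)))
        for si, r in enumerate(usable):
            fcov[si] = 100.0 * r.matched[ch][list(FEATURES)].mean(axis=0).to_numpy()
            facc[si] = 100.0 * r.correct[ch][technique][list(FEATURES)].mean(axis=0).to_numpy()
        feature_stats[ch] = pd.DataFrame(
            {"coverage": fcov.mean(axis=0), "accuracy": facc.mean(axis=0)},
            index=list(FEATURES),
        )

        # Spearman across subjects: episode counts vs matched / correct
        # counts for this channel's best pair
        best_pi = int(np.argmax(cov.mean(axis=0)))
        for kind, counts in (("coverage", matched_counts), ("accuracy", correct_counts)):
            if np.std(counts[:, best_pi]) == 0 or np.std(episode_counts) == 0:
                r_s, p_s = np.nan, np.nan
            else:
                r_s, p_s = stats.spearmanr(episode_counts, counts[:, best_pi])
            spearman_rows.append(
                {"channel": ch, "analysis": kind, "pair": idx[best_pi],
                 "spearman_r": r_s, "p_value": p_s}
            )

    # six-channel merged coverage per feature, averaged over subjects
    six = np.empty((len(usable), len(FEATURES)))
    for si, r in enumerate(usable):
        for fi, feat in enumerate(FEATURES):
            merged = np.zeros(r.n_epochs, dtype=bool)
            for ch in channels:
                merged |= r.matched[ch][feat].to_numpy(dtype=bool)
            six[si, fi] = 100.0 * merged.mean()
    six_by_feature = pd.Series(six.mean(axis=0), index=list(FEATURES))
    best_feature = str(six_by_feature.idxmax())

    return CohortSummary(
        technique=technique,
        n_subjects=len(usable),
        channels=channels,
        pair_stats=pair_stats,
        feature_stats=feature_stats,
        six_channel_by_feature=six_by_feature,
        six_channel_best_feature=best_feature,
        six_channel_best_coverage=float(six_by_feature.max()),
        spearman=pd.DataFrame(spearman_rows),
    )


@dataclass
class ChannelSelection:
    """Ranking of channels against the six-channel reference."""

    ranking: pd.DataFrame  # channel, best_pair, best_coverage, relative_improvement_pct
    optimal_channels: list[str]
    six_channel_coverage: float
    six_channel_feature: str
    top_pairs: dict[str, pd.DataFrame]  # channel -> top-3 pair stats


def select_optimal_channel(
    summary_or_coverages: CohortSummary | dict[str, float],
    six_channel_coverage: float | None = None,
    six_channel_feature: str = "",
    top_n: int = 3,
) -> ChannelSelection:
    """Rank channels by best-pair combined coverage vs the six-channel value.

    Accepts either a full :class:`CohortSummary`, or a plain mapping
    channel -> best-pair coverage together with the six-channel
    coverage (useful for evaluating published coverage tables). Ties
    break lexicographically by channel name. A channel is optimal when
    its best-pair coverage >= the six-channel single-best-feature
    coverage; relative improvement is 100 x (channel - six) / six.
    """
    top_pairs: dict[str, pd.DataFrame] = {}
    if isinstance(summary_or_coverages, CohortSummary):
        summary = summary_or_coverages
        six = summary.six_channel_best_coverage
        six_feat = summary.six_channel_best_feature
        best = {}
        for ch in summary.channels:
            df = summary.pair_stats[ch].sort_values(
                "combined_coverage", ascending=False, kind="stable"
            )
            best[ch] = (df.index[0], float(df["combined_coverage"].iloc[0]))
            top_pairs[ch] = df.head(top_n)
    else:
        if six_channel_coverage is None:
            raise ValueError("six_channel_coverage required with a plain mapping")
        six = float(six_channel_coverage)
        six_feat = six_channel_feature
        best = {ch: ("", float(v)) for ch, v in summary_or_coverages.items()}

    rows = []
    for ch, (pair, covv) in best.items():
        rows.append({
            "channel": ch,
            "best_pair": pair,
            "best_coverage": covv,
            "relative_improvement_pct": 100.0 * (covv - six) / six,
        })
    ranking = pd.DataFrame(rows).sort_values(
        ["best_coverage", "channel"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    optimal = ranking.loc[ranking["best_coverage"] >= six, "channel"].tolist()
    return ChannelSelection(
        ranking=ranking,
        optimal_channels=optimal,
        six_channel_coverage=six,
        six_channel_feature=six_feat,
        top_pairs=top_pairs,
    )


def technique_comparison(results: list[SubjectResult], channel: str,
                         techniques: tuple[str, ...] | None = None) -> pd.Series:
    """Best-pair average combined accuracy per thresholding technique."""
    from .thresholds import TECHNIQUES

    techniques = techniques or TECHNIQUES
    pairs = enumerate_pairs()
    out = {}
    for tech in techniques:
        acc = np.empty((len(results), len(pairs)))
        for si, r in enumerate(results):
            c = r.correct[channel][tech]
            for pi, (fa, fb) in enumerate(pairs):
                acc[si, pi] = combine_pair(c[fa].to_numpy(), c[fb].to_numpy())
        out[tech] = float(acc.mean(axis=0).max())
    return pd.Series(out)
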