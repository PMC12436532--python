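# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic cohorts do and do not
emulate, and the design choices made where the procedure was genuinely
open.

## The analysis in one paragraph

Drowsy and wakeful episodes are scored from an eye-aspect-ratio (EAR)
trace (the reference system); six-channel EEG is band-limited, cut into
episode-aligned epochs, and summarized by ten wavelet/spectral features
per epoch; each feature classifies epochs against a subject- and
feature-specific threshold (seven candidate techniques), and a
threshold-free comparative criterion checks whether each drowsy
episode's feature value beats its flanking wakeful episodes. Feature
pairs are combined by an epoch-wise logical OR, averaged across
subjects, and the best single channel is compared against the
six-channel merge evaluated with its single best feature.

## Visual scoring

Chain: median filter (5 frames) → centred moving average (5 frames) →
adaptive threshold → closure runs → PERCLOS/CLOSDUR windows → episodes.

* **Adaptive threshold.** The per-frame threshold is 0.7 × a rolling
  *open-eye baseline*: the rolling maximum, over 60 s, of a 2-s rolling
  median of the smoothed trace. The 2-s median rejects individual blink
  dips; the maximum then tracks the open-eye level even where the eye
  is closed most of the time. A plain long-window rolling median was
  evaluated first and rejected: in heavy-closure spans (closed fraction
  above ~50%, routine during genuine drowsiness) the median collapses
  to the closed level and closures go undetected.
* **Closures.** Maximal runs of frames strictly below threshold, at
  least `min_blink_frames` = 3 long. Runs separated by one open frame
  are never merged.
* **Windows.** Non-overlapping 30-s windows; a window is
  candidate-drowsy when PERCLOS ≥ 0.15 *and* it contains a closure
  ≥ 1 s (CLOSDUR). The AND combination is this package's documented
  choice; both cutoffs follow common PERCLOS practice and are
  configurable. Adjacent same-label windows merge; episodes shorter
  than 30 s are absorbed into the longer neighbour (with a small float
  tolerance so one-window episodes survive a reconstructed frame rate).
* **Resolution.** Episode boundaries are quantized to the window grid,
  so scored boundaries can be off by up to one window (30 s); the
  recovery tests account for this via a Jaccard > 0.5 overlap rule.

## EEG preprocessing

Order-25 equiripple FIR high-pass (stop 0.5 Hz, pass 1 Hz) and low-pass
(pass 30 Hz, stop 35 Hz), designed with `scipy.signal.remez` and applied
forward–backward per channel so episode timestamps are not shifted
(zero phase; whether the original analysis filtered causally is
unknown — zero-phase is this package's choice because the comparative
criterion depends on epoch/episode alignment). Two numerical notes:

* A high-pass FIR needs an odd tap count (type I), so 26 taps becomes
  27 — the same promotion standard equiripple tooling applies.
* At 200 Hz an order-25 filter is only 0.135 s long and cannot make a
  sub-hertz transition steep. With stop/pass weights (1, 20) the
  passband stays flat within ~3% one-pass, but 0.2 Hz content is only
  attenuated ~15% after forward–backward application. The downstream
  logic depends on within-epoch power *contrasts*, not absolute sub-Hz
  attenuation, so this gentleness is accepted and tested as relative
  attenuation (0.2 Hz and 45 Hz versus 10 Hz).

Epochs are samples `[floor(start·fs), floor(end·fs))` — 0-based,
half-open — so contiguous episodes partition the recording exactly.
Epochs shorter than 1 s are retained with a warning.

## Features

Each epoch is denoised by a 3-level db2 DWT, reconstructing from A3 and
D3 only (≈ 0–25 Hz at 200 Hz). Band powers are then Welch PSDs (Hann,
2-s segments, 50% overlap) integrated by trapezoid over delta 1–4,
theta 4–7.5 and alpha 7.5–15 Hz. The analysis bands do not align with
dyadic db2 subbands at 200 Hz, so band powers are **not** taken from
subband coefficient energies; integrating the PSD of the denoised
signal honours both the denoising step and the stated band edges. The
four spectral descriptors use the normalized PSD over 1–30 Hz:
centroid Σf·p, spread √Σ(f−c)²p, Shannon entropy normalized by
log(bins) into [0, 1], and rolloff at the 85th power percentile
(configurable; standard definitions).

Normalization is min–max per subject × channel × feature over all
epochs of a session (thresholds are subject- and feature-specific, so
within-subject scaling is the consistent scope; pooling across channels
was considered and rejected as it would couple channel gains into the
comparison). A constant feature column maps to 0.5 with a warning.

## Thresholds

For each feature, the normalized values split by visual label; each of
seven statistics is computed per class and the threshold is the average
of the two class values: AM (mean), Std (population SD), M (median),
TM (trimean (Q1+2M+Q3)/4), MAD (median absolute deviation), IQR
(Q3−Q1), RS ((M−Q1)/IQR). Quartiles use linear interpolation (the
"type 7" convention) everywhere. Two interpretation switches are
exposed: `std_population` (N vs N−1) and `mad_median` (median- vs
mean-centred deviation), defaulting to population SD and median-MAD.

Std, MAD, IQR and RS are *spread* statistics, yet they are compared
against feature values downstream exactly as defined. This semantic
oddity is intentional — the technique comparison evaluates these
definitions as printed — and is not "fixed". One practical consequence:
RS is undefined when a class IQR is zero, which genuinely occurs for
quantized features (spectral rolloff takes values on the PSD frequency
grid) with few epochs. The `threshold` operation raises with a
remediation hint; the batch `threshold_table(on_error="nan")` records
NaN instead, and a NaN threshold classifies every epoch wakeful (both
strict comparisons are false, falling to the tie branch).

## Classification, matching, coverage

Directions are fixed per feature: θ/α, δ/α, δ/θ, PSD θ, PSD δ and
spectral spread indicate drowsiness when *above* threshold; PSD α,
entropy, centroid and rolloff when *below*. A value exactly equal to
its threshold classifies wakeful (the drowsy branch is a strict
inequality); the tie rule is configurable.

The comparative criterion, per drowsy episode i with wakeful
neighbours i−1 and i+1 (for an above-is-drowsy feature; mirrored
otherwise): value(i) greater than both ⇒ all three epochs match; only
the preceding inequality ⇒ epoch i+1 unmatched; only the following ⇒
epoch i−1 unmatched; neither ⇒ all three unmatched. Ties fall on the
non-matching side. Two decisions the criterion itself leaves open:

* a wakeful epoch flanked by two drowsy episodes receives two verdicts,
  combined by AND (must be consistent with both; OR is switchable);
* a boundary drowsy episode with a single wakeful neighbour is judged
  on that one comparison rather than discarded, so short sessions keep
  their edge episodes.

Coverage is the matched percentage; six-channel coverage ORs the match
flags across channels per epoch, so it dominates every single channel
by construction.

## Pairing and channel selection

All C(10,2) = 45 pairs combine flags by epoch-wise OR; combined
coverage/accuracy therefore dominate each constituent. Cohort averages
are arithmetic means across subjects with two-sided 95% t-interval
half-widths; Spearman rank correlations relate per-subject episode
counts to matched/correct counts for each channel's best pair.
Channels are ranked by best-pair average combined coverage (ties break
lexicographically for determinism); the six-channel reference uses the
feature maximizing the average merged coverage (computed as an argmax,
not hard-coded); a channel is optimal when it meets or exceeds that
reference, and relative improvement is 100×(channel−six)/six.

Note that "combined accuracy" ORs each feature's agreement with the
reference — an evaluation device quantifying what a second feature
adds, not a deployable two-feature classifier: pairing a feature that
over-predicts drowsiness with one that over-predicts wakefulness can
score highly without either being individually strong. The metric is
implemented as defined.

## Synthetic cohorts: what they emulate, what they do not

Each subject is a pure function of (config, subject index, seed):

* **Timeline** — alternating episodes, durations uniform per state
  (defaults 90–240 s wakeful, 60–180 s drowsy over a 3000-s session,
  matching roughly 18 episodes per 50 minutes; the analysis configs use
  10-minute sessions with 60–120 s / 45–90 s episodes for desk-scale
  runs). The final episode extends to the session end rather than
  truncating, so no sub-resolution tail episodes exist.
* **EEG** — per channel, four zero-phase band-limited Gaussian noise
  carriers (delta/theta/alpha/beta at 1–4/4–7.5/7.5–15/15–30 Hz),
  amplitude-scaled per episode by √weight of the state's band-power
  profile (drowsy doubles theta and halves alpha by default), with ≤1-s
  cosine cross-fades at boundaries to avoid spectral splatter, plus
  broadband noise and a per-channel gain perturbation. Channel
  imperfection comes from two mechanisms scaled by `noise_sd` and the
  per-channel `channel_noise_scale`: broadband noise, and a lognormal
  per-episode jitter on every band weight (log-sd =
  `band_weight_jitter` × `noise_sd` × channel scale). The jitter
  default (0.6) was calibrated so that unit-noise channels show
  best-pair coverages in the ~92–98% range — imperfect and orderable,
  as multi-channel coverage comparisons require — while an SNR-boosted
  channel (scale 0.3) stays at the ceiling; with `noise_sd = 0` both
  mechanisms vanish and every drowsy episode's θ/α ratio exceeds both
  neighbours on every channel.
* **EAR** — open-eye baseline 0.30 with Gaussian jitter, closures as
  trapezoidal dips (100-ms fall/rise, hold = closure duration) to 0.05.
  Blink trains are quasi-periodic: counts are rate × duration with mild
  lognormal variation and centres are evenly spaced with jitter. Purely
  Poisson arrivals were evaluated first and rejected: their low-count
  tail produces drowsy episodes that fail to express their own blink
  profile, which no scorer could recover. Drowsy episodes optionally
  guarantee one closure ≥ 1 s (the CLOSDUR premise).

Not emulated: real EEG nonstationarity beyond episode-level power
shifts (no artifacts, no 1/f background, no spindles/K-complexes),
head-pose or lighting effects on EAR, inter-subject physiology, and the
clinical characteristics of the study population. Passing tests
therefore demonstrate that the *pipeline* recovers structure it is
designed to detect under its stated assumptions — not field
performance on clinical recordings.

## Problem sizes and numerical choices

The analysis and acceptance runs use 10 subjects × 10-minute sessions
(~7 episodes each), chosen as the desk-scale cohort that exercises
every stage in seconds while leaving enough episodes (~70) for cohort
statistics. EDF output is 16-bit with per-channel fitted physical
ranges (round-trip error ≤ 2 quantization steps, verified against an
independent reader). Welch segments are min(2 s, epoch length); all
RNG streams derive from `numpy.random.default_rng([seed, subject,
stream])`.

## Known limitations

* The EDF writer covers continuous 16-bit EDF with 1-s records and
  integer sampling rates — sufficient for this analysis, not a general
  EDF+ implementation.
* The order-25 high-pass barely attenuates sub-hertz content (above);
  drift rejection relies on the short epochs and normalization.
* Visual scoring quantizes boundaries to the PERCLOS window.
* With small epoch counts per class, quartile-based thresholds (TM,
  IQR, RS) are noisy, and RS can be undefined for quantized features.
* The OR-combined accuracy rewards complementary over-predicting
  features (above); it is reported as defined, alongside coverage.
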