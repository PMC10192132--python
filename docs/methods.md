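# Methods

`hfdeeg` implements a nonlinear EEG complexity analysis: Higuchi fractal
dimension (HFD) features extracted per channel from multichannel
recordings, a data-driven procedure for tuning the estimator's `k_max`
hyperparameter, channel-level expert-vs-novice statistics, and binary
classification under three cross-validation split schemes. Because it is
exercised end-to-end on synthetic cohorts, this note states exactly what
the generator emulates, which defaults were open choices, and what passing
tests do and do not establish about real EEG.

## The estimator

For a series x(1..N), subsampling interval k and phase offset m ∈ {1..k},
the normalised curve length is

    L_m(k) = [ Σ_{i=1}^{M} |x(m+ik) − x(m+(i−1)k)| ] · (N−1) / (M·k²),
    M = ⌊(N−m)/k⌋,

L(k) is the mean over the k offsets, and HFD is the ordinary-least-squares
slope of log L(k) against log(1/k) for k = 1..k_max (natural log; the
slope is base-invariant). For self-affine signals L(k) ∼ k^(−D), giving
≈1 for smooth curves, ≈2 for uncorrelated noise, and 2−H for fractional
Brownian motion (fBm) with Hurst exponent H.

Numerical choices:

- every integer k from 1 to k_max enters the fit; no logarithmic
  subsampling of k;
- a constant window raises `DegenerateSignalError` (zero curve length has
  no log); callers that prefer skip-and-log handle it explicitly;
- `higuchi_fd` requires N ≥ 2·k_max so every (m, k) pair has at least one
  increment;
- the production path vectorises the (m, k) double loop with a strided
  zero-padded reshape; the test suite holds it to within 1e−10 of a plain
  triple-loop reference on random signals, and the scalar
  `curve_length_m` / `curve_length` functions expose the textbook formulas
  directly.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: two groups
(22 experts, 22 novices by default), 16 task presentations per subject in
matched algebraic/geometric (A/G) pairs with durations drawn once per pair
from 13–68 s and shared by every subject, one eyes-open rest recording per
subject, and a 129-channel montage whose 5 auxiliary leads ("VEOGL",
"HEOGL", "HEOGR", "VEOGU", "HEART") never enter analysis, leaving 124 EEG
channels. The default montage uses the 32 extended-10/20 labels plus 92
high-density filler sites (`HD01`–`HD92`); real vendor label sets vary, so
labels are fully configurable.

Brain channels carry spectrally synthesised power-law noise: amplitude
∝ f^(−β/2) with β = 5 − 2D, randomised phases, which is the spectrum of
fBm with D = 2 − H. This gives O(n log n) generation and direct control of
the target HFD. Structure on top of the base process:

- **Group effect.** During task only, channels in `effect_channels`
  (default four frontal high-density sites outside the 10/20 subset,
  mirroring the finding that the most discriminative channels are absent
  from the standard montage) get an FD offset `effect_delta_fd` (default
  +0.15) for the effect group (default novices — frontal complexity higher
  in novices). Rest recordings never carry the effect, making them the
  negative control.
- **Subject random effect.** One FD offset per subject (SD `subject_sd`,
  default 0.05) shared across all channels and recordings. This is the
  simplest structure that makes subject identity learnable, so pooled
  (case-1) cross-validation outperforms subject-wise (case-2) — the
  central methodological contrast.
- **Measurement noise.** Additive white noise at relative amplitude
  `noise_sd`. Default 0.005: white noise floors exactly the fine-scale
  increments HFD reads, and calibration runs showed that 5% noise
  compresses the estimated-vs-target FD regression slope to ≈0.3–0.45,
  while 0.5% keeps it at ≈0.75–0.80 — inside the generator's calibration
  guard (slope in [0.7, 1.3], monotone means over targets 1.2–1.8).
- **Band limit.** Spectral amplitudes above `highcut_hz` (default 40 Hz)
  are zeroed, emulating low-pass-filtered EEG. The cutoff biases HFD
  estimates down slightly (up to ≈0.1 at target 1.8 at 256 Hz), which is
  why the standalone validation synthesizer
  (`synthesize_fractal_signal`) defaults to no cutoff: estimator-validity
  checks compare against the exact fBm relation.
- Auxiliary channels carry unrelated white noise.

Default sampling rate is 256 Hz (desk scale); 2048 Hz is supported as a
configuration value. Cohorts are generated lazily: the manifest stores a
deterministic seed key per recording (derived from the cohort seed via
`SeedSequence`, with the subject FD offset keyed by a CRC32 of the subject
id so any recording regenerates in isolation), and signals materialise on
demand. Writing recordings to disk (columnar CSV, channel-label header,
one row per sample, `#`-prefixed metadata) is an explicit opt-in; a
full-rate default cohort is ~1 GB of samples and is not meant to be
stored as text.

What the generator does **not** emulate: event-related potentials,
oscillatory rhythms, eye blinks, line noise, electrode drift, volume
conduction or any spatial correlation between channels, non-stationarity
within a recording, and style (A vs G) effects. Passing tests therefore
show that the pipeline is correct and well-calibrated under its own
assumptions — channel-localised complexity differences on a stationary
power-law background — not that real expert/novice EEG is separable, and
no synthetic result is a reproduction of the original study's absolute
ΔHFD magnitudes or accuracy table.

## k_max tuning

The sweep computes, per candidate k_max (default grid
{2, 5, 20, 100, 150, 200, 400}), the grand-mean HFD over all recordings
and channels and the grand mean of the per-recording channel spread
(max-channel HFD − min-channel HFD, the min read as baseline complexity).
Curve lengths are computed once per recording up to the largest feasible
candidate and the slope refit per candidate; candidates needing more than
half a recording's samples are skipped with a warning and the per-candidate
recording count reported.

Selection formalises a dual criterion — spread maximised, mean HFD
plateaued — with a single relative tolerance `plateau_tol` (default 0.02):
among candidates within tolerance of the peak spread, take the smallest
whose mean HFD is within tolerance of the final candidate's; if none has
plateaued, the smallest spread maximiser. Ambiguity in whether the spread
should be maximised per subject before averaging is resolved as:
per-recording spread, then grand mean.

On synthetic power-law cohorts both the mean HFD and the spread keep
creeping upward with k_max (estimator variance grows with k), so the
selector typically lands on the largest candidate; the procedure's
contract — monotone-then-plateau mean, selection a stable member of the
grid — holds, but the peaked-then-declining spread shape seen on real EEG
is not reproduced by this generator.

## Channel statistics

The unit of analysis is the subject: HFD is averaged over presentations
(and windows) per channel first, then compared between groups, avoiding
pseudo-replication of the 16 presentations. The per-channel contrast is
the difference of group means of those subject means; the test is Welch's
two-sample t-test (pooled-variance available via `equal_var=True`),
one-sided by default in the direction novice > expert and switchable.
P-values are reported uncorrected at α = 0.05, with a
Benjamini–Hochberg-adjusted column always alongside. Ranking for top-k
reporting defaults to |Δ|, ties broken by channel label. The A-vs-G style
contrast is paired within subjects (paired t-test of within-subject
style differences against zero, two-sided by default).

Because the subject random effect is shared across channels, per-channel
null tests are strongly correlated within one cohort: a single cohort can
show many (or zero) nominally significant channels at rest purely from the
group-imbalance draw. Calibration is therefore assessed across replicate
cohorts, with error bars from the replicate-level spread rather than
channel-count binomials.

## Classification

Samples are subject-presentation pairs (704 × 124 at defaults). Split
schemes: `subject_presentation` (rows split freely; subject identity leaks
and inflates accuracy), `subject_specific` (subjects partitioned;
generalisation to unseen people), `presentation_specific` (one
presentation's 44 rows, split at subject level; windowed channel×window
features are supported here because durations match within a
presentation). Classifiers and grids: k-NN (3/5/7/9/11 neighbours),
linear SVM (C ∈ {0.025, 0.5, 0.75}), decision tree (depth 3/5/7),
AdaBoost (25/50/100 estimators). Hyperparameters are selected by mean
case-1 ten-fold cross-validated accuracy and then frozen for the other
schemes; results average folds and the fixed seed set {0, 1, 2}, which
drives both fold shuffling and classifier randomness. Features are
standardised with training-fold statistics only (distance- and
margin-based classifiers need comparable scales; toggleable). The metric
is plain validation accuracy — classes are balanced by construction.

The subject-concatenated case-2 variant (one sample per subject with all
presentations' features concatenated) is intentionally not the default;
the per-pair reading is the one consistent with 704 samples.

## Pipeline and reproducibility

`run_pipeline` chains generate → tune → extract → contrast → classify from
one config, expanding a single global seed into per-stage seeds via
`SeedSequence` so stages rerun independently. The run manifest records the
config snapshot, selected k_max, per-stage wall-clock and a SHA-256
checksum of every emitted file; identical (config, seed) runs produce
identical checksums, which the test suite asserts.

## Problem sizes

Monte-Carlo properties are scale-free, so the test suite and
`scripts/acceptance.py` run them on reduced cohorts chosen once: 8–12 EEG
channels, 4-second recordings at 128–256 Hz, k_max = 24 for feature
extraction, 5+5 to 22+22 subjects depending on what the property needs
(recovery and classification checks keep the full 22+22 group size), 10
replicates for power/stability checks and 100 for null calibration. The
full 44-subject, 129-channel, 256 Hz default cohort is exercised in the
dataset-structure check (704 × 124 feature matrix).

## Known limitations

- No EDF import/export; recordings interchange as columnar CSV plus a
  JSON manifest.
- The generator's channels are spatially independent; montage-reduction
  results quantify information loss from dropping effect channels, not
  realistic sensor-space redundancy.
- The k_max spread curve does not peak-then-decline as on real EEG (see
  above).
- HFD estimates carry a small negative bias at high target FD under the
  40 Hz band limit; analyses compare groups under identical conditions, so
  contrasts are unaffected, but absolute FD values should not be read as
  unbiased.
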