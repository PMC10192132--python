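# hfdeeg

Nonlinear EEG complexity analysis for expertise research: **Higuchi
fractal dimension (HFD)** features from multichannel EEG, data-driven
tuning of the estimator's `k_max` hyperparameter, channel-level
expert-vs-novice statistics with a resting-state control, and
expert/novice classification under three cross-validation split schemes —
all exercisable end-to-end on a synthetic EEG cohort with controllable,
channel-localised complexity effects.

It is aimed at researchers analysing EEG recorded during long,
naturalistic cognitive tasks (here: multi-slide math demonstrations
watched by math experts and novices), where linear oscillation and ERP
measures miss the nonlinear structure of the signal and where the choice
of cross-validation split decides whether a classifier measures real
generalisation or subject-identity leakage.

## The method

For a series x(1..N), interval k and offset m ∈ {1..k}, the normalised
curve length is

```
L_m(k) = [ Σ_{i=1}^{M} |x(m+ik) − x(m+(i−1)k)| ] · (N−1)/(M·k²),   M = ⌊(N−m)/k⌋
```

L(k) averages L_m(k) over the k offsets, and

```
HFD = slope of the OLS fit of log L(k) vs log(1/k),  k = 1..k_max
```

HFD ≈ 1 for smooth signals, ≈ 2 for uncorrelated noise, and 2 − H for
fractional Brownian motion with Hurst exponent H. `k_max` is tuned by
sweeping a candidate grid and picking the value that maximises the mean
max-minus-min HFD spread across channels, preferring the smallest
candidate at which the grand-mean HFD has plateaued.

Downstream, per-channel contrasts Δ = mean(expert) − mean(novice) of
subject-level mean HFD are tested with one-sided Welch t-tests (BH-adjusted
column included), and subject-presentation samples (44 subjects × 16
presentations → 704 × 124 at defaults) are classified with k-NN, linear
SVM, decision tree and AdaBoost under pooled (case 1), subject-wise
(case 2) and presentation-wise (case 3) splits.

Since the underlying human EEG is not redistributable, the package ships
a first-class synthetic cohort generator (spectral synthesis of power-law
noise, FD-controlled per channel, group effect on chosen channels during
task only, per-subject random FD offsets) so every stage is testable.
See `docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
import hfdeeg as h

montage = h.MontageSpec.default()            # 124 EEG + 5 auxiliary channels
config = h.CohortConfig(n_experts=8, n_novices=8, n_presentation_pairs=2,
                        duration_range=(8.0, 12.0), seed=7)
cohort = h.generate_cohort(config, montage)  # lazy, deterministic

features = h.extract_features(cohort, h.HfdParams(k_max=100), conditions=("task",))
contrasts = h.channel_tests(features)        # expert − novice, one-sided
print(h.top_channels(contrasts, 5).to_string(index=False))
```

```
channel     delta    t_stat  p_value  p_adj_bh  significant  rank
   HD03 -0.105599 -7.676817 0.000004  0.000271         True     1
   HD04 -0.104534 -7.009790 0.000006  0.000271         True     2
   HD01 -0.102083 -6.720370 0.000007  0.000271         True     3
   HD02 -0.101802 -6.912698 0.000011  0.000328         True     4
   HD15  0.017077  1.165886 0.865690  0.865690        False     5
```

The four configured effect channels (HD01–HD04, carrying a +0.15 FD
offset for novices during task) head the ranking with negative
expert−novice deltas of ≈ −0.10 — the injected 0.15 compressed by the
band limit and estimation noise — and are the only significant channels;
the first null channel (HD15) shows a near-zero delta. Classification on
the same features:

```python
samples = h.assemble_samples(features, montage)   # 64 samples × 124 features
report = h.run_grid(samples, schemes=("subject_presentation", "subject_specific"),
                    hyperparameters={"linear_svm": {"C": 0.5}})
print(h.best_per_scheme(report).to_string(index=False))
```

```
              scheme presentation_id   algorithms  accuracy
subject_presentation            None [linear_svm]       1.0
    subject_specific            None [linear_svm]       1.0
```

With an effect this strong both splits saturate; shrinking
`effect_delta_fd` toward the per-subject variability (`subject_sd`) opens
the case-1 > case-2 gap that makes subject-wise validation the honest
benchmark.

A command-line interface mirrors the stages:

```bash
hfd cohort --out cohort/ --seed 7      # generate + store a cohort
hfd inspect cohort/
hfd extract --data cohort/ --kmax 100 --out features.csv
hfd tune-kmax --data cohort/ --out sweep.csv
hfd contrast --features features.csv --mode group --out contrasts.csv
hfd classify --features features.csv --scheme case2 --out results/
hfd run --seed 0 --out run/            # full pipeline + checksummed manifest
```

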