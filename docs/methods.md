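# Methods

This note documents the models, rules, and numerical choices behind
`phenostress`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort

**Latent stress schedule.** Each subject's stress is a piecewise-constant
latent level in 1..5 over the simulation horizon. Nighttime (clock
00:00–06:00) is forced to level 1; daytime segments last 30–90 min
(uniform) and draw their level i.i.d. from a distribution heavily skewed
toward "no stress" — defaults `(0.504, 0.353, 0.10, 0.04, 0.003)`, matching
the self-report imbalance typical of healthy working populations (~50 % no
stress, well under 1 % extreme stress). A separate activity trace adds
daytime movement bouts (0.8/h, 15 min, intensity 0.3–1.0). The daytime
level distribution is a configuration, not a claim of fidelity to any
particular population.

**Phenotypes.** Subjects are *responsive* or *blunted*. Full-scale (level
1 → 5) effects default to: heart rate +10 vs +1 bpm, SCR arrival rate
+3/min vs +0.3/min, skin temperature −1.0 vs −0.1 °C, and RR-modulation
shrinkage 0.5 vs 0.05. Effects scale linearly with (level − 1)/4. The
responsive margin is strictly positive on every channel, so phenotype
recovery is a well-posed target. Questionnaire scores are drawn
phenotype-conditionally (blunted: higher PSS/DASS/PSQI), mirroring the
empirical association between blunted stress reactivity and poorer
self-reported health.

**Signals.**

- *Beats*: RR(t) = 60000/HR(t) + LF (0.1 Hz) and HF (0.3 Hz) sinusoidal
  modulation (25/20 ms, shrunk under stress) + white noise (8 ms);
  HR(t) = baseline + stress effect − 10 bpm at night. R-peak times are
  emitted directly: every downstream computation consumes beats, so ECG
  waveform synthesis would add cost without adding testable structure.
- *Skin conductance*: tonic level (baseline + 1.1 µS at night + slow
  sinusoidal drift) plus Poisson-arriving SCRs — 1 s linear rise,
  exponential decay τ = 4 s, log-normal amplitudes (median 0.3 µS,
  σ_log = 0.5) — plus 0.01 µS noise, clipped at 0. SC is simulated and
  processed at a configurable rate (default 8 Hz; the wrist hardware
  contract is 256 Hz) — all SC rules are rate-parameterized and the band of
  interest is < 1 Hz, so the lower default only changes runtime.
- *Skin temperature* (1 Hz): baseline + 1.7 °C at night + stress effect +
  slow drift + 0.05 °C noise.
- *Accelerometer magnitude* (32 Hz): mean 1 g, SD = 0.015 + 0.12 × activity
  intensity, so rest windows sit below the 0.04 activity threshold and bout
  windows above it.
- *EMA*: 12 prompts/day at random times in 08:00–22:00 with a ≥ 30-min gap
  (sorted-uniform-plus-spacing construction, so constraints hold by
  construction). The reported level equals the latent level at the prompt,
  perturbed ±1 with probability 0.05 (`ema_misreport_prob`), which separates
  label noise from physiological blunting in experiments. Pleasure is
  negatively, arousal positively coupled to the reported level. Prompt
  hours are a convention (the waking window is configurable).

All timestamps are timezone-naive seconds from day-1 midnight. Cohorts are
bitwise-reproducible: one `SeedSequence` per cohort spawns independent
child streams per subject and channel.

**What the simulator does not emulate:** realistic ECG/SCR morphology
beyond the canonical shapes, respiration and its effect on HF power,
posture/temperature confounds, missing-by-nonwear patterns, weekday
structure, or smartphone context streams. Passing tests therefore
demonstrate that the *pipeline machinery* recovers known ground truth under
the stated generative model — not that the classifier would reach any
particular accuracy on real recordings.

## Quality indicators

ECG verdicts are per 10-s beat segment. Inter-beat gaps include the leads
from segment edges to the first/last beat, so empty or half-covered
segments fail the 3-s rule rather than passing vacuously. The ratio rule
fails at max(RR)/min(RR) ≥ 2.2 exactly ("less than 2.2" is the passing
condition). The adaptive template is the mean 8-point RR *quantile* profile
of the last 5 accepted segments; the match statistic is
1 − mean|profile − template| / mean(template), accepted at ≥ 0.66, seeded
by the first segment passing the three explicit rules and updated only from
accepted segments. A temporal-profile correlation was rejected at design
time: clean RR profiles are near-constant with phase-shifted modulation, so
correlations between healthy segments are centered on zero and any
correlation threshold destroys specificity. The scale-normalized quantile
distance passes constant and physiologically variable RR (measured
false-bad rate ~0 on clean simulation), and fails wholesale shifts of the
RR distribution (e.g., a sustained halving of heart rate against a
40-bpm-compatible template history).

SC verdicts are per 5-s segment: lost-signal fraction (< 0.001 µS) must not
exceed 0.9, and consecutive 1-s means must not rise > 20 % or fall > 10 %
(relative to the preceding 1-s mean, floored at the lost threshold to avoid
division blow-ups). The comparator for "per second" changes was left
unstated upstream; adjacent 1-s aggregates are used and configurable. ST is
judged per sample, inclusive bounds [20, 40] °C. The trailing partial
segment of any channel is marked bad (conservative). Window quality is the
time-weighted good fraction; inclusion is *strict* (> 0.8).

## Features

Windows are 300 s at a 60-s hop, aligned to the recording start (no
clock-minute snapping), giving floor((T − 300)/60) + 1 rows. Frequency-domain
HRV cubic-interpolates the RR tachogram to 4 Hz, removes a linear trend, and
integrates a single-segment Hann periodogram over 0.04–0.15 Hz (LF) and
0.15–0.40 Hz (HF); LF/HF is missing when HF = 0, and spectral features are
missing when beats span < 60 s. The SC tonic component is a second-order
zero-phase Butterworth low-pass at 0.05 Hz; phasic is the residual, so
tonic + phasic reconstructs the input exactly. SCRs are trough-to-peak rises
≥ 0.01 µS completed within 5 s; SCR area integrates the phasic deviation
above each onset over ≤ 10 s, truncated at the next onset. In `extract_all`
the tonic filter and the tachogram are computed once per recording and
sliced per window — this avoids zero-phase-filter edge transients at window
borders; the standalone per-window functions keep the window-local contract
and agree with brute-force formulas to 1e-9.

Feature identities: the six ECG features are mean HR, RMSSD, SDNN, LF, HF,
LF/HF (SDNN chosen as the sixth; any canonical time-domain HRV summary
would serve). The eight SC features are tonic mean, phasic power, SCR area,
SCR count, mean |first difference|, mean |second difference|, tonic slope
and SD — tonic/phasic/area/second-difference are canonical EDA summaries,
the rest are standard window statistics. ST contributes mean, median,
least-squares slope (°C/s) and SD. Missing-feature policy: a window failing
one channel's quality gate gets missing values for that channel's features
only.

## Dataset assembly

A report at prompt time T labels rows with window_start in [T − 60 min, T);
overlapping lookbacks (possible with 30-min prompt spacing) are resolved by
the later prompt. Night state N is [00:00, 06:00), day [06:00, 24:00),
half-open. Row-level quality is the minimum across the three channel
fractions. The ≥ 10-min rule drops a labeled hour when fewer than 10 of its
rows survive the quality/activity screens. The activity bound is inclusive
(ACC SD ≤ 0.04). Z-normalization is per subject over retained rows;
zero-variance features map to 0 rather than dropping the subject.
Redundancy pruning runs on pooled normalized rows (Spearman, threshold
0.7), visiting features in the documented canonical order and dropping the
later member of any offending pair — deterministic and row-order invariant.
In practice RMSSD is pruned in favour of mean HR (their rank correlation is
near −1), matching the strong empirical coupling of the two.

## Modeling

LOSO: one fold per subject; training folds impute missing features with the
training median, select features by univariate ANOVA-F p-values with BH at
α = 0.05 (falling back to all features if none survive), and fit a random
forest (200 trees, √p features per split, min_samples_leaf 10, 30 %
bootstrap per tree — chosen for desk-scale LOSO runtime and configurable).
No fitted state crosses folds; per-subject normalization is fold-independent
by construction. The score is macro F1 over the classes present in the
subject's true labels (weighted averaging available by config); the
baseline predicts the training-fold majority class. Group cuts: F1 < 0.33
low, > 0.66 high, boundaries to medium (the defining intervals are open).
Dynamic range is the per-subject mean(S3) − mean(S1) contrast averaged
within group; subjects lacking either state are excluded per feature.

## Statistics

State medians are population medians of per-subject-normalized features;
pairwise contrasts use the Wilcoxon rank-sum test (exact for small
tie-free samples, tie-corrected normal approximation otherwise, via
scipy's auto policy), BH-corrected across the full feature × pair family,
with nested significance tiers 0.05/0.005/0.0005. Population summaries
report the mean and the central 95 % *population* interval (2.5th–97.5th
percentiles of pooled window values) — a spread descriptor, not a standard
error of the mean. BH adjustment delegates to statsmodels and is tested
against brute-force step-up enumeration.

## Problem sizes

Default experiment sizes: the phenotype-recovery study uses 30 subjects ×
2 days (responsive fraction 0.5, misreport probability 0.05); formula
oracles use 100 random inputs; BH checks use 1,000 random p-vectors and
1,000 null replicates; the random-F1 anchor uses 10,000 samples. Longer
horizons (30+ days) are used where a single channel suffices (effect
recovery, EMA constraints).

## Known limitations

- The template-match stage operates on beat intervals, not QRS waveforms;
  its discriminative power beyond the three explicit rules is limited to
  distributional shifts of RR.
- SCR overlap at high arrival rates biases detected amplitudes and areas
  downward; the detector is not a deconvolution.
- Stay-location clustering assumes planar coordinates in meters; no
  geodesic handling or GPS noise model.
- Group comparisons inherit the usual caveats of small per-group n at desk
  scale; the high-performance group can be small or empty for unlucky
  seeds, in which case downstream contrasts fall back to a median split on
  F1 (only in the summary script).
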