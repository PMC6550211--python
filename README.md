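# phenostress

Digital phenotyping of daily-life stress from wearable physiology.

Ambulatory studies pair multi-day wearable recordings — R-peak (heartbeat)
series, skin conductance (SC), skin temperature (ST) and accelerometer
magnitude (ACC) — with smartphone stress self-reports (ecological momentary
assessment, EMA: 12 prompts/day on a 5-point Likert scale, ≥ 30 min apart).
The analytic question is whether window-level physiology predicts the
self-reported stress state, and — since stress responses are strongly
person-dependent — which *subjects* it works for. `phenostress` implements
that analysis end to end for researchers in ambulatory psychophysiology,
plus a fully specified synthetic-cohort generator so every stage is testable
without access to private study data.

## What the pipeline computes

1. **Signal quality.** Rule-based per-segment indicators: ECG beat series on
   10-s segments (mean HR ∈ [40, 180] bpm, no inter-beat gap > 3 s,
   max(RR)/min(RR) < 2.2, adaptive beat-interval template match), SC on 5-s
   segments (signal "lost" below 0.001 µS with a 0.9 lost-ratio cap; per-second
   rise ≤ +20 % and fall ≤ −10 %), ST per sample (20–40 °C). Verdicts
   aggregate to window-level quality fractions.
2. **Features.** On 5-min windows with 4-min overlap (one row per minute):
   6 ECG/HRV features — mean HR = 60000 / mean(RR), RMSSD = √mean(ΔRR²),
   SDNN, LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) tachogram band power,
   LF/HF — 8 SC features (tonic mean, phasic power, SCR area, SCR count,
   |Δ|, |Δ²|, tonic slope, SD), 4 ST features (mean, median, slope, SD), and
   ACC SD as the physical-activity proxy.
3. **Dataset assembly.** Each EMA report labels the 60 rows of its preceding
   hour; Likert levels collapse to S1 (no stress), S2 (light), S3 (high,
   merging levels 3–5); 00:00–06:00 rows form the nighttime baseline N.
   Inclusion: quality fraction > 0.8, ACC SD ≤ 0.04, ≥ 10 retained rows per
   labeled hour, subjects with a single reported state discarded. Features
   are z-normalized per subject and pruned at |Spearman r| > 0.7.
4. **Phenotyping.** Leave-one-subject-out (LOSO) random forests with
   fold-internal FDR feature selection (Benjamini–Hochberg, α = 0.05);
   per-subject macro F1 defines low (< 0.33), medium and high (> 0.66)
   performance groups, characterized by per-feature dynamic range
   (mean S3 − S1 contrast), label imbalance, and questionnaire scores
   (PSS, DASS, PSQI) with Kruskal–Wallis / rank-sum / χ² tests.
5. **Descriptive statistics.** Population medians of normalized features per
   state with all six pairwise contrasts (N–S1 … S1–S3), rank-sum tested and
   BH-corrected at FDR 0.05; per-state population summaries.

The synthetic cohort assigns each subject a latent phenotype — *responsive*
(large heart-rate, electrodermal and skin-temperature stress effects) or
*blunted* (near-zero effects, poorer questionnaire scores) — and a latent
piecewise-constant stress schedule that drives both physiology and EMA
answers, so recovery of the phenotype signature is a testable claim.

## Worked example

```python
from phenostress.pipeline import run_study
from phenostress.config import SimConfig

res = run_study(n_subjects=30, responsive_fraction=0.5, seed=1,
                sim=SimConfig(days=2))
m = res.model.per_subject.merge(res.profiles[["subject_id", "phenotype"]],
                                on="subject_id")
print(m.groupby("phenotype")["f1"].mean().round(3))
print("mean F1 =", round(res.model.mean_f1, 3),
      " majority baseline =", round(res.model.per_subject.baseline_f1.mean(), 3))
print("groups:", res.groups.value_counts().to_dict())
```

Output:

```
phenotype
blunted       0.341
responsive    0.573
Name: f1, dtype: float64
mean F1 = 0.457  majority baseline = 0.230
groups: {'medium': 21, 'low': 6, 'high': 3}
```

Blunted subjects — whose physiology barely tracks their latent stress —
classify near the majority-class baseline, while responsive subjects reach
F1 well above it; the high-performance group also shows the larger
S3 − S1 dynamic range for most features (9 of 11 retained features in this
run). That performance split *is* the digital-phenotype signature the
pipeline is built to detect.

The same analysis is available from the shell:

```bash
phenostress run --subjects 30 --days 2 --seed 1 --out results/
phenostress simulate --subjects 10 --days 5 --seed 7 --out cohort/   # CSV export
```

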