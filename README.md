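# afburden

Continuous atrial-fibrillation (AF) burden tracking from per-minute wearable
rhythm epochs.

Paroxysmal AF is traditionally assessed with episodic, binary snapshots
(a symptom visit, a 24-hour Holter) that miss how the arrhythmia actually
evolves.  Wrist-worn photoplethysmography (PPG) devices can classify the
rhythm minute by minute for weeks, but their output is noisy (motion
artifacts invalidate a large share of daytime epochs) and a raw AF/sinus
label stream is not yet a clinically interpretable description of disease
progression.  `afburden` is a toolkit for researchers working with such
paired wearable/Holter epoch data.  It provides:

* **Multiscale fusion** — signal-quality gating, a per-epoch classifier
  contract (with a deterministic interbeat-interval-irregularity reference
  stand-in), and contextual fusion that re-estimates each epoch's AF
  probability from a short weighted window of neighbors, exploiting the
  temporal continuity of AF episodes.  Yield-rate accounting (valid epochs /
  total epochs, overall and by clock window) quantifies artifact tolerance.
* **A 5-dimensional spatiotemporal progression model** — 15 metrics in five
  dimensions: *number* (AF-epoch ratio; rates of episodes ≥ 6 min and
  ≥ 1 h), *duration* (overall burden and the burden of sustained/prolonged
  episodes), *aggregation* (a Lorenz-type AF density index of burst-like
  clustering), *circadian rhythm* (CV of episode onset time, signed
  day/night contrast VOM, burden variabilities, average real variability of
  hourly burden), and *tachycardia* (fraction of valid time above 120 bpm).
* **A composite burden score** — min–max feature normalization, weights
  integrating |r|, R² and ICC per feature, a weighted sum on [0, 1], and an
  optimal diagnostic cutoff against clinical events by Youden's
  J = sensitivity + specificity − 1.
* **Agreement statistics** — MAE, Pearson/Spearman/Kendall-τb, R² with
  bootstrap CI, ICC(2,1) absolute agreement with F-based CI,
  sensitivity/specificity/accuracy with Wilson score CIs, ROC/PR curves,
  and the Kruskal–Wallis H test.
* **A seeded synthetic cohort generator** — paired index/reference epoch
  streams with circadian inhomogeneous-Poisson episode onsets, a lognormal
  duration mixture spanning the three duration strata, tachycardic AF pulse
  rates, daytime-dominant artifact masking and graded classifier noise,
  plus clinical labels (EHRA class, event flags) linked to true burden.

## Core definitions

With per-minute epochs labeled AF / SINUS / INVALID, all ratios use *valid*
(non-INVALID) epochs as denominator.  For valid epoch *i* with AF
probability *pᵢ*, the fused probability over a window of half-width *W* with
weights *w₀ ≥ w₁ ≥ … ≥ w_W* is

    p̃ᵢ = Σ_{|k| ≤ W, i+k valid} w_{|k|} p_{i+k}  /  Σ_{|k| ≤ W, i+k valid} w_{|k|}

and the epoch is AF iff p̃ᵢ ≥ 0.5 (defaults: W = 2, triangular weights
3-2-1).  AF burden is AF epochs / valid epochs.  The AF density index is

    D = ∫₀¹ |C(u) − u| du / ((1 − b)/2)

where u indexes valid time, C(u) is the cumulative fraction of AF time and
b the burden; D = 1 when all AF forms a single block at either end of
monitoring, and D → 0 for perfectly interleaved AF.  Agreement between the
index device p and reference g uses MAE = Σ|pᵢ − gᵢ|/n, ICC(2,1) (two-way
random effects, absolute agreement) and Youden-maximizing cutoffs with
subjects positive iff score ≥ cutoff.

## Worked example

```python
from afburden import (SimParams, simulate_cohort, FusionConfig,
                      gate_quality, contextual_fuse, yield_rate,
                      extract_features)

params = SimParams(seed=7, n_subjects=2)       # 24 h per subject
cohort = simulate_cohort(params)
s = cohort.subjects[0]

fused = contextual_fuse(gate_quality(s.index, 0.5), FusionConfig())
print(yield_rate(fused))
# {'overall': 0.701, 'day': 0.599, 'night': 0.906}

vec = extract_features(fused)
print(round(vec.burden_all, 4), round(vec.af_density, 4), round(vec.vom, 4))
# 0.0426 0.5504 1.0
```

The yield rates say that 70.1% of this subject's monitoring minutes carried
a valid rhythm decision, with the night window (90.6%) much cleaner than
the day window (59.9%) — the signature of daytime motion artifacts.  The
fused stream spends 4.26% of its valid time in AF (the noiseless truth for
this subject is 5.0%), that AF time is moderately clustered
(density 0.55), and it falls entirely in the daytime window (VOM = +1).

The same pipeline is available from a shell:

```sh
afburden simulate --config cfg.yaml --out sim/ --seed 7
afburden fuse --in sim/S0000_index.csv --out fused.csv
afburden features --in fused.csv --out features.csv
afburden run --config cfg.yaml --out results/   # full pipeline + manifest
```

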