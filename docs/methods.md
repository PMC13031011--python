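# Methods

## Epoch streams and episodes

The unit of analysis is the 1-minute epoch: a left-closed right-open window
carrying a rhythm label (AF / SINUS / INVALID), an optional AF probability,
an optional mean pulse rate and a signal-quality score.  Timestamps are
local clock time, because the circadian metrics are clock-time constructs.
Streams must be strictly increasing at a constant 1-minute cadence; readers
fill timestamp gaps with INVALID epochs so that every ratio has a
well-defined total-time denominator.  INVALID epochs count toward total
monitoring time but never toward valid time, and every burden-type ratio in
the package is taken over valid time.

An AF episode is a maximal run of AF epochs.  Runs separated only by a
short run of INVALID epochs are merged (default bridging gap: 3 minutes):
an unreadable stretch inside one physiological episode should not fragment
it, whereas a confirmed SINUS epoch — evidence of an actual rhythm change —
always terminates the episode.  Bridged invalid minutes inflate an
episode's duration (onset to last AF epoch inclusive) but never its AF
epoch count, so burden is unaffected by bridging.  Whether an episode
interrupted by unreadable signal is one episode or two is not observable;
the bridging rule is this package's construction and the gap is a
parameter.

The daytime window is [06:00, 22:00) and night is its complement, used
consistently for day/night yield, VOM and the day/night variabilities.

## Multiscale fusion

Fusion has three stages.  (1) Quality gating relabels epochs below a
quality floor (default 0.5) as INVALID; the stage is idempotent.  (2) The
per-epoch classifier is a *contract*: any function mapping an epoch with at
least 12 interbeat intervals (250–2500 ms) to an AF probability plugs in.
The bundled reference scorer is a deterministic irregularity index — the
mean absolute circular successive difference of the intervals, normalized
by the mean interval, combined with the Shannon entropy of the
normalized-difference histogram and squashed through a fixed logistic.
Circular differences make the score exactly invariant to duplicating the
input, which is the operational meaning of length-adaptivity here.  The
scorer is a stand-in that satisfies the contract; it is not a trained
model and no claim is made that it matches any commercial device's
classifier.  (3) Contextual fusion replaces each valid epoch's probability
with a validity-masked weighted mean over a symmetric window (default
half-width W = 2, triangular weights 3-2-1) and thresholds at 0.5.  The
window covers 5 minutes, deliberately shorter than the 6-minute episode
stratum so that genuine short episodes survive smoothing.  Valid epochs
without a probability fall back to their {0, 1} label encoding, so fusion
degrades gracefully to weighted majority voting.  Fusion operates on
probabilities rather than hard labels because graded evidence dominates
voting whenever the classifier is better than random and collapses to it
otherwise.

## The 5D spatiotemporal feature model

Fifteen metrics, five dimensions; denominators are valid epochs throughout;
a feature whose preconditions fail is *missing* (NaN), never silently 0.

* **Number**: AF epochs / valid epochs; episodes ≥ 6 min / valid epochs;
  episodes ≥ 1 h / valid epochs.  Duration strata are closed bounds (≥ 6,
  ≥ 60 minutes).
* **Duration**: burden overall and restricted to episodes ≥ 6 min / ≥ 1 h
  (AF time of an episode = its AF epoch count).
* **Aggregation — AF density**: with u ∈ [0, 1] indexing valid time and
  C(u) the cumulative fraction of AF time (piecewise linear through the
  per-epoch cumulative counts), D = ∫|C(u) − u| du / ((1 − b)/2), where b is
  burden and the normalizer is the integral attained by a single AF block
  at either end of monitoring.  The integral is evaluated exactly segment
  by segment (the |·| of a linear segment integrates in closed form, also
  across zero crossings).  D is a Lorenz-type deviation-from-uniform-
  accumulation index: 1 for maximal clustering, and for a perfectly
  interleaved stream it equals 1/n_AF (n_AF = number of AF epochs), hence
  → 0 with monitoring length.  D is defined as 0 at b ∈ {0, 1}, where no
  localization contrast exists.
* **Circadian**: CV of episode onset clock time (sample SD / mean of
  minutes-after-midnight; linear, not circular, statistics — a circular
  variant would change the scale and the plain CV is the conventional
  report); VOM, the signed symmetric day/night contrast
  (f_day − f_night)/(f_day + f_night) of AF-epoch frequency per valid
  epoch, in [−1, 1] and 0 when both windows are AF-free; AF variability,
  the SD of per-day burden when at least two days have ≥ 12 h of valid
  data, else the SD of the hourly burden series (the day scale is
  preferred when multi-day data exist; under a single 24-h recording the
  hourly scale is the only one available); day/night variability, the SD
  of hourly burden within each clock window; ARV, the mean absolute
  successive difference of hourly burden over adjacent hours with valid
  data.
* **Tachycardia**: fraction of valid minutes/epochs with pulse strictly
  > 120 bpm.  With 1-minute epochs the two ratios coincide identically;
  both are kept because they are distinct constructs that only coincide at
  this epoch length.

## Composite score and cutoff

Features are min–max normalized on the training cohort so the score lies on
[0, 1] and a cutoff value is directly interpretable; zero-variance and
all-missing features are dropped with a warning and missing values are
imputed as 0 after scaling (absence of evidence of burden scores as no
burden).  Per-feature weights integrate the agreement of that feature
between index device and reference: raw weight = mean(|r|, R², max(ICC, 0)),
renormalized to sum to 1.  The arithmetic mean is the minimal symmetric
integration of the three named ingredients; geometric-mean and
user-supplied modes are provided.  The composite score is the weighted sum,
clamped to [0, 1], and is monotone non-decreasing in every feature.

The diagnostic cutoff maximizes Youden's J over candidate thresholds at
midpoints between consecutive sorted unique scores (±∞ sentinels included),
classifying positive iff score ≥ cutoff, ties broken toward the smallest
cutoff.  The search is exact (verified against exhaustive enumeration).

## Agreement statistics

MAE = Σ|pᵢ − gᵢ|/n.  The correlation battery reports Pearson r (t-based p),
Spearman rho (Pearson on midranks, t-approximation) and Kendall tau-b
(tie-corrected, normal-approximation p) — the standard large-sample forms.
R² is the squared Pearson correlation (equivalently the OLS variance
decomposition of reference on index), with a seeded percentile bootstrap
95% CI over subjects.  ICC(2,1) — two-way random effects, absolute
agreement, single measure — is computed from the ANOVA mean squares

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with the McGraw–Wong F-based 95% CI, and is reported with the conventional
bands (> 0.75 excellent, 0.50–0.75 moderate, < 0.50 poor).  Per-epoch
diagnostic metrics join the two streams on exact timestamps, exclude
epochs invalid on either device, and report sensitivity, specificity and
accuracy with Wilson score 95% CIs (no continuity correction); ROC/PR
curves use a full threshold sweep with trapezoid AUC (equal to the
Mann–Whitney statistic, including under ties) and a seeded bootstrap AUC
CI.  Kruskal–Wallis uses midranks with tie correction and a chi-square
reference; all observations identical is taken as H = 0, p = 1.  All tests
are two-sided at α = 0.05 and no multiple-testing correction is applied;
reports state this in their header.

Statistics whose preconditions fail (zero variance, a single class, too few
pairs) are missing, never 0 — a missing correlation and a zero correlation
mean different things.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised and tested.  Per subject, AF episode onsets follow an
inhomogeneous Poisson process λ(t) = ρ(1 + A cos(2π(t − φ)/24 h)) simulated
by thinning; durations are a three-component lognormal mixture; overlapping
episodes merge; pulse rates are drawn per epoch from a sinus or AF
distribution.  Defaults: ρ = 0.15 episodes/h, A = 0.5, φ = 03:00 (nocturnal
onset predominance), mixture weights (0.50, 0.35, 0.15) with medians
≈ 2.5, 20 and 150 minutes (log-SDs 0.5/0.5/0.6), spanning the < 6 min /
6 min–1 h / ≥ 1 h strata with a stationary expected burden of ≈ 9% —
a realistic paroxysmal-AF profile in which short episodes dominate counts
while long episodes dominate burden.  Sinus pulse ≈ 75 ± 8 bpm, AF pulse
≈ 110 ± 18 bpm, so a meaningful share of AF epochs crosses the 120 bpm
tachycardia threshold.

The index-device channel marks epochs INVALID independently at 0.40
(daytime) and 0.10 (night) — ≈ 30% overall with the daytime dominance of
motion artifacts — and emits classifier probabilities centered at
0.5 ± 0.3 (AF vs sinus) with additive Gaussian noise (SD 0.15), clamped to
[0, 1] and thresholded at 0.5.  The graded-probability channel, rather
than hard label flips, is what gives contextual fusion evidence to
exploit; a hard-flip mode is retained for worst-case tests.  The reference
channel has a 2% artifact rate and no classifier noise.  Clinical event
flags are Bernoulli with a logistic link from true burden
(α = −2.5, β = 4); EHRA classes are cohort quartiles of true burden
(I–IV, 10% ordinal jitter, class 0 at zero burden), creating a monotone
burden–symptom gradient without asserting any particular effect size.

All randomness descends from one integer seed; per-subject and per-device
generators are derived deterministically, so equal seeds give bit-identical
cohorts, features and reports.

What the generator does **not** emulate: real PPG waveforms and their
artifact structure (artifacts here are independent Bernoulli, not bursty),
classifier error correlated with rhythm or motion, inter-subject variation
in onset rate or episode-duration mixture, treatment effects on the AF
process, and device clock drift.  Passing tests therefore demonstrate the
internal correctness and statistical calibration of the pipeline under a
plausible generative model — not field performance of any device.

## Numerical choices and degenerate inputs

Epoch alignment for agreement uses exact timestamp joins.  Candidate Youden
cutoffs include ±∞ so the all-positive rule is always considered.  The
Wilson interval endpoints at k = 0 and k = n are set to exactly 0 and 1
(the closed-form values), avoiding 1e-18 round-off leaking into boundary
comparisons.  ICC confidence bounds are clamped to contain the point
estimate; when MS_E = 0 (perfect agreement) the CI is omitted.  Feature
extraction on a stream with zero valid epochs returns an all-missing
feature vector; cohorts of fewer than two subjects cannot be normalized or
weighted.  The acceptance script and all stochastic tests derive every
generator from explicit seeds.

## Problem sizes

Test and script problem sizes are the package's own choices, balancing
statistical resolution against a quick default run: the exhaustive episode
oracle covers all label strings up to length 8 plus seeded 50-epoch
strings; the fusion-gain experiment uses 200 simulated days; cutoff
recovery uses 1000 subjects with 10% label noise; Kruskal–Wallis
calibration uses 2000 null replicates; the acceptance pipeline simulates a
60-subject, 24-hour cohort (≈ 86 000 epochs per device).
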