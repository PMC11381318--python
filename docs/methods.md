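# Methods

This note documents the models, algorithms, and design choices behind
`tanlab`, the defaults that matter, and what the synthetic-data generator
does and does not emulate.

## Task model

Two task variants share one 6 s trial skeleton with the cue 1 s after trial
start. In the time-estimation task (TET) the cue side indicates a minimum
waiting interval (`short_threshold`/`long_threshold` seconds from cue
onset); a trial is *correct* when the bar is released between the threshold
and threshold + `limited_hold` (default 2 s) and the target is touched
within `movement_time_limit` (default 1 s) of release. Release before the
threshold is an *underestimation*, after the hold a *late release*, a slow
reach a *slow movement*; trials without release or contact are *excluded*.
A release at exactly the threshold counts as correct (the waiting period
has elapsed); this boundary rule is a package decision. In the Pavlovian
variant (PCT) reward follows the cue at the fixed threshold delay and every
trial is correct.

Preset geometries: thresholds 1.3/2.3 s (`monkeyC_*`) and 1.0/2.0 s
(`monkeyD_*`); both PCT presets use 1.0/2.0 s delays.

## Behavioral generator

Movement onset times are drawn per interval from a normal truncated at
zero with SD = `weber_fraction` × mean, so the coefficient of variation is
constant across intervals — the scalar (Weber) property. The default
`weber_fraction` is 0.15, a typical CV for primate interval production in
the seconds range. Cue sides are pseudorandom, balanced within blocks of
10; any non-correct trial enqueues an immediate repetition of the same
side, as the task rules prescribe.

No numeric MOT distributions are published for this task, so the preset
means are anchored to the reported *reward rates* instead: with CV 0.15, a
mean of threshold + 0.40 s (monkey C preset) gives ≈ 89% correct pooled
over intervals and threshold + 0.225 s (monkey D preset) gives ≈ 82%,
matching the reported block-wise reward rates of the two animals. These
offsets were fixed once from the closed-form truncated-normal calculation.
`p_no_response` (default 0.02 in presets) produces excluded trials.

The documented skew of one animal's short-interval MOT distribution is not
modeled by default; the generator is deliberately the simplest process
satisfying the scalar property.

## Spike-train generator

Tonic firing is a gamma-interval renewal process: inter-spike intervals
are Gamma(shape = `firing_regularity`, mean = 1/rate). Shape 2 (TAN
default) is more regular than Poisson, matching the clock-like TAN
baseline; PANs use shape 1 (Poisson). A stationarizing prefix of 20 mean
intervals is discarded.

Event-locked responses multiply the baseline rate by `rate_factor` over
`[latency, latency + duration)` after the alignment event; overlapping
windows multiply. Modulation is realized by **time rescaling**: the renewal
process runs homogeneously in operational time Λ(t) = ∫ factor(u) du and
spikes are mapped through Λ⁻¹. Unlike thinning a non-Poisson renewal
process, rescaling preserves the renewal structure exactly and makes the
expected aligned-window rate equal factor × baseline, so injected pause
depths are recovered without bias (rate-conservation and depth-recovery
properties are tested at 3 SD / ±0.05 tolerances).

Two optional couplings tilt the per-trial pause depth linearly, in percent
points of magnitude: with the trial's MOT (centered on the mean MOT of
applicable trials, so the average depth is unchanged) and with the trial's
1-based position inside a streak of correct trials. The resulting factor is
clipped to [0, 1] for pause specs (≥ 0 otherwise).

## Pause detection

A `window_ms` = 100 ms test window advances in `step_ms` = 10 ms
increments over `scan_span_ms` = [0, 1000) ms after the alignment event.
Per-trial counts in each window are converted to rates and compared with
the control period using the Dunn rank z (tie-corrected mean-rank
difference; identical to the tie-corrected Mann–Whitney normal deviate) at
`alpha` = 0.01 per step, uncorrected; a Bonferroni flag across steps exists
for sensitivity analyses. A pause is the first run of at least `min_run` =
5 consecutive significant decreases; its onset is the first step's start
and its offset the last consecutive significant step's start + window
length (an offset definition the package fixes explicitly). Increases are
tracked symmetrically for rebound reporting. The control period is always
the 500 ms immediately before **cue** onset, also for movement- and
reward-aligned scans.

Two numerical choices matter:

* **Control segmentation.** Ranking 100 ms test counts directly against
  500 ms control counts is biased: the two count distributions live on
  different discrete supports even at equal rate (one spike in 100 ms maps
  to 10 spikes/s and out-ranks most control rates, while an empty window
  under-ranks nearly all of them). Measured on null 6 Hz shape-2 trains at
  60 trials, that z has mean −0.22 and SD 1.21, inflating spurious pause
  detections to ~10%. The scan therefore segments the control period into
  window-length (100 ms) sub-windows, five per trial, giving z mean ≈ 0 and
  SD 0.96 under the same null and an empirical false-positive rate of ~1%
  (≤ 5% required), while the 5-step run rule handles step-level
  multiplicity.
* **Exact small-sample p-values.** The normal approximation's two-sided p
  deviates from exact enumeration by ≥ 0.046 even at n = 8 + 8 and by up
  to 0.68 at n = 1 (0.089 at 2 + 2 even with continuity correction). Rank
  tests therefore use exact enumeration of the rank-sum null distribution
  when both groups are tie-free with ≤ 10 observations, and the
  tie-corrected normal z otherwise. Sliding-window scans always run at
  trial-count sample sizes and thus use the normal path.

Onset estimates carry the method's intrinsic smearing: a window overlapping
the pause edge becomes significant slightly before the true onset, giving a
typical early bias of about half a window (≈ −50 ms at 60 trials for a
deep pause) — well within the one-window tolerance used for recovery
checks.

## Quantification

Magnitude is 100 × (window rate − baseline rate)/baseline, computed per
unit and condition from the condition's own trials, with the baseline taken
from the same trials' pre-cue control period. Reward-aligned magnitudes use
rewarded trials only. Fixed windows ship as presets per monkey × event ×
interval (cue: 93–309 ms; 127–313 / 211–418 ms; reward: 139–369 /
194–391 ms) and can be re-derived from detected pauses by mean or central
coverage of onsets/offsets. Trial-level magnitudes (n = 1 windows against
the session baseline) feed the MOT and correct-run trend analyses; they are
noisy per trial and are always averaged across units before trend fitting.

Population curves are across-unit means ± SEM of trial-averaged rates in
non-overlapping 10 ms bins. Gaussian smoothing is parameterized directly by
σ in bins: the conventional MATLAB-style window "alpha" (inverse width) is
ambiguous without the window length, so the package exposes σ explicitly
and records it in the curve's metadata.

## Unit classification

TAN if baseline rate ≥ 3.5 spikes/s and spike width ≥ the monkey's width
cut; PAN if rate ≤ 2.5 spikes/s and width ≤ the cut; otherwise
unclassified. The width cuts are midpoints between the reported class means
(830 µs for the monkey C population, 938 µs for monkey D; spike widths are
standardized to microseconds throughout). On bivariate-normal populations
drawn from the reported class moments, the default rule assigns the wrong
class to < 10% (Monte-Carlo, n = 1000/class). Task responsiveness is
deliberately **not** a criterion, keeping classification independent of
pause detection even though in practice the pause phenotype supports the
identification.

## Group statistics

* χ² on 2×2 proportions is the uncorrected Pearson statistic (the
  published statistics are reproduced from their counts to ±0.02 only
  without continuity correction; a Yates flag exists for sensitivity).
* Within-neuron interval contrasts default to the **paired** signed-rank
  test (the data are intrinsically paired); between-region and
  between-animal contrasts are unpaired rank-sum. Both are exposed via an
  explicit `paired` flag.
* Magnitude-vs-MOT trends report the least-squares slope plus Spearman ρ;
  MOT binning uses half-open 500 ms bins tiling from zero, empty bins
  omitted.
* Correct runs are maximal streaks of ≥ 5 correct trials with intervals
  pooled to preserve chronology; within-run trends are fit on (position,
  across-unit mean magnitude) points pooled over runs.
* No multiple-testing correction is applied across the battery of group
  tests, matching standard practice for this analysis family; results echo
  their inputs (counts, n) for audit.

## Problem sizes

The test suite and the acceptance script use: 200 null units × 60 trials
for detector calibration; 50 units for pause recovery; 8 units × 300 trials
per factor for magnitude recovery; 10,000 trials per interval for scalar
timing; exhaustive enumeration to n = 8 + 8 for rank-test accuracy; and 20
seeds × 10 units × 150 trials for the correct-run trend recovery. These
sizes give Monte-Carlo standard errors comfortably below the tolerances
they are checked against.

## What the generator does not emulate

Synthetic sessions capture rate structure, not biophysics: no spike
waveforms, bursting, drift, or cross-unit correlation (recorded TANs can
synchronize); no learning across sessions; no licking or eye movements; the
skewed short-interval MOT distribution seen in one animal is off by
default. Passing tests therefore demonstrate that the analysis chain
recovers what the generative model puts in at realistic rates and trial
counts — not that it is robust to every pathology of real recordings.
Monkey-specific published values that depend on the original recordings
(responsive-unit percentages, Wilcoxon z values, population reward
modulations) are used only to calibrate preset parameters, not asserted as
outputs.
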