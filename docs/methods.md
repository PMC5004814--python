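# Methods

`vibroseq` re-implements, as a tested pipeline, the standard analysis chain
for trial-aligned extracellular recordings from barrel cortex (S1) during a
whisker vibrotactile sequence-discrimination task: stimulus kinematics, unit
quality control, temporal-modulation testing, impulse-evoked metrics,
integration-window regression, population decoding, and behavioral
summaries.  Because the pipeline is exercised on a synthetic-data generator
rather than the original recordings, this note states precisely what each
stage computes, which choices were genuinely open, and what passing tests do
and do not establish.

## Stimulus model

A pulse is an up–down "ramp-return" panel deflection parameterized by rise
time, fall time (ms) and peak amplitude (mm).  The ramp profile is a raised
cosine, `x(t) = A/2 (1 − cos(π t / T))`, chosen because the published panel
traces show smooth ramps with mid-ramp velocity maxima; the profile is not
otherwise constrained.  Under this model peak velocity is `π A / (2T)` and
total travel per pulse is exactly `2A`.  Amplitude and rise/fall time are
treated as authoritative; the nominal hardware peak velocities (e.g., 220
mm/s for the fast pulse vs. 202 mm/s derived) are carried as informational
metadata, because amplitude, time and velocity jointly over-determine any
single ramp shape.  Printed sequence-level mean speeds are likewise not
reproducible from the pulse parameters under any simple ramp model, so the
package asserts only orderings and equalities (fastest > mixed ≈ mixed >
slowest; the two mixed-order trains equal within 1%).

Sequences concatenate pulses with a 34-ms quiet gap (end of one pulse to
onset of the next).  The shipped YAML library contains the three-pulse set
(FFF/FMS/SMF/SSS), the four-pulse FSFS/SFFS set, and amplitude-rescaled
"different-intensity" FSFS/SFFS variants.

`mean_speed` averages `|v|` over a window; the default window is the
waveform's own support.  Averaged over a fixed 150-ms window the four
three-pulse trains have nearly equal mean speed (their total travel is
nearly equal); averaged over each train's own duration the behavioral-cue
ordering emerges.  Analyses that need a common window (e.g., the published
150-ms convention) pass it explicitly.

The integration-window regressor for rate bin `[t, t+5)` is the integral of
panel speed over the trailing window `[t−W, t)`, zero-padded before
sequence onset, for `W ∈ {5, 10, …, 180}` ms.  The raw integral (mm of
travel) is used rather than the window-mean; R² and the slope p-value are
invariant to affine rescaling of the regressor, so this cannot affect
window selection or classification — only the units of the slope (Hz per mm
of integrated travel).

Numerics: default sampling step 0.5 ms; velocities analytic; integrals by
trapezoid on the sample grid with linear interpolation at window edges.

## Synthetic sessions

The generator produces trial tables, spike trains and unit metadata in the
same schema the real-data reader would emit, plus ground-truth archetype
labels.  It encodes the statistical structure the analyses assume, not a
biophysical model.

**Behavior.**  P(right choice) is a lapse-adjusted logistic of the
stimulus's mean panel speed — the integrated cue the animals' choices
track.  Defaults: slope 0.2 logit/(mm/s), midpoint at the mean of the
stimulus-set speeds, lapse 0.05, no side bias.  These place FFF-vs-SSS
discriminability at d′ ≈ 0.9, inside the published 0.5–1.5 range, with the
two mixed-order trains at chance.  Withdrawal times are shifted gamma
(shape 2) truncated at the 150-ms task minimum with mean 190 ms.

**Spiking.**  Five archetypes define rate functions λ(t) on a 0.1-ms grid
over the trial epoch (−25 to +250 ms), clipped at zero, sampled by Poisson
thinning:

* **Fast** — baseline (default 8 Hz) plus a Gaussian transient (peak 10 ms
  after pulse onset, s.d. 3.5 ms) per pulse, scaled by the pulse's derived
  peak velocity (gain 0.30 Hz per mm/s) and per-pulse adaptation
  multipliers (1, 0.8, 0.7), the published paired-pulse ratios.
* **Medium** — baseline 14 Hz minus a broad suppression (10 Hz, peak 28 ms,
  s.d. 16 ms) per pulse.  The kernel width/latency were calibrated, before
  any acceptance run, so the archetype's intrinsic time scale (noiseless
  best integration window ≈ 35 ms) sits inside the 25–50 ms "Medium" band.
* **SlowPos** — baseline 10 Hz plus small sustained responses (8 Hz, s.d.
  10 ms) on pulses 2+ that are *not* velocity-scaled (slow units do not
  track kinematics), plus a choice ramp (12 Hz) on right-choice trials
  rising from the offset of pulse 2 to a plateau during pulse 3.
* **SlowNeg** — baseline 16 Hz with a 50 Hz/s linear decline from stimulus
  onset, not locked to pulses.
* **Unmodulated** — constant baseline.

Per-unit baselines are drawn log-normally (s.d. 0.4 in log) around the
archetype default, matching the positive skew of cortical rate
distributions; all response gains scale with the drawn baseline so
response-to-baseline ratio is homogeneous.  Unit metadata (depth within the
archetype's typical layers, RS/FS width, SNR, ISI-violation fraction) is
sampled so that default units pass QC.

The generator deliberately omits: spike waveforms, cross-unit noise
correlations, non-Poisson spiking statistics (refractoriness, bursting),
session-to-session drift, and any reafferent/movement signals.  Passing
tests therefore demonstrate that the analysis chain recovers the structure
it assumes from realistic spike counts — not that it would behave
identically on the original recordings.

## Unit QC

Single-unit eligibility: ISI-violation fraction (< 1.5 ms intervals)
strictly below 0.005 and trough-to-peak SNR strictly above 2.  FS units
have width strictly below 0.375 ms.  Laminar bins are half-open,
lower-closed ([200,650) µm → L2/3, [650,975) → L4, [975,1285) → L5A,
[1285,1575) → L5B, [1575,2200) → L6, else "out"); the published ranges
print touching boundaries, so the boundary depth is assigned to the deeper
layer, and depths above 200 µm are "out" because no units were reported
there.

## Temporal-modulation test

Firing in the 0–180 ms epoch, binned at 10 ms, is compared against spike
trains whose spike times are re-drawn uniformly within the epoch per trial
(preserving per-trial counts, destroying all timing).  The test statistic —
unstated in the original description — is the sum over bins of squared
deviations of the trial-averaged rate from the epoch-mean rate.  Because
re-drawn times are i.i.d. uniform, the pooled null bin counts are exactly
multinomial, which is how the null is sampled (mathematically identical to
per-spike re-draws, ~100× faster).  p-values use the add-one rule
`(1 + #{null ≥ obs}) / (1 + n_perm)`, making the test valid at any
permutation count; a unit is "temporally modulated" at p < 0.05.  Units
with zero epoch spikes get p = 1.

## Evoked responses, adaptation, choice firing

Per pulse: baseline = mean rate 0–10 ms before onset; peak modulation =
extremal deviation of the 10-ms-boxcar-smoothed 1-ms PSTH within 40 ms
after onset (latency = its time); mean evoked rate = 5–35 ms window minus
baseline; significance by paired t-test of per-trial window rates.
Adaptation = evoked rate to pulse N over pulse 1; units with non-positive
pulse-1 response are excluded (recorded missing).  Choice bias = per-unit
rate difference (right − left choice trials) 5–50 ms after the final pulse
onset, paired t-test across units, with the same statistic on the 25-ms
pre-sequence baseline as control.  Divergence time uses a sliding paired
t-test (10-ms window, 5-ms step — both unstated originally and
configurable) and requires 3 consecutive significant windows to guard
against isolated false positives.

## Integration-window regression

For each unit, trial-averaged 5-ms rates over 0–180 ms are stacked across
the four sequences (144 observations) and regressed (OLS) on the
integrated-speed regressor for each of the 36 windows.  Pooling the four
sequences into one regression — rather than fitting them separately — is
this package's documented choice; a single per-unit best window is the
natural output of the pooled fit.  No latency offset is inserted between
regressor and rate bin, so window length and response latency are
deliberately confounded exactly as in the original analysis.  Significance
uses the slope F-test at α = 0.05/36 ≈ 0.0014 (Bonferroni); the best window
is the significant window with maximal R², ties broken toward the smaller
window.  Classes: Fast 5–20 ms; Medium 25–50 ms; Slow 55–180 ms split by
slope sign into SlowPos/SlowNeg.  The source ranges print 55 ms in both the
Medium and Slow bands; 55 ms is assigned to Slow (the choice-analysis
cohort) and the boundaries are configurable.

On default synthetic sessions the classifier recovers the generating
archetype for ≥ 90% of non-unmodulated units (pinned regression baseline),
and unmodulated units acquire a class at roughly the family-wise error rate.

## Population decoding

Each unit is an independent classifier over its binned single-trial counts
(10-ms bins over 0–150 ms, a single 150-ms bin, or the last 100 ms before
nose-poke withdrawal).  The stimulus decoder is one-vs-all logistic (four
binary L2-penalized fits per unit, scikit-learn); the four probabilities
are renormalized to sum to one so every unit carries equal vote mass.  The
population prediction is the argmax of summed probabilities, ties broken
uniformly at random under the run seed.  Evaluation repeats (default 300;
the calibration benchmarks use 100) a stratified 70/30 trial split; each
held-out test event receives, from each unit, one train sampled without
replacement from that unit's held-out trials of the queried class.
Confusion matrices are row-normalized and averaged over repeats.

Regularization: the default is a fixed small L2 penalty (C = 1.0).
Selecting C by within-training k-fold cross-validation is implemented
(`cv_folds`, `Cs`) but off by default: at benchmark scale it multiplies
runtime roughly eightfold and leaves the chance-calibration results
unchanged.  The original description mentions k-fold cross-validation
without stating k, the grid, or its purpose.

The choice decoder fits one binary logistic per unit on trials of all
stimuli pooled and is evaluated separately per stimulus on choice-balanced
held-out sets, so 50% remains a meaningful chance level despite behavioral
side bias; a stimulus with a single choice class among held-out trials is
skipped.  Controls: rate normalization divides each count vector by its
Euclidean norm (zero vectors pass unchanged); time scrambling re-draws
spike times uniformly within the trial epoch, preserving counts.

A caveat worth knowing: on a single finite dataset of label-independent
units, the expected decoder accuracy deviates from the asymptotic chance
level by roughly ±1–2 percentage points (training and held-out trials of a
class are anti-correlated within a finite sample).  Averaged over
independent populations the accuracy converges to 25% (four-way) and 50%
(binary), which is what the calibration test asserts.

## Behavior

Relative right choice = per-stimulus right-choice fraction minus the
unweighted mean across stimuli (cancels side bias; sums to zero).  d′ uses
the equal-variance Gaussian form with rates clipped to
[1/(2n), 1 − 1/(2n)] before the normal quantile; whether the original
analysis clipped is unstated.  The mixed-order comparison uses the
two-sample proportions z-test at the Bonferroni threshold 0.05/8 = 0.00625
(eight comparisons, one per animal).  The fixed-panel comparison is the
simple difference measure: fraction right to the fastest train minus
fraction right to the slowest, per condition block.

## Problem sizes and runtime

The pytest suite runs the stochastic calibrations at reduced scale (eight
independent 12-unit populations × 12 decoder repeats; 300 permutation-test
units × 500 permutations; 150–200 regression-recovery replicates), chosen
so the full suite completes in about a minute while keeping Monte-Carlo
error small enough for 3-sigma assertions.  `scripts/acceptance.py` runs
the full benchmark sizes — 100 units × 100 repeats for each decoder, 1000
units × 2000 permutations for the modulation test — in about 3 minutes.

## Known limitations

* The archetype parameterizations are this package's constructions,
  calibrated only to qualitative published response shapes; absolute rates,
  laminar fractions and real-data decoding accuracies are out of scope.
* The permutation statistic, sliding-test window, d′ correction, OVA
  regularization scheme and stimulus pooling in the regression are all
  documented package choices where the original description is silent;
  each is configurable.
* Ingestion of the original deposited recordings is not implemented; the
  session schema (`trials.csv`, `units.csv`, `spikes.parquet`) is the
  surface such an adapter would target.
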