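# vibroseq

Spike-train analysis and population decoding for whisker vibrotactile
sequence discrimination experiments.

## What this is for

In rodent vibrotactile tasks, a moveable panel delivers rapid trains of
brief whisker deflections ("pulses") that differ in single-pulse kinematics
(5–20 ms time scale) and in time-integrated intensity (mean panel speed over
the ~150-ms train).  Animals typically guide their left/right choice by the
integrated cue, while primary somatosensory cortex (S1) may encode the
stimulus on much faster time scales.  Analyzing such experiments requires a
chain of standard computations over trial-aligned spike trains: stimulus
kinematics, unit quality control, tests for task-related firing, evoked and
adaptation metrics, a regression that identifies each unit's stimulus
integration window, population decoders for stimulus identity and
behavioral choice, and signal-detection summaries of behavior.

`vibroseq` implements this full chain as a tested, reproducible pipeline
for systems neuroscientists.  Because deposited recordings are not always
at hand, it ships a first-class synthetic-session generator whose units
follow the canonical response archetypes (Fast, Medium, Slow-Positive with
choice-correlated firing, Slow-Negative, Unmodulated), so every stage can
be validated against ground truth.

## The core computations

* **Temporal-modulation permutation test.**  Observed firing in 10-ms bins
  over the 0–180 ms stimulus epoch is compared against spike trains with
  times re-drawn uniformly within the epoch.  Statistic
  `T = Σ_b (r_b − r̄)²`; p-value `(1 + #{T_null ≥ T}) / (1 + n_perm)`.
* **Integration-window regression.**  For each unit, trial-averaged 5-ms
  firing rates (stacked over the four sequences, 144 observations) are
  regressed on panel speed integrated over a trailing window
  `W ∈ {5, 10, …, 180}` ms.  With Bonferroni threshold `α = 0.05/36 =
  0.0014`, the best window is the significant `W` with maximal R²; units
  are classed Fast (5–20 ms), Medium (25–50 ms) or Slow (55–180 ms,
  split by slope sign).
* **Population decoding.**  Each unit is an independent one-vs-all
  logistic classifier over its binned single-trial counts; per-unit class
  probabilities are renormalized to sum to 1 (equal vote mass) and the
  population prediction is `argmax_s Σ_units P(s | train)`.  Evaluation
  repeats stratified 70/30 splits; rate-normalized and time-scrambled
  controls separate rate from temporal coding.  A binary analogue decodes
  choice, scored per stimulus on choice-balanced held-out sets.
* **Behavior.**  Relative right choice (per-stimulus right fraction minus
  the mean across stimuli), equal-variance `d′ = z(hit) − z(fa)` with
  1/(2n) clipping, and two-sample proportion tests.

See `docs/methods.md` for models, assumptions, parameter defaults, and the
design choices made where the procedures are underdetermined.

## Worked example

```python
import numpy as np
from vibroseq.synthetic import SessionConfig, generate_session
from vibroseq.response import temporal_modulation_test
from vibroseq.windows import classify_session
from vibroseq.decoder import BinSpec, binned_counts, evaluate_stimulus_decoder
from vibroseq.behavior import summarize_behavior

cfg = SessionConfig(seed=42)                     # 30 units, 50 trials/stimulus
session = generate_session(cfg)

rng = np.random.default_rng(0)
pvals = {u: temporal_modulation_test(session.spikes_by_trial(u),
                                     n_perm=2000, seed=rng)
         for u in session.unit_ids()}
modulated = [u for u, p in pvals.items() if p < 0.05]

cls = classify_session(session, cfg.resolve_sequences(), unit_ids=modulated)
print(cls["unit_class"].value_counts().to_string())

X = binned_counts(session, BinSpec())            # 10-ms bins over 0-150 ms
report = evaluate_stimulus_decoder(X, session.trials["stimulus"].to_numpy(),
                                   n_repeats=50, seed=0)
print(f"stimulus decoder accuracy: {report.overall_accuracy:.1%}")
print(f"d' (FFF vs SSS): {summarize_behavior(session.trials).dprime:.2f}")
```

Output:

```
unit_class
Fast       10
SlowPos     4
Medium      3
SlowNeg     3
stimulus decoder accuracy: 53.6%
d' (FFF vs SSS): 1.11
```

20 of 30 units test as temporally modulated (the 10 flat-baseline units are
correctly excluded), and the window regression recovers the generating
archetype of every modulated unit.  The four-way stimulus decoder reaches
53.6% correct from single-trial spike trains (chance 25%) — driven by the
Fast units' temporally precise pulse responses — and the behavioral d′ of
1.11 for the fastest-vs-slowest discrimination falls in the realistic
0.5–1.5 range encoded by the generator's psychometric model.

The same stages are available from the shell:

```bash
vibroseq simulate --seed 42 --out session/
vibroseq modulation session/
vibroseq classify session/
vibroseq decode stimulus session/ --bins 10ms --repeats 300 --seed 0
vibroseq run-all --seed 42 --out run/
```

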