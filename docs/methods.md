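# Methods

This note documents the models, parameter choices and numerical conventions
behind `eegcam`, and what the synthetic-data experiments do and do not show.

## Synthetic driving sessions

`eegcam.synth` emulates the study conditions the pipeline assumes: 19
channels of the 10–20 montage at 500 Hz, 5-minute sessions, 4 laps × (4
left + 4 right) turns = 32 balanced events.  The montage is ordered in the
Mitsar/WinEEG convention (FP1, FP2, F3, F4, C3, C4, P3, P4, O1, O2, F7,
F8, T3, T4, T5, T6, FZ, CZ, PZ), because that ordering is what makes the
numeric feature names meaningful (channel 15 = T5, 9 = O1, …).

* **Turn schedule.**  The session is split into 32 equal slots; each slot
  holds one onset at a quarter of the slot, alternating left/right so every
  lap is balanced.  Only the lap layout is prescribed by the experimental
  design, not the timing, so even spacing plus seeded jitter (±10 % of a
  slot) is the generator's own choice.  Scheduling fails when slots fall
  under 1 s.
* **Background noise.**  Independent Gaussian samples per channel
  (default sd 10 µV, a typical broadband EEG amplitude inside 1–30 Hz),
  with an optional 1/f amplitude-shaping toggle.  This is the simplest
  model that exercises band-power estimation; it has no volume conduction,
  no channel correlation, no oscillatory peaks.
* **Group signatures.**  Three behavioral groups with delta-band effects:
  G1 elevates FP2 and O1 on right turns; G2 elevates F7 on right and P3 on
  left; G3 elevates FP2, P3 and T4 on left.  The default cohort has
  5/2/3 subjects in G1/G2/G3.  During a matching turn, a sinusoidal burst
  at the band's center frequency spans `[onset, onset + epoch_length]`
  (epoch_length default 5 s — a free parameter; the turning-maneuver
  duration is not prescribed).  The burst amplitude is
  `sqrt(2 (m − 1) P̄)`, where `m` is the signature's power multiplier
  (default 5) and `P̄` the channel's baseline band power measured once
  over the whole pre-burst session.  Anchoring on the session-wide
  baseline rather than each window's own noise power makes the planted
  effect a fixed-amplitude oscillation per event — the way an evoked
  response behaves — instead of one that tracks the local noise; the
  epoch-level band power is then `≈ m × P̄` with only the chi-square
  spread of the background, and the multiplier is recovered by the
  feature stage to within spectral noise.
* **Artifacts.**  Optional Poisson transients (120 µV, 0.5 s, 2 Hz) that
  amplitude screening removes; sessions are clean by default.  The
  external artifact-removal (ICA) step is a pass-through hook only.
* **Determinism.**  Every session is a pure function of
  (config, subject id, seed); subject streams are split off the seed with
  a CRC of the subject id, kept below 2³¹.

Passing tests on this generator demonstrate parameter recovery and
internal consistency of the pipeline, not performance on real EEG: real
turn-related dynamics are broadband, time-locked, correlated across
channels and contaminated by ocular/muscular sources in ways the generator
deliberately omits.

## Preprocessing

1–30 Hz Butterworth band-pass, order 2 per pass (12 dB/octave), applied
forward–backward per channel, so the effective roll-off is 24 dB/octave
and the phase response is zero (verified by a zero-lag cross-correlation
test).  Amplitude screening splits each epoch at 8 Hz (delta+theta vs
alpha+beta — the slow/fast boundary is a documented choice, not
prescribed) with 4th-order zero-phase low/high-pass filters and rejects
the epoch when any channel's slow peak exceeds 50 µV or fast peak exceeds
30 µV; the peak is the maximum absolute sample of the filtered component.
Screening is monotone: scaling an epoch up can never turn reject into
keep.

## Band power

Single rectangular-window periodogram of the whole (mean-removed) epoch,
one-sided, normalized so that the bin sum equals the signal's mean square
— Parseval's identity holds to machine precision and is used as a test
oracle (1e-6 relative on bin-aligned partitions; the independent
cross-check is scipy's spectrum-scaled periodogram).  A bin belongs to a
band when its center frequency lies in the closed interval [low, high];
with the band edges used here (3.5 vs 4 Hz etc.) no bin can fall in two
bands at typical epoch lengths, and the closed rule is deterministic.
Units are µV².  A Hann window is available but not default — plain FFT
power is the convention being reproduced.

## Feature selection and binarization

Welch (unequal-variance) two-sample *t* per feature between left and right
epochs; features ranked by |t| descending, stable ties by column order,
p-values reported descriptively (ranking, not testing — no
multiple-comparison correction).  Degenerate (zero-variance) features get
t = 0 and rank last.

Two selection rules:

* **two-stage** — channels scored by mean |t| over their bands, bands by
  mean |t| over channels (max-aggregation optional); the selection is the
  cross product, e.g. 7 × 2 = 14 features.  This mirrors the pooled
  analysis design.
* **scalar** — keep every feature with p ≤ α (default 1e-3), at least 2,
  i.e. "high |t| chosen, others rejected".  This is the default for the
  per-subject flow: individual synthetic subjects carry 2–3 informative
  features, and every uninformative feature admitted into the bipolar code
  contributes a coin-flip bit that dilutes the Hamming readout, so a lean
  adaptive selection is the design that matches the sparse ground truth.

Binarization centers each selected feature on its cross-epoch training
mean and takes the sign, with sign(0) → +1 as the single global tie rule.
Class prototypes are binarized class means; positions where the two
prototypes agree are pruned (they carry no class information), leaving the
"effective neurons".  In every evaluation flow the ranking, selection,
centering and pruning are fit on the training split only.

## Hopfield memory

Hebbian outer-product weights are exact integer sums; symmetry and zero
diagonal are enforced invariants.  Updates use sign(W x − T) with
sign(0) → +1 (the same global tie rule).  Two schedules:

* **asynchronous** (default for recall/classification): one neuron at a
  time in a seeded random order; every update is non-increasing in the
  energy, so recall always terminates at a stable state.  Outcomes for
  probes on basin boundaries legitimately depend on the update order —
  the order is part of the seeded randomness.
* **synchronous**: all neurons at once (the matrix form of the update
  rule); deterministic, but may enter 2-cycles, reported as
  non-converged at the iteration cap.  The distortion-recall benchmark
  uses this schedule, matching the matrix-form update it reproduces.

Recall iterates full sweeps until none changes a neuron, capped at 40
iterations.  Classification returns the label of the stored pattern
nearest the final state in Hamming distance; exact ties are indeterminate
and scored as misses.  Distortion flips exactly `rint(fraction · n)`
distinct positions (ties-to-even, so 15 % of 6 bits flips 1).

A known small-net pathology follows from the sign(0) → +1 rule: when a
probe's overlap with a stored pattern is exactly 1, every already-correct
neuron sees a zero local field (the self-term is excluded) and is forced
to +1 regardless of the pattern.  This is inherent to the specified
dynamics, is covered by tests, and is one reason heavily pruned 2–3-neuron
nets behave worse than a majority-vote intuition suggests.

## The six group patterns

The group-level benchmark stores one pattern per (group, direction) cell
over six selected features.  The original bit values are unavailable, so
`eegcam.patterns` ships a synthetic reconstruction built once from the
described group behaviors: +1 where a cell's feature power is elevated,
−1 otherwise, with the undescribed T5-delta column resolved by the global
tie rule.  Under 15 % distortion × 20 trials this net scores ≈ 78 %
bit-level performance (mean error ≈ 0.22); the sixth feature column is the
dominant unknown — across all 64 possible columns the same experiment
spans roughly 53–80 % — so the packaged fixture is a structural stand-in,
not a transcription.  Both bit-level and pattern-level metrics are always
reported because "performance" of an overloaded memory is ambiguous; at
six patterns in six neurons only the bit-level reading is informative.

## Evaluation protocols

* **Time-domain baseline**: per-class 19×1 electrode means over 50 s of
  turn-locked signal (25 000 samples at 500 Hz), binarized against their
  joint mean, pruned, stored as 2 prototypes; tested on 10 + 10 seeded 5 s
  sub-segment means.  How the original test samples were formed is not
  documented; seeded sub-segment means are this package's choice.
* **Band-wise / selected (pooled)**: prototypes and test patterns from the
  same epochs (in-sample, as in the design being reproduced), restricted
  to one band's 19 features or to the two-stage 14; reports effective
  neurons and accuracy.
* **Monte-Carlo CV**: stratified 70/30 splits (stratification avoids
  empty-class test sets at n = 20; splits that would still produce one are
  re-drawn and logged), 10 repeats, per-repeat accuracies retained.
* **Significance**: exact binomial test against chance 0.5 plus an
  optional label-permutation test — an assumption-light replacement for
  parametric ANOVA.
* **Benchmark ladder** (`study_progression`): on the fixed seed-0 default
  cohort, mean per-subject accuracy ≥ pooled feature-selected ≥ best
  single band ≥ time-domain baseline.  The pooled rungs are depressed by
  inter-subject variability (opposite-direction signatures across groups
  partially cancel), the per-subject rung is near-perfect — the
  qualitative progression the pipeline is meant to exhibit.  The ladder
  runs the full ten-subject cohort (≈ 15 s on one core).

## I/O

Sessions are stored as plain CSV (samples × channels, header = channel
labels, µV) with a JSON sidecar carrying fs, subject metadata, turn events
and run metadata (seed, config fingerprint, package version); networks as
JSON `{n, W row-major, T, stored}`.  CSV + JSON keeps artifacts
text-based, diffable and byte-stable for identical seeds.

## Known limitations

* The generator's noise is spatially white; no realistic forward model,
  eye-blink topographies or line noise, so the screening and (pass-through)
  ICA stages are only lightly exercised.
* The six-pattern fixture is a reconstruction (see above); quantities
  derived from it inherit that uncertainty.
* Pattern-level accuracy of the overloaded six-neuron memory is near zero
  by construction; only bit-level recall is meaningful there.
* Real-data accuracies cannot be reproduced (no recordings exist); all
  quantitative tests are against synthetic ground truth or closed-form
  oracles.
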