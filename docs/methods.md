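# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic-session generator does and does not
emulate.

## Stimulus geometry

A stimulus lives in degrees of visual angle, centre origin, y-up.  The
polygon sampler places 3 or 4 vertices at base angles 90° + k·360°/n,
jittered uniformly by ±20°, at radii uniform in 3° ± 0.5°, and rejects
candidates violating convexity or the interior-angle bounds
([30°, 120°] for triangles, [50°, 130°] for quadrilaterals), up to 1000
retries before declaring the configuration infeasible.  Each vertex carries
a Pac-Man inducer of radius 1°: a disc minus a wedge whose angle equals the
interior angle.  The configuration validator enforces that the inducer
radius stays below half the minimum inter-vertex distance implied by the
radius/jitter bounds, so inducers can never overlap.

Collinearity is encoded by the mouth bisector: when it equals the bisector
of the two polygon edges at the vertex, the mouth edges coincide with those
edges and the array induces the illusory polygon.  The no-SCI twin rotates
each inducer independently by a magnitude uniform in [40°, 140°] with
random sign — large enough that no mouth edge re-aligns with a polygon
edge.  Because rotation preserves disc-minus-wedge area, SCI and no-SCI
twins have exactly equal vector ink (and raster ink within 1 % with
antialiasing off), so class differences cannot be driven by low-level
features.

Primers are two 1°-long segments per vertex sharing the vertex endpoint.
Congruent primers trace the target's own mouth edges.  Incongruent primers
trace the mouth edges of the *opposite-class* twin built from the same
polygon: an incongruent primer actively reinforces the wrong class rather
than being merely different, which is the reading that makes incongruency a
genuine interference manipulation.

Rendering is deterministic: PNG via integer rasterisation (optional 4×
supersampled antialiasing), SVG as explicit path arcs.  Pixel counts of the
raster track the closed-form vector areas.

## Protocol

A test session is 550 trials in 5 blocks of 110 with 60 s breaks and a 2 s
lead-in before the first trial (the lead-in keeps the first epoch clear of
the recording edge and of filter start-up).  Conditions are i.i.d. uniform
over the 2 × 2 × 2 cells — 550 is not divisible by 8, so exact balance is
impossible and independent draws are the natural reading of a uniformly
random distribution.  Practice is 12 trials, three per primary 2 × 2 cell
with vertex counts alternating 3/4/3.  Trial timing: fixation 100 ms,
primer 150 ms, target held until response (simulation safety timeout 3 s),
ITI uniform on [400, 600] ms.  With a 750 ms mean response time the
expected trial duration is exactly 1500 ms.  The SCI response hand
alternates with participant parity.

## Synthetic behaviour

Response times are ex-Gaussian per primary condition.  The SD is split
σ = 0.8·SD, τ = 0.6·SD (so σ² + τ² = SD²) and µ is solved from the exact
exponnorm median, making the distribution median and SD equal the target
values (396/65, 453/101, 468/78, 489/85 ms) by construction.  Error
probabilities are 0.7, 0.7, 2.0 and 0.8 %.  Between-participant structure,
which the condition-level targets do not constrain, consists of

- a N(0, 5 ms) offset on all of a participant's RTs;
- a log-normal (sd 0.22) dispersion scale multiplying σ and τ with µ
  re-solved so the condition median is unchanged — participants differ in
  RT variability but not in median structure;
- an interference-prone subgroup (probability 0.35) whose incongruent
  error probability is multiplied by Uniform(2.5, 4.5) — most participants
  are uniformly accurate while several reach ~5 % errors on incongruent
  trials, and per-condition error medians stay at the target values since
  the subgroup stays below half the cohort;
- an optional lapse process (default off, so condition SDs equal the
  target RTVs exactly).

A deliberate consequence of the first two choices: the RT-variability rank
test shows participant overlap (effect sizes around 0.4–0.5) instead of
saturating at the Mann-Whitney ceiling of |z|max/√34 ≈ 0.85, while the
median-RT chain stays cleanly ordered.

## Synthetic EEG

The recording is a sum of four parts, sampled at 512 Hz on either the full
Biosemi-128 montage or a reduced montage of the 19 ROI channels plus one
filler (the reduced montage is the testing default; the four ROIs —
vertex A1+5, parietal A19+4, occipital A23+4, fronto-medial C19–C21 —
resolve in both).

**ERP components.**  Four Gaussian-envelope bumps (FWHM 40 ms for the N1s,
120 ms for P3a/P3b) at their nominal latencies (primer N1 at 0 ms re
target, target N1 at 165 ms, P3a at 280 ms, P3b at 480 ms), each with a
spatial topography of unit weight on its ROI channels and Gaussian falloff
with projected scalp distance (scale 0.35 rad).  Per-condition amplitudes
are not set to the published deltas directly: the generator *defines* the
injected effect as "what the analysis pipeline measures", and solves the
amplitude tables by fixed-point iteration so that the pipeline's
baseline-corrected, filtered, windowed contrasts equal the published
values to 1e-6 µV on noiseless templates.  This absorbs three small but
systematic mechanical biases: the primer-N1 bump leaks into the −100…0 ms
target-level baseline; the high-pass ringing redistributes slow P3 energy;
and the 20 Hz low-pass is applied to finite epochs whose reflected edges
touch the earliest baseline and the latest window.  The calibration
operator replicates the epoch-level processing exactly (long-template
high-pass, 384-sample cut, baseline, epoch-level low-pass).  A zero-mean
N(0, 0.3 µV) per-participant offset on each component × condition
amplitude adds between-participant spread; it is kept small so that the
cohort-mean recovery stays within ±0.3 µV, which means synthetic
standardized effect sizes (d ≈ 4–20) are deliberately larger than real
data would give — the cohort tests calibrate recovery, not realism of d.

**Background noise.**  1/f (power exponent 1.0) Gaussian noise, 4 µV RMS
per channel, built from a common field (30 % of variance) plus independent
per-channel noise.  The level represents artifact-cleaned residual EEG.

**Theta dynamics.**  Induced theta is 4–8 Hz band-limited random-phase
noise whose amplitude ramps linearly from 1.5 to 4.0 µV RMS across the
session; the evoked part is a fixed-phase 6 Hz, 300 ms Hann-windowed burst
at target onset whose amplitude decays from 2.5 to 0.4 µV across trials.
Both project through the fronto-medial topography.  Late trials therefore
show more theta power with less stimulus phase-locking.  Under the pooled
early+late ERSP baseline, the session-long power drift dominates the
early/late ERSP panels in this regime (late sits above the pooled
baseline); the early/late ERSP *difference* — the quantity actually
tested — is baseline-free and unbiased.

**What the generator does not emulate.**  No ocular/muscle/line artifacts
(the artifact-rejection hook is exercised only as an amplitude threshold),
no volume-conduction head model (topographies are radial-basis weights),
no habituation of ERP amplitudes across trials, no autonomic channels.
Passing tests therefore demonstrate that the analysis chain measures what
it claims to measure under realistic noise and timing — not that it is
robust to every artifact class of a physical recording.

## Analysis choices

- **RT summaries**: error trials removed first; median of hit RTs per
  condition; RTV is the SD of hit RTs (per target class RTV pools hits
  across congruency; the congruency error rate pools across class).
- **Rank tests**: Mann-Whitney U as documented, with average ranks for
  ties, tie-corrected normal z without continuity correction (so the
  reported z is the one that enters ES = |z|/√N, N = n₁+n₂), and an exact
  enumeration branch for samples of ≤ 8.  A paired Wilcoxon alternative
  sits behind a flag because the compared samples are participant-paired
  even though the documented test is unpaired.  All-tied input returns the
  symmetric p = 0.5, flagged degenerate.
- **Holm-Bonferroni**: step-down with monotonicity, capped at 1; applied
  per family (behavioural battery; ERP battery).
- **Filters**: the high-pass follows a least-squares linear-phase design
  of order 1.5 × SR with band edges 0.85/SR and 1/SR (≈ 0.5 Hz at 512 Hz);
  both filters are applied forward-backward (zero phase, squared
  magnitude).  Application mode is the package's choice; the design is
  fixed.
- **Epochs**: −250…+500 ms, 384 samples at 512 Hz, nearest-sample event
  alignment, hit trials only for ERPs (everything for spectra).  Epochs
  that would cross a recording edge are dropped.
- **Dual baselines**: whole-trial questions (P3a/P3b congruency, primer
  N1) use −250…−150 ms, the 100 ms before the trial; target-locked gestalt
  questions use −100…0 ms, the late primer period, to cancel
  primer-induced offsets trial by trial.  Windows are closed intervals,
  centre ± half-width.
- **Paired t / Cohen's d**: df = n−1; d = t·√(2/n), the convention that
  reproduces the published ES values from the published t statistics
  (6.68 → 2.29, −3.06 → −1.05 at n = 17).  The published df column is
  internally inconsistent across rows; df is reported honestly as n−1.
- **Time-frequency**: one 3-cycle complex Morlet decomposition (4–30 Hz in
  1 Hz steps — 750 ms epochs cannot support lower frequencies) feeds both
  ERSP and ITC.  Wavelet support is truncated to the epoch with a
  zero-mean correction, and coefficients are rescaled by the captured
  kernel-energy fraction so stationary noise reads flat across the epoch;
  for strongly autocorrelated signals an edge baseline can still be
  attenuated, which is another reason conclusions rest on early/late
  contrasts rather than absolute dB.  ERSP is the dB of the epoch-mean
  power over the pooled early+late −250…−150 ms baseline (log of the mean,
  not mean of the per-epoch log, avoiding the chi-square bias of averaging
  logs).  ITC is the resultant length of unit phasors; zero-magnitude
  coefficients are excluded per bin.
- **Permutation tests**: two-tailed label shuffles of the early/late
  assignment, 500 permutations by default, p = (exceedances+1)/(n+1);
  α = 0.05 for ERSP and 0.01 for PSD/ITC, mirroring the reported
  thresholds; ITC permutations recompute the coherence on shuffled groups
  since ITC is not an epoch mean.  The stability utility reruns an
  analysis under ten spawned seeds and reports the per-bin significant
  fraction.
- **Effect-size pooling**: only records with adjusted p ≤ 0.05 enter; a
  cell never mixes the z-based and d-based estimators; medians are
  reported to two decimals, half away from zero; nominal labels use the
  extended thresholds (0.01 very small, 0.2 small, 0.5 medium, 0.8 large,
  1.2 very large, 2.0 huge) with closed lower bounds.  The three RT-chain
  tests mix the congruency and gestalt questions and are tagged with
  neither, so they never enter pooling.  The verdict holds when the
  congruency median exceeds the gestalt median in every computable family;
  a family with an empty cell yields a partial verdict flagged incomplete.

## Problem sizes and determinism

The default study is 17 participants × 550 trials on the reduced montage
with 500 permutations; the full-cohort analysis runs in roughly two
minutes on one core, and the test suite samples the same conditions.  The
spectral battery in the cohort driver runs on one representative session
(55 early vs 55 late epochs), the unit the permutation procedure operates
on.  Every stage draws from seeds spawned from a single root seed
(SeedSequence), so schedules, stimuli, behaviour, recordings and
permutation masks are bit-reproducible, and two `run-all` invocations with
the same seed write identical tables.

## Known limitations

- The rank-test effect size is capped at |z|max/√N (≈ 0.85 for 17 vs 17),
  so published ES values above that ceiling cannot be reproduced by the
  documented formula; the package implements the formula as stated.
- The EEG container is a documented float binary + JSON sidecar rather
  than EDF (float32 by default, float64 for bit-exact round-trips).
- ERSP/ITC absolute values near epoch edges inherit truncated-wavelet
  attenuation (see above); masks and conclusions use within-decomposition
  contrasts.
- The ERP-image visualisation, scalp maps, channel interpolation and
  ICA-based artifact pipelines are out of scope; artifact rejection is a
  simple amplitude threshold hook.
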