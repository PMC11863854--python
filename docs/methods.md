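# Methods

This note documents the models, conventions and defaults behind `armswing`,
the choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real recordings.

## Signal model of the synthetic generator

A recording is a timeline of non-overlapping activity bouts. During a gait
bout, the arm-swing angle is

θ(t) = A·sin(2πft + φ) + h·A·sin(4πft + 2φ),

with amplitude A (deg), cadence-linked swing frequency f (Hz, constrained to
(0, 0.9] so angle extrema stay at least 1/1.8 s apart), harmonic fraction h,
and a random phase φ. The gyroscope y/z axes carry ω = dθ/dt along a fixed
unit direction (0.866, 0.5) in the y–z plane, mimicking a wrist-worn sensor
whose swing-sensitive axes are y and z. The accelerometer carries a
per-bout gravity pose (a small set of canonical wrist orientations;
a fixed near-vertical pose during gait, so gravity mean/SD features are
informative), plus band-limited "step" noise centred at 2f — heel strikes
arrive at roughly twice the arm-swing frequency — with sd 0.12 g.

Other arm activities occupy a sub-interval of a gait bout and multiply the
swing amplitude by 0.2 while adding broadband gyroscope noise (sd 25 deg/s)
and extra accelerometer noise (0.02 g): holding or manipulating an object
suppresses the rhythmic swing and adds irregular motion. These perturbation
constants are stipulated, not derived from data; no quantitative signal
model of real arm activities was available.

Non-gait bouts get activity-specific dynamic noise (sitting/standing nearly
static; turning/stairs/cycling band-limited low-frequency energy, turning
and cycling also rotating the wrist). Rest tremor, when enabled, adds
band-limited 3.5–8 Hz acceleration during non-gait bouts;
`tremor_band_power` is implemented as the sd (g) of that component — an
amplitude keeps the generator linear, and the spectral-placement tests
verify by direct DFT that ≥80% of the dynamic power lands in the tremor
band. White measurement noise defaults: 0.02 g (accelerometer), 2 deg/s
(gyroscope). All randomness flows from one integer seed; identical
configurations are byte-identical.

Cohort-level defaults encode the study conditions being emulated: visits of
a few hundred seconds alternating non-gait bouts (15–45 s; sitting and
standing dominating) with gait bouts whose durations follow the four
duration categories (half of gait time in bouts ≥20 s), roughly a quarter
to a third of annotated time being gait; about half of gait bouts carry one
other-arm-activity sub-interval covering 30–90% of the bout; subject-level
swing amplitudes ~35 deg for controls, ~18 deg for PD pre-medication, +10
deg post-medication, with f drawn from 0.4–0.85 Hz. Desk-scale visit
durations (240–300 s in the test suite) keep the full suite in tens of
seconds while leaving every stage statistically exercised.

### Harmonic fraction and the peak-spacing rule

The default h is 0.05. The centered 1-s moving-average detrend attenuates
the angle fundamental by (1 − sinc f) — only ~0.36 at f = 0.5 Hz — while
passing the first harmonic essentially unattenuated (factor ~1.07 at 1 Hz).
A large angle harmonic therefore *dominates* the detrended angle at low
cadence, producing extrema spaced ≈ 1/(2·2f) < 1/1.8 s; the greedy spacing
rule then discards alternating extrema, can leave successive same-sign
peaks, and collapses the median RoM toward zero. Real arm-swing angle
trajectories are near-sinusoidal, so a small h is the realistic choice; the
interaction is a genuine property of the peak rules worth knowing when
applying them to data with strong harmonic content.

## Preprocessing conventions

- Orientation harmonization: orientation "A" is canonical; "B" flips the
  sign of x and y on both sensors (a 180° rotation about z). The map is an
  involution, so toggling the orientation field and re-applying restores
  the original signal.
- Decimation: integer ratios only; an 8th-order Butterworth low-pass at
  0.4× the target rate is applied forward–backward before sample dropping.
- Gravity split: 4th-order Butterworth high-pass, 0.2 Hz cutoff, applied
  zero-phase (`sosfiltfilt`) so gravity and dynamic components used jointly
  in one feature window stay phase-aligned; gravity = input − dynamic, so
  reconstruction is exact by construction. The reflect-pad length is
  3/cutoff seconds (15 s at 0.2 Hz): at so low a cutoff the library default
  padding leaves multi-second edge transients. Signals shorter than that
  are rejected, and the first/last 5 s of a recording are excluded from
  feature windows.
- Unannotated samples are removed *after* filtering the continuous
  recording, and the retained data are kept as contiguous blocks so windows
  never span a removed region.

## Feature conventions

Spectral estimates are single-segment Hann-tapered one-sided periodograms
normalized so the bin sum approximates signal power; band bins are
half-open [lo, hi) so the 0.7/3.5/8 Hz boundaries are never counted twice;
logs are floored at ε = 1e-10 (signal units²) so silent windows are finite.
The dominant frequency breaks ties toward the lower frequency. MFCCs use 15
triangular filterbanks spaced on the mel scale over 0–25 Hz, an orthonormal
DCT-II, no liftering, and return coefficients 1–12 (the 0th, pure-energy
coefficient is excluded — "12 MFCCs" means 12 shape coefficients; a silent
window yields exactly zero for all of them). Band powers and dominant
frequencies are computed on the dynamic component, consistent with the
gravity component feeding its own mean/SD features. The 3-s arm-filter task
reuses the same definitions at the shorter window. Feature name order is
fixed in a registry serialized with every model.

## Classifier training

Nested leave-one-subject-out cross-validation: the outer loop holds one
subject out; the inner loop grid-searches hyperparameters (logistic
regression: C over {0.05, 0.5, 5}; random forest: 50 trees, depth {3, ∞})
by balanced accuracy with leave-one-subject-out over the training subjects.
Standardization for the logistic regression lives inside the sklearn
pipeline, so fold statistics never leak. The logistic regression is
LASSO-regularized (l1_ratio = 1, liblinear).

Thresholds operate as "positive iff p ≥ t" and are searched over the sorted
unique training scores. Gait detection returns the smallest threshold with
training specificity ≥ 0.95 (maximal sensitivity subject to the
constraint); the arm filter returns the balanced-accuracy-maximizing
threshold, ties toward the lower threshold. Calibration can be restricted
to a subset mask (e.g. PD subjects only, matching a design where controls
lack arm-activity labels). Model selection takes the higher out-of-fold
balanced accuracy, with exact ties resolved to the logistic regression for
its simplicity.

Ties in all majority votes (window labels, timestamp votes) resolve to the
negative class for gait (limit false positives) and to *with other arm
activity* for the arm filter (prefer excluding possibly contaminated
windows). Per-sample predictions are uniform majority votes over the
thresholded decisions of covering windows; samples covered by no window are
negative.

## RoM numerics

- PCA is fitted once per participant-side on the pooled (y, z) gyroscope
  samples of all filtered segments, then applied per segment; the component
  sign makes the larger-magnitude loading positive so angles are comparable
  across runs.
- Integration is cumulative trapezoidal with θ(0) = 0.
- Detrending subtracts a symmetric trapezoid-weighted centered mean spanning
  exactly 1 s (half-weight endpoints, shrinking at edges): an even sample
  window cannot be centered, an odd one does not span exactly one second;
  the trapezoid kernel cancels linear drift exactly and passes a 1-Hz
  component exactly in the interior.
- Candidate extrema are sign changes of the first difference with plateaus
  resolved to their midpoint. Rule 1 (same-type successions collapse to the
  largest |θ|) is applied before rule 2 (a peak closer than 1/1.8 s to the
  previously kept peak is discarded), in that order and once; with a
  sign-change detector, same-type successions only arise from degenerate
  candidate lists, so rule 1 is primarily a robustness guard (and is
  exercised directly in the tests through `apply_peak_rules`).
- Percentiles use linear interpolation between order statistics; sides with
  under one minute of filtered gait are flagged excluded rather than given
  aggregates. Segments shorter than 1 s contribute no RoM (too short to
  detrend meaningfully).

## Evaluation statistics

The ICC is the two-way random-effects, absolute-agreement, single-measure
form (ICC2), delegated to `pingouin` and cross-checked in the tests against
an ANOVA mean-squares implementation; the form is recorded in the result.
The Bland–Altman bias line is the *median* difference — robust to the few
large discrepancies that classifier errors produce — rather than the
classical mean. Paired effects are the median of within-subject differences
with the Wilcoxon signed-rank test; unpaired effects are the Hodges–Lehmann
median of pairwise differences with the rank-sums test; CIs are percentile
bootstrap (2000 resamples, seeded). Prevalence-adjusted sensitivity is the
weighted mean of per-stratum sensitivities with group-level prevalence
weights (validated to sum to 1); AUC is available descriptively.

## What the synthetic tests do and do not show

Passing tests establish that every documented rule is implemented exactly
(oracle equivalence against brute-force DFT/counting/sorting
implementations), that the RoM chain is analytically correct (2A(1 − sinc f)
recovery within a fraction of a percent), that threshold calibration
delivers its specificity guarantee, that cross-validation has no
subject-level leakage, and that the filter does not preferentially remove
small-amplitude swing *in the generator's world*. They do not establish
classifier performance on real wrist data: the generator's class structure
(band-limited step energy, clean damping signatures) is far more separable
than free-living movement, it contains no dyskinesia, no sensor drift or
dropout, no soft-tissue artifacts, and its arm-activity perturbation is one
stipulated mechanism among the many real ones. Reported balanced accuracies
on synthetic cohorts are sanity floors, not performance claims.

## Known limitations

- Swing frequencies above 0.9 Hz are rejected at the generator level
  because the spacing rule would systematically discard extrema; the RoM
  stage itself does not guard against such cadences in external data.
- Strong angle-harmonic content interacts pathologically with the 1-s
  detrend plus spacing rule (see above).
- The arm filter is binary (with/without other arm activities); multi-class
  arm-activity recognition and dyskinesia handling are out of scope.
- Fractional-ratio resampling, sensor-fusion orientation estimation and
  timestamp-jitter repair are out of scope.
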