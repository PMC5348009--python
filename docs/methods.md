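# Methods

This note records the models, conventions and numerical choices behind
`oknbr`, in the order the pipeline runs.

## Signals and conventions

Horizontal position and direction are signed with **left = −1, right = +1**
everywhere: stimulus direction, raw key state, smoothed button press,
slow-phase velocity.  Positions are degrees of visual angle, 0 at the
stimulus centre.  Gaze is nominally 300 Hz, buttons 60 Hz; traces must be
uniform to 1% or loading fails.  Binocular trackers are reduced to one
horizontal trace before the pipeline sees them (the mean of valid eyes, one
eye if only one is valid, invalid otherwise); the analysis core is
device-free and the `pixels_to_degrees` helper handles screen-coordinate
imports.

## Button-press measures

`RawBP(t)` is smoothed with a centred 100-ms boxcar, truncated and
renormalised at the edges so constants survive trial boundaries.  With an
even window length (6 samples at 60 Hz) the extra sample sits on the
earlier-time side, i.e. `BP[i]` averages `RawBP[i-3 .. i+2]`.  One useful
consequence, asserted in the tests: for a clean press from silence the
window at the press sample contains exactly half pressed samples, so the
inclusive consistency threshold (`BP·dir ≥ 0.5`, exactly as specified) is
met **at** the press sample and the first-consistent-press time equals the
first-press time.  When the press is preceded by an opposite-direction
press, BP must climb through the old press's contribution and the
first-consistent time lags by ~100 ms — which is exactly what the canonical
worked example (`exemplar_button_trial`) shows: first press 0.5 s, first
consistent press 0.6 s.

A trial with `pBP = 0` has no dominant direction; it is left unlabelled and
excluded from rivalrous analyses.  Event times are the timestamp of the
first sample satisfying the predicate — no sub-sample interpolation, since
60 Hz matches the reporting precision of these latencies.

## Slow-phase OKN extraction

Detection computes central-difference velocity and acceleration on a
3-sample running median of position (edge-replicated; a zero-padded median
would fabricate steps at the trace ends).  Missing samples are linearly
bridged *for the derivative estimate only*, so blink edges are not doubly
flagged as saccades.  A sample is artifactual when it is invalid/missing,
or when |v| > v_thresh **or** |a| > a_thresh — the OR reading is the
conservative one for artifact removal.  Defaults are the conventional
printed constants (6 deg/s, 1 deg/s²).  Two caveats, both configurable:

* an acceleration bound of 1 deg/s² is far below real saccadic
  accelerations (10³–10⁴ deg/s²) and, applied to any noisy derivative,
  flags everything; analyses of generated sessions therefore disable the
  acceleration criterion (`a_thresh = inf`);
* whenever the slow phase itself is faster than 6 deg/s (gain > 0.27 at a
  22.3 deg/s stimulus), the velocity criterion must sit *between* the
  slow-phase ceiling and the quick-phase speed.  Quick phases are
  near-instant (≥ ~1200 deg/s for a multi-degree jump at 300 Hz), so the
  separation is wide; `synthetic_data.recommended_v_thresh` picks a value
  ≥ 8 noise standard deviations above the noise-velocity floor and well
  below the quick-phase speed.

Each removed interval is padded by 10 ms on both sides; padded intervals
that overlap are merged first so the shift accumulation is well defined.
The padded span is held at the position just before it and every later
sample is shifted to make the trace continuous ("integrated OKN").
Velocity is then boxcar(100 ms) → neighbouring-sample difference × rate
(midpoint-aligned, edge-replicated back to full length) → boxcar(100 ms).
Per-trial traces are cut from the block-level velocity so the kernels never
see window edges.  First-of-block trials carry no pre-onset recording and
are skipped.

**Known bias.** Holding the bridged span flat means the integrated trace
gains no displacement during it, so the measured mean slow-phase speed is
low by roughly the bridged-time fraction: (run + 20 ms) per artifact.  At
the generator's default quick-phase rate (~1.5 Hz) this is ~4–5%; tests
and the generator's recovery invariants account for it (5% tolerance
noiseless, 15% at default noise).  This is a property of the bridging
procedure itself, not of the implementation.

## Quality control

"More than half" is strict (rejecting exactly half keeps the subject) and
is applied separately within the rivalrous and non-rivalrous subsets, per
criterion family (button, eye).  The imbalance rule (≥ 3 kept rivalrous
trials per labelled side) runs after the other rejections.  First-of-block
trials are excluded from the eye-rejection denominator: their eye data is
structurally unrecorded rather than artifactual.  In two-session on/off
designs a subject rejected in either session leaves the paired analysis.

## Discriminability

With one feature, a linear maximum-margin classifier is an oriented
threshold; `ThresholdClassifier` fits it exactly by scanning every
candidate cut (midpoints of consecutive distinct values plus the outer
half-planes) for both orientations and keeping, among the
accuracy-maximisers, the cut with the widest margin — ties resolve to the
lowest threshold with orientation +1, so fits are deterministic.  A test
cross-checks the separable case against a hard-margin `sklearn` SVM and an
exhaustive best-threshold oracle over all 2⁸ labelings of 8 points.

Balancing subsamples the majority class down to N = min(N_R, N_L); the
70/30 split is stratified per class (train = ⌊0.7·N⌋ per class) so test
sets stay balanced and accuracy is comparable to the 0.5 chance line.
Stratification is a design choice here.  Both the subsample and the split
draw a single permutation of all trials and select per class from it, which
makes the whole computation exactly invariant under a global label swap.
One `numpy.random.Generator` drives every repetition and time point in
order, so a curve is bit-reproducible from one seed.  Columns with fewer
than 2 trials per class are NaN.

Latency of a curve is the earliest time it reaches halfway between a
baseline and its maximum over [0, 2] s (pre-onset values sit at baseline by
construction).  Baselines: 0 for speed and consistency curves, 0.5 (chance)
for discriminability curves — the absolute-half-of-maximum reading is
available by passing `baseline=0`.  Mean-consistency curves additionally
get the fixed 0.5-crossing time, which tracks the first-consistent-press
latency through the smoothing identity above.

## Trial images

Per subject: trials sorted by mean consistency over the 2-s trial (stable
descending), the trial dimension linearly interpolated onto 1000 rows
("upsampled to 1000 points"; endpoints at the first/last sorted trial),
then a 31-point boxcar along rows only — never across time — and finally an
element-wise mean across subjects.  Velocity rows of leftward-labelled
trials are sign-flipped first so "moving with the percept" is positive in
every row.  Linear interpolation is the simplest stretch consistent with
uniform-height panels; nearest-neighbour is the obvious alternative and
was not chosen because it quantises the row positions.

## Group statistics

Classic pooled-variance two-tailed t tests by default (Welch available via
`equal_var=False`), paired for within-subject designs; zero-variance paired
differences yield NaN and are flagged non-significant rather than extreme.
The Benjamini–Hochberg family is all time points of one comparison (one
panel), not pooled across panels.  Omnibus ANOVAs over latency summaries
are deliberately out of scope; `latency_table` exports a tidy per-subject
table for external tools.

## Synthetic sessions

The generator emulates the study protocol: 7 blocks of 20 trials (2-s
stimulus + 1-s blank; exactly 5 left / 5 right / 10 rivalrous per block in
random order), 22.3 deg/s gratings, 300/60 Hz sampling, with a 1-s pre-roll
before each block's first onset.  Per trial a latent percept path (the
stimulus direction, or an initial fair-coin dominance with Poisson-hazard
switches) drives:

* gaze — slow-phase velocity `okn_gain × 22.3 × percept`, delayed by the
  oculomotor latency at both stimulus onset and offset (OKN persists
  briefly after the grating disappears), integrated to position with
  one-sample quick-phase resets at ±3 deg eccentricity (6-deg amplitude,
  ~1.5 Hz at control gain — a realistic fixation-free quick-phase rate),
  plus Gaussian position noise (0.05 deg SD) and Poisson blinks
  (0.1 Hz, ~180 ms);
* buttons — a press in the percept direction at onset + Gaussian reaction
  time (0.482 ± 0.08 s control preset), following percept switches with
  fresh reaction times, with configurable rates of brief initial
  wrong-key presses (5%), lapses (2%) and ITI release failures (2%).

Preset groups order the parameters as the study reports them: patients
press later (536 ms on-treatment vs 482 ms) and have a lower OKN gain
(~1.5 deg/s slower slow phases).  All randomness flows from one seed
through a `SeedSequence` that spawns one stream per block, consumed in a
fixed order — sessions are byte-identical given a seed.

**What the generator does not model** — and hence what passing tests do not
establish about real recordings: pursuit-like asymmetries and gain
adaptation, fused/mixed percepts beyond a lapse rate, onset-dominance bias
structure (the bias is a scalar knob, default 0.5), tracker-specific noise
spectra and drift, head movement, and any clinical covariate structure.
Recovery tests show the *pipeline* is unbiased under its own assumptions,
not that those assumptions hold in a given lab.

## Problem sizes and determinism

Tests run the generator at 1–4 blocks per session and evaluate
discriminability on thinned time grids (`time_stride_*`), which leaves the
statistics unchanged at these trial counts while keeping the suite fast;
the full 300-Hz grid is the default for real analyses.  The acceptance
script uses 200-trial feature sets over 20 independent streams.  Every
stochastic step takes an explicit seed or `Generator`; nothing reads global
RNG state.
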