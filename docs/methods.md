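# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `cahow`, in the spirit of the model documentation that
accompanies simulation and statistics packages.

## Signal metrics

The static component of each acceleration axis is a **centred** moving mean
over a 1-s window (25 samples at the nominal rate); edge samples use
truncated windows rather than being dropped, so the metric table has one
row per raw sample and `static + dynamic == raw` holds exactly (to floating
round-off) everywhere. The window length is configurable: conventions in
the dynamic-body-acceleration literature vary between 1 s and 2 s
smoothing, and the choice changes VeDBA slightly at low flapping
frequencies.

Pitch and roll use the convention

    pitch = atan2(s_surge, sqrt(s_sway² + s_heave²))
    roll  = atan2(s_sway, s_heave)

with angles in degrees in (−180, 180]. A bird resting level reads
(0°, 0°); a vertical surge axis reads pitch 90°. An all-zero static vector
(free fall) yields NaN rather than an exception.

**Wingbeats.** Candidate peaks are local maxima of raw heave whose
amplitude exceeds 1 g; successive candidates no more than 0.25 s apart
(flapping at ≥ 4 Hz) chain into bouts, and only bouts of ≥ 2 peaks are
kept. Amplitude is measured by default as peak **prominence** rather than
the raw heave value at the maximum: gravity puts stationary heave at 1 g,
so a raw-value criterion would chain noise maxima riding on any supra-1 g
excursion — notably the slow load-factor oscillations of dynamic soaring —
into spurious beats, contradicting the defining absence of wingbeats in
that flight style. The raw-value reading remains available via
`criterion="height"`. Detection operates on raw heave (not dynamic heave),
configurable.

## Dive analysis

Order of operations: spike repair first, then zero-offset correction, then
detection — the order in which a TDR analyst would clean the record.
Samples deeper than 15 m (implying vertical speeds far beyond a
surface-feeder) are replaced by linear interpolation; a magnitude
threshold is used rather than a vertical-speed criterion, which would be
the natural alternative if non-isolated anomalies occurred. The ZOC is the
rolling 10th percentile of depth over a centred 10-min window (linear
interpolation between order statistics, truncated at the edges); corrected
depths below 0 are clipped to 0, making the correction invariant to any
constant offset of the raw record. A dive is a maximal run of samples at
or above 0.5 m; a single-sample event counts as 1 s.

## Behaviour classification

Each contiguous metric block is cut into non-overlapping 15-s segments
(trailing partial windows dropped; windows never straddle gaps). The
36-feature map is 4 statistics (mean, IQR, q10, q90 — quantiles with
linear interpolation) × 8 channels (dynamic surge/sway/heave, raw heave,
pitch, roll, VeDBA, VeSBA) plus mean surge, mean sway, mean temperature
and the wingbeat count. This guarantees by construction that the features
reported as most informative in ethogram work (mean VeDBA, q90 VeDBA, mean
dynamic sway, mean dynamic heave, IQR heave) exist under those names.

Training follows the caret/ranger recipe: a stratified 50/50
train/validation split; within each cross-validation training fold,
classes are up-sampled with replacement to even sizes (up-sampling inside
the folds is the leakage-safe reading; validation folds are never
resampled); a random grid of 18 combinations over minimum node size
(1–10), variables per split (2–p) and split rule (gini vs
extremely-randomised trees, mapped to `RandomForestClassifier` vs
`ExtraTreesClassifier`); combinations are scored by repeated stratified
k-fold (5 × 10 by default) mean Cohen's kappa. Recursive feature
elimination ranks features by impurity importance of the tuned model and
evaluates nested subsets of sizes {4, 8, 12, 14, 18, 24, 30, 36}, keeping
the smallest subset whose CV kappa is within 1% of the best. Prediction is
by feature name, so column order is irrelevant.

Evaluation reports the confusion matrix, overall accuracy with an exact
binomial (Clopper–Pearson) interval, Cohen's kappa
(p_o − p_e)/(1 − p_e), and per-class precision, recall and balanced
accuracy ((sensitivity + specificity)/2, one-vs-rest). Kappa and balanced
accuracy are implemented directly from their definitions and
cross-checked in the tests against scikit-learn and brute-force
confusion-matrix formulas. Variable importance is permutation-based,
scaled so the top feature reads 100%.

Desk-scale runs (tests, acceptance script) use reduced search settings —
3-fold single-repeat CV, a 6-combination grid, RFE sizes {8, 14, 36}, 100
trees — because the synthetic classes are strongly separated and the full
5 × 10 × 18 search adds nothing but runtime; the defaults of
`ClassifierConfig` remain the full recipe.

## Solar position

`cahow.solar` implements the standard NOAA low-precision ephemeris
(Meeus-style series for solar longitude, obliquity, declination and the
equation of time), returning geometric elevation without atmospheric
refraction — the diel model needs a smooth day/night covariate, not
horizon-accurate rise times. Tests compare it against an independently
coded Michalsky (1988) algorithm; agreement is better than 0.005 rad over
1950–2050. Sun angle is evaluated at the colony: across a foraging range
of a few degrees of longitude the elevation differs by well under
0.06 rad near sunrise, negligible relative to the diel signal.

## Zero-inflated beta regression

Hourly proportions y ∈ [0, 1] of time in one behaviour are modelled as a
mixture: y = 0 with probability π(x) = logistic(γ₀ + γ₁x); otherwise
y ~ Beta(μφ, (1−μ)φ) with logit μ(x) = β₀ + β₁x and precision φ > 0.
Exact 1s (a behaviour filling a whole hour) are squeezed just inside the
open beta support via y′ = (y(n−1) + 0.5)/n. The joint likelihood is
maximised by L-BFGS-B from multiple jittered starts (gradient tolerance
1e-8, log-parameterised φ); standard errors come from the inverse
numerical Hessian. Because the submodels share no parameters, the joint
fit equals the two-part (logistic + beta) decomposition — checked to 1e-6
in log-likelihood by the tests.

Random-effects structure is deliberately simplified relative to a full
GLMM: per-bird intercepts are available as fixed-effect deviations
(`bird_effects=True`), and first-order autoregressive errors are not
modelled. This keeps the estimator desk-scale, fully testable by
parameter recovery, and adequate for the leave-one-bird-out robustness
check (`leave_one_bird_out`), which refits the model excluding each bird
and reports coefficient deviations. Slopes estimated without AR1 errors
are consistent but their SEs are mildly optimistic under residual
autocorrelation — a known limitation.

Hours are aligned to UTC clock hours; an hour enters the budget when at
least 50% of its labelled seconds are at sea (configurable), and
proportions are computed over at-sea seconds (renormalisation, the
default) or over the whole hour.

## Trip segmentation

Distances are haversine on a sphere of radius 6371.0088 km. A trip is a
maximal run of fixes more than 1 km from the colony (32°20′ N 64°40′ W →
(−64.6667, 32.3333) decimal degrees); it is complete iff bracketed by
within-radius fixes, and its start/end are the first/last at-sea fix.
"Long" means ≥ 2 days — the threshold cleanly separates the published
1.9-day short trip from the 5.9–13.9-day long trips and is configurable.
Summaries use the arithmetic mean and sample SD (n−1). The 50 km
`exclusion_filter` supports distribution analyses in which only
unambiguous foraging positions should enter.

## Synthetic deployments

The generator's defaults are the study conditions the analysis assumes;
they are not free knobs.

**Acceleration signatures.** Each class is a parameterised signal: a
gravity vector rotated by smoothly wandering pitch/roll angles and scaled
by an oscillating load factor, plus periodic components, band-limited
noise, scheduled wingbeat bouts, and temperature (28 °C in the burrow vs
18 °C at sea — the burrow range is not published; the values are
configurable). Defaults are hand-tuned so ≥ 95% of 15-s windows satisfy
the class's defining ethogram criteria when run through the signal-metrics
stage (e.g. burrow-still: mean VeDBA < 0.05 g; water-active: mean VeDBA
0.1–1 g with 10–50° posture fluctuations and stable VeSBA; dynamic
soaring: VeSBA peaks > 1.5 g, heave peaks > 2 g, no wingbeats; flap-glide:
wingbeat bouts of ≥ 3 successive > 2 g beats). The load-factor
construction keeps VeSBA ≈ 1 for water classes (a rotation does not change
the norm) while letting flight classes oscillate above 1.5 g — an additive
formulation could not satisfy both the posture and VeSBA criteria at once.

**Diel switching.** At-sea behaviour is a first-order Markov chain at 1-s
resolution. The default chain jumps with per-second probability 0.02 to a
target distribution equal to the configured at-sea occupancy — set to the
published activity budget (soaring 52.9%, flap-glide 27.6%, intensive
flight 0.9%, water active/inactive/intensive 9.2/6.2/4.5%) — tilted by
exp(m_j · sun angle) with positive m for water classes and negative for
flight. Tilting the jump target (rather than the transition rows) keeps
the realised time-averaged occupancy equal to the tilted occupancy, so a
24-h deployment reproduces the configured budget up to Markov sampling
noise. A user-supplied transition matrix instead has its destination
weights tilted and renormalised.

**Depth.** Sensor drift is a smoothed random walk min-max-confined to
[0, drift_max] (default time-scale 1800 s, slow relative to the 10-min ZOC
window so the correction can follow it); scheduled dives are smooth
excursions whose deepest sample equals the scheduled maximum and whose
shallowest in-dive sample stays above ~60% of it, so detected duration
matches the schedule.

**GPS.** Tracks are out-and-back correlated random walks: a sinusoidal
distance-from-colony profile pinned to the requested maximum range, small
correlated radial wiggle, and a slowly drifting bearing, mapped to
coordinates by the exact spherical destination formula. A truncation
fraction emulates loggers failing mid-trip (incomplete trips).

**Seeds.** One global seed expands into named per-stream sub-seeds via
`SeedSequence(seed, spawn_key=(k,))`, so the accelerometer, depth, diel,
track and label streams are independently reproducible; identical
configurations and seeds produce byte-identical output files.

**What the generator does not emulate** — and hence what passing tests do
not establish about field data: wind and wave forcing of the acceleration
signal, sensor calibration error and axis misalignment, gradual behaviours
that straddle segment boundaries (deployment labels change only at 15-s
block edges), magnetometer channels, prey-driven spatial structure in the
tracks, and moonlight effects on activity. Classifier accuracies near 100%
on synthetic segments reflect the sharply separated default signatures;
field accuracy with manual labels is necessarily lower.

## Problem sizes

Desk-scale runs use: 40 windows per class for signature fidelity; 200
segments per class (1800 total) for classifier acceptance; a 24-h at-sea
deployment (5760 segments) for the activity-budget check; 100 replicates
of n = 2000 hourly records for zero-inflated beta recovery; 12-h depth
traces for the dive pipeline. These sizes give stable statistics while
keeping the full suite around a minute and a half on one CPU.

## Degenerate inputs

Empty traces, all-outlier depth records, single-class training sets,
fewer than 3 birds for leave-one-out, and invalid transition matrices
raise `ValueError` with a named message. Burrow-only deployments flow
through the pipeline with warnings and empty at-sea outputs rather than
errors. Non-convergence of the beta mixture is flagged
(`converged_ = False`), not raised; an all-zero or all-positive outcome
marks the fit degenerate.
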