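# Methods

`homefield` reimplements the behavioral and neural analyses of a
homing-by-path-integration task: a mouse leaves a peripheral home-base bridge,
searches a circular arena (radius 40 cm) for a movable lever box, presses the
lever, and returns to the periphery — under alternating light and dark
conditions — while hippocampal CA1 units are recorded.  This note documents
the models, conventions, parameter choices and known limitations.

## Coordinate conventions

The arena center is the origin; the bridge center sits on the negative-y axis
at (0, −45) cm, so "south", the unit vector (0, −1), points from the arena
toward the bridge.  Angles are degrees in [−180, 180), counterclockwise
positive, measured from south where a reference is needed.  Units are cm, s,
Hz, degrees at the API boundary.  Position sampling need not be uniform: all
occupancy uses per-sample dwell time (gap to the next sample) capped at 3×
the median gap, so tracking dropouts do not inflate occupancy.

## Behavioral segmentation

Trials run from door-open to door-close; the light flag is the state of the
light events at door opening.  Trials whose lever-box center is more than
30 cm (75% of the arena radius) from the arena center are excluded.  A
journey is one bridge→arena→bridge excursion; the animal is "on the bridge"
when y < −42 cm (2 cm beyond the arena edge on the bridge side — the task
defines no numeric bridge zone, so this is our choice).  For journeys with a
lever press, the search path ends at the first sample within 10 cm of the
lever-box *wall* (nearest point of the 11.6 × 8.2 cm footprint, not the
center), the homing path begins when the animal leaves that zone after the
press, and it ends at the first sample within 3 cm of the arena edge (radial
distance ≥ 37 cm), which is the periphery-arrival point.

Path metrics: length (summed steps), duration, mean speed, and complexity
ln((1 − MVL) · 100), where MVL is the mean vector length of the unit
movement-direction vectors.  MVL is capped at 0.999 before the logarithm so
perfectly straight paths get a finite floor (≈ −2.303) instead of −∞; the
cap preserves monotonicity.  The homing direction is the signed angle at the
lever-box center between the lever→bridge and lever→arrival vectors; the
error at the periphery is the absolute angle at the *arena center* between
arrival point and bridge, a definition consistent with its 90° chance level
under uniform arrivals.

Median splits (short/long search, accurate/inaccurate homing) assign the
median element to the low group after a stable sort — deterministic, and
group sizes differ by at most one.  The light/dark classifier is a linear
SVM over the 8 search/homing path features with per-fold standardization and
seeded stratified 10-fold cross-validation.

## Firing-rate estimators

2D maps: 3 cm bins; occupancy smoothed with a 5 cm SD Gaussian; rate =
spike counts / smoothed occupancy, then smoothed again (5 cm SD).
Lever-centered maps use 1 cm bins and a 2 cm SD kernel.  Smoothing kernels
are renormalized over valid (visited) bins, so no mass bleeds in from
outside the sampled region; bins with zero raw occupancy stay masked.

1D histograms (firing rate vs y coordinate or vs lever distance) have
exactly 20 bins.  The shared range across light and dark is
[fixed minimum, min(p90_light, p90_dark)] with fixed minima −42.5 cm
(y coordinate; the arena–bridge gap) and 12.0 cm (lever distance);
percentiles use linear interpolation.  Occupancy and rate are each smoothed
with an SD of 1 bin.  The information score
Σᵢ pᵢ (λᵢ/λ) log₂(λᵢ/λ) is always computed from the *unsmoothed* occupancy
and rates, with 0·log 0 ≡ 0.

## Trial matrices

One row per lever-pressed journey; columns bin the y coordinate (2 cm),
lever distance (2 cm), or direction around the lever-box center (20° by
default; drift analyses use 10° bins, giving a 36-bin circle).  Rows are
smoothed with a 1D Gaussian, SD 2 bins (circularly for direction).  Rows
occupying fewer than 5 bins are dropped.  The trial matrix correlation is
the mean Pearson r over all distinct row pairs (jointly valid bins only);
zero-variance rows are excluded and counted.  Its significance, where
needed as a selection step, is assessed against 500 within-row permutations
of the rate values (α = 0.05) — the same shuffle used by the
peak-location-versus-lever-position test, whose null permutes rate values
within each row and compares the observed Pearson r between per-row peak
locations and lever y positions to the null's 95th percentile.  Peak ties
within a row resolve to the bin nearest the row's (circular) center of
mass.

## Lever-centered analysis

Positions are re-expressed relative to the lever-box center; samples more
than 12 cm from the box wall are excluded.  Direction around the box is
measured in one of three frames: cardinal (from south), bridge (from the
lever→bridge vector), lever (from the box-center→lever vector); the latter
two are rigid rotations of the cardinal data.  Directional tuning uses 36
bins of 10°, occupancy and rate each circularly smoothed (SD 1 bin); the
mean vector length and preferred direction come from the rate-weighted
resultant of the bin centers (the occupancy-corrected rate-vector form,
rather than per-spike directions).

A neuron is lever-box-anchored when all three criteria hold: (1) the peak
of its firing-rate-versus-lever-distance curve (2 cm bins over 0–30 cm)
lies within 10 cm of the box and exceeds the 95th percentile of a null
built from 500 circular time shifts of the spike train (≥ 20 s) along the
pooled journey samples; (2) the peak of its 2D lever-centered map exceeds
7.5 Hz; (3) the similarity of lever-centered maps from two independent
trial sets — odd versus even pressed journeys — exceeds 0.4.

Trial drift: the direction trial matrix is rolled so the mean tuning peak
sits at bin 0; the idealized tuning curve is the mean of rows after
aligning each row's own peak to bin 0; each row's drift δ_t is the lag
maximizing its circular cross-correlation (mean-subtracted, wraparound)
with the idealized curve, ties resolving to the smaller |lag|.  The
estimator is exactly shift-equivariant *given a fixed global roll*; the
API therefore accepts a precomputed roll, since re-deriving the roll from a
shifted matrix would absorb a common shift.  Drift–homing coupling uses the
Fisher–Lee circular–circular correlation with a 500-permutation p-value
(permuting homing directions) and reports the least-squares slope of drift
on homing deviation, both variables centered on their circular means and
wrapped to (−180, 180] — the slope convention that recovers an injected
drift-per-unit-homing-deviation coupling.

## Remapping

Pair similarity: Pearson r between two simultaneously recorded neurons'
rate maps over jointly valid bins, one value per unordered pair; stability
between conditions is the Pearson r of the two pair-similarity vectors over
pairs defined in both (≥ 10 shared pairs).  Condition partitions use
odd/even trial splits (not temporal halves) to decouple within-condition
comparisons from slow drift.  Zone-restricted maps (between bridge and
arena center) use the rectangle x ∈ [−15, 15], y ∈ [−40, 0] cm with 2.5 cm
bins, both configurable.

## Spike-train QC and cell classification

The refractory ratio is the mean of the spike-time autocorrelation in
(0, 1.5] ms divided by the maximum 0.5 ms bin in [5, 25] ms; units above
0.25 fail quality control.  Classification reduces peak-aligned,
amplitude-normalized mean waveforms and (sum-normalized) autocorrelations
to 3 principal components each, appends the mean rate (7 features total),
standardizes, and runs 2-means with 10 fixed-seed restarts; the lower-rate
cluster is pyramidal.  Log-transforming the rate is available but off by
default.

## Synthetic session generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the test suite.

* Task structure: 100 trials by default, the first seven in light, then
  strict light/dark alternation; the lever is re-placed uniformly within
  75% of the arena radius every fourth trial and rotated with the arena by
  a random multiple of 45° otherwise; every trial is door-open → journey →
  press → homing → door-close with a 5 s intertrial interval on the bridge.
* Search paths are discrete-time correlated random walks at 50 Hz
  (turn-noise SD per step 5° light / 18° dark; speed 40 / 20 cm/s; strong
  goal attraction in light, none in dark, with attraction ramping up after
  30 s so every search terminates well before the 240 s task timeout).
  Dark searches are therefore longer and more complex, as in the task.
* At the lever the mouse circles the box once at 8 cm/s at 7 cm radius and
  pauses 1.5 s at the pressable side; the task does not quantify at-lever
  dwell, so this single-circumnavigation model is a stand-in that samples
  all directions around the box each trial.
* Homing is a straight run to a peripheral arrival point whose angular
  error about the bridge direction is von Mises with concentration
  κ = 300 / (1 + 0.15 · search_length).  These constants were chosen so a
  default session shows light/dark median errors of roughly 5°/15° and a
  positive search-length/error correlation in the dark; only the
  qualitative structure (dark ≫ light, error grows with search) is load-
  bearing for the analyses.
* Spikes are inhomogeneous Poisson (per-sample thinning at dt = 20 ms) on
  one of three field archetypes: world-anchored Gaussian place field;
  lever-distance field (Gaussian in wall distance); lever-anchored
  directional field (von Mises in direction around the box × Gaussian
  radial window), whose per-trial orientation is rotated by
  δ_t = drift_slope · (homing deviation) + Gaussian noise.  Baseline 0.1 Hz.
* Multi-journey trials (failed searches) are available but default to
  probability 0 for determinism of trial counts.

What the generator does *not* emulate: theta rhythmicity and phase
precession, rate remapping within a condition, overdispersion beyond
Poisson, behavioral idiosyncrasies (wall following, grooming bouts),
tracking noise and dropouts.  Passing recovery tests therefore shows the
estimators are correct and well calibrated under the generative
assumptions, not that real recordings satisfy those assumptions.

## Validation benchmarks and problem sizes

`homefield.validation` fixes the benchmark conditions: 20 sessions × 50
trials × 10 neurons (5 lever-anchored with heterogeneous tuning widths
κ ∈ [2, 4], typical of broad object-directional fields, and 5 place cells)
for anchored-field detection; one 50-trial session with ~29° injected
rotations for drift recovery; 100 trials for slope recovery (injected
slope 0.5); 200 independent-drift neurons for the shuffle test's type-I
error; 20 in-zone place cells per condition for the remapping contrast
(the zone activity filter is set between the 0.1 Hz baseline and the ~1 Hz
condition mean of an in-zone field, since synthetic search traversals are
brief); 70 units for the cell-type closed loop.  These sizes keep the full
validation run to a few minutes on one CPU while leaving comfortable
statistical margins.

## Numerical notes and edge cases

* Gaussian smoothing with SD 0 returns the raw (masked) values.
* Zero-occupancy histogram bins are masked with a warning, not imputed.
* A distance/direction row with fewer than 5 occupied bins is dropped.
* Permutation p-values use the (k + 1)/(n + 1) convention and are therefore
  never exactly zero.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  public stochastic routine takes an explicit seed, and identical seeds
  give bitwise-identical sessions and analysis outputs.

## Limitations

The pipeline assumes the canonical frame (bridge due south) for
segmentation; rigidly rotated sessions are supported for frame-equivariance
checks but not for full re-segmentation.  The lever-anchored criterion 1
shuffle inherits its power from the ratio of at-lever firing to at-lever
occupancy, so very long at-lever dwells reduce sensitivity — visible in the
generator when the at-lever pause is made long.  The population-vector
style of remapping analysis is not implemented; remapping is quantified
through pair-similarity stability only.
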