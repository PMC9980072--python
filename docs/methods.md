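# Methods

This note documents the models and procedures implemented in `groomens`, the
parameters that matter, the design choices made where the design was open,
and the limits of what the synthetic-data validation can show.

## Conventions

All times are seconds (floats) on a single session clock. Intervals are
half-open `[start, end)`; frame `f` of a pose track spans
`[f/rate, (f+1)/rate)`. Bin indices are 0-based. A single pipeline seed fans
out through `numpy.random.SeedSequence.spawn` into independent child streams
per stage, so each stage is reproducible on its own and the full pipeline is
byte-deterministic given (config, seed).

## Grooming-bout detection

A grooming frame is one where the animal is rearing with its paws held near
the snout. The per-frame predicate is the conjunction of five postural
conditions — snout height above `min_snout_height`, eyes-midpoint to
hindlimbs-midpoint distance below `max_eyes_hind_dist`, paws-midpoint to
snout distance below `max_paws_snout_dist`, paws-midpoint to eyes-midpoint
distance below `max_paws_eyes_dist`, paws-midpoint height above
`min_paws_height` — plus an optional body-speed ceiling (`max_speed`,
disabled by default; the speed signal is the displacement of the eyes
midpoint smoothed by a 0.2 s centred moving average). Midpoints are
coordinate-wise means, distances 3D Euclidean. Keypoints with confidence
below 0.6 are treated as missing; any missing feature fails its predicate,
so uncertain frames are conservatively non-grooming.

Flagged runs whose gaps are strictly shorter than `merge_window_s` (1.2 s)
are merged in a single left-to-right pass, then merged candidates shorter
than `min_bout_s` (2 s) are discarded. Merging precedes the duration filter,
so two sub-2 s runs separated by a short gap survive as one bout. A gap
exactly equal to the window is *not* merged ("within 1.2 s" read as strict).

The threshold values carried as defaults are calibrated to the geometry of
the synthetic pose generator's arena (dimensionless units; the triangulated
coordinate frame of a real rig carries no canonical unit) and are expected
to be re-tuned per rig by inspecting predictions against video. Agreement
between two annotations is the temporal Jaccard index; two empty annotations
agree perfectly (1.0) by convention.

Separately from detection, bout lists entering event-aligned analyses are
post-processed: bouts separated by less than 3 s are merged into one bout,
and a bout is "well-isolated" only if it starts at least 10 s after the end
of the previous bout (the first bout needs 5 s of clear session so that ±5 s
flanks exist).

## Unit classification

Units are typed from two waveform features and the mean firing rate over the
entire session (total spikes / session duration):

| label | peak width | peak–valley interval | mean rate |
|-------|-----------|----------------------|-----------|
| SPN   | > 150 µs  | > 500 µs             | ≤ 10 Hz   |
| FSI   | ≤ 150 µs  | ≤ 500 µs             | ≥ 0.1 Hz  |
| other | everything else — excluded from all downstream analyses |

The boundary operators are exact: a 150 µs width is FSI-side, a 10 Hz rate is
SPN-side. The feature definitions — full width at half maximum of the
dominant deflection (linear interpolation at the half-max crossings), and
time from the dominant extremum to the subsequent opposite-sign extremum —
are standard choices; they are isolated behind `extract_waveform_features`
so an alternative convention can be swapped in without touching the rule.

## Transition-aligned responses

Event-triggered averages use a ±5 s window at 250 ms bins (40 bins; the
event time is the boundary between bins 19 and 20), averaged over
well-isolated bouts; events without full flanks inside the session are
dropped rather than zero-padded.

The 2-SD modulation flag works at 500 ms bins: for start alignment the
baseline is the bout-averaged activity 5–2 s before the start (6 bins) and
the test window runs from 1 s before to 1 s after (4 bins); for end
alignment the baseline is 2–5 s after the end. A unit is flagged iff
mean(test) > mean(baseline) + 2·sd(baseline), with the sample standard
deviation (n−1) over the six bout-averaged baseline bins; a fully silent
baseline degenerates to "any test activity". The flag is a labelled utility
for picking display examples — it does not gate any downstream stage.

For response typing, each unit's event-triggered average is z-scored across
its 40 bins and PCA is run with units as observations, separately per cell
type and alignment. Component sign is intrinsically arbitrary; each
component is oriented so its largest-|value| time bin is positive, which
makes group counts reproducible. Units with |weight| larger on PC1 than PC2
form the PC1 (step-like) group, the rest the PC2 (transient) group; the
weight's sign splits elevated from suppressed variants. Constant rows cannot
be z-scored and are dropped with a warning.

A caveat worth knowing: centered PCA can only separate step-like from
transient response *classes* when the population contains both signs of at
least one class. With exactly two homogeneous one-signed classes the column
mean absorbs their average and the first component becomes the
between-class difference. Recorded striatal populations mix elevated and
suppressed responses, and the synthetic validation populations do the same.

## The grooming matrix

Ensemble analyses operate on activity restricted to grooming bouts padded by
±5 s. Overlapping padded windows are merged into one segment. Each segment
is tiled with 1.5 s bins from its start; the trailing partial bin is kept
(so short bouts still contribute) and flagged. Binned activity is expressed
as a rate (count / bin width): with full-width bins this is
indistinguishable from counts after normalization, and it removes the
shared count deficit that width-truncated bins would otherwise imprint on
every unit simultaneously. Rows are min-max normalized over the concatenated
matrix (all-zero rows stay zero) and smoothed with a Gaussian filter
(σ = 3 s = 2 bins, truncated at 4σ) applied within each segment
independently, so activity never leaks between non-contiguous times.
Ensemble identification requires at least 30 SPN+FSI units.

The whole-session matrix used for the correlation contrast applies the same
binning, normalization and smoothing to the full session as a single
segment, so the grooming-vs-session comparison isolates the time mask alone.

## Ensemble count: shuffle-eigenvalue test

Each unit's binned rates are z-scored; the eigenvalues of the resulting
unit × unit correlation matrix are compared against the null distribution of
the *maximum* eigenvalue obtained when every unit's time bins are permuted
independently (5000 shuffles by default; 1000 in the scaled validation
runs). The estimate is the number of real eigenvalues above the null's 99th
percentile. Two numerical choices:

- The test consumes the raw (unsmoothed, un-normalized) binned rates, not
  the smoothed display matrix: the permutation null assumes exchangeable
  bins per row, and smoothing-induced autocorrelation would break that.
- Width-truncated trailing bins are excluded from the test (not from the
  matrix): their variance is inflated in a way that is aligned across all
  units, a structure the per-row shuffle cannot reproduce; with them
  included, sessions of fully independent units occasionally report
  spurious dimensions.

Calibration on independent-unit sessions (60 units, 2 h) returns zero
significant eigenvalues in ≥ 95% of runs; five planted ensembles are
recovered as 5 ± 1.

## Ensemble detection: meta-k-means

1000 repeats of k-means cluster the units (time bins are the features), with
greedy k-means++ initialization, one initialization per repeat, max 300
iterations, tolerance 1e-4, and k = round(√n_units). The fraction of runs in
which each unit pair shares a cluster forms the co-assignment matrix; pairs
above 0.8 (strict) define a graph whose connected components are the
intermediate clusters — components are the minimal closure of the pairwise
"same cluster" relation. Size-1 components are unassigned. Finally, cluster
pairs are greedily merged: the merge that yields the highest mean silhouette
score (Euclidean, over assigned units only) is accepted while the score does
not decrease; merging down to a single cluster is never evaluated since the
silhouette is undefined there. Cluster labels are relabelled by first member
for determinism.

The distance step operates on each unit's **z-scored** binned rates — the
same standardized representation the eigenvalue test uses — rather than on
the min-max/smoothed matrix. This is the one place the implementation
departs from applying the display matrix verbatim, and it is deliberate:
Euclidean distances on min-max rows are dominated by each unit's overall
activity level (low-rate and high-rate units form a one-dimensional
continuum of "rate bands"), and smoothing collapses the effective number of
independent time bins roughly seven-fold. Both artifacts make k-means
partitions of *unstructured* units highly repeatable across restarts, so
chance pairs pass the 80% co-assignment threshold and chain into large
spurious clusters. After standardization, proximity means co-fluctuation:
planted ensembles are recovered essentially perfectly (adjusted Rand index
≈ 1), and independent units are left unassigned, which is the behavior the
consensus-threshold construction presupposes.

## Ensemble characterization

Pairwise Pearson correlations are computed on the unsmoothed normalized
rows (smoothing correlates neighbouring bins, which widens the null spread
of between-pair correlations on the short grooming matrix without adding
information), split into within-cluster and between pairs (between includes
unassigned units), and summarized by the probability that a within pair
exceeds a between pair (Mann–Whitney AUC, ties ½). On grooming-specific
synthetic ensembles the grooming-matrix AUC exceeds the whole-session AUC
in 10/10 seeds. Probe-plane distances (shank axis × depth) are split the
same way, with per-animal cumulative curves reported as mean ± SEM.

Per-bout activity is linearly time-warped onto a common base: each padded
segment's flanks (3 bins = 4.5 s at 1.5 s resolution) are copied unwarped
and the core is linearly interpolated to a fixed number of bins — by default
the median core length across the session's bouts, stored in the output for
reproducibility. Affine traces warp exactly; a core shorter than two bins is
duplicated from the nearest sample and logged.

Significance bands come from 1000 random windows: durations resampled from
the observed bout-duration pool, starts uniform from 5 s into the session to
5 s before its end, each window processed identically to a bout (pad, bin,
normalize with the session's per-unit factors, smooth, population-average,
warp) and the per-bin mean, 2.5th and 97.5th percentiles taken across
windows. Windows may overlap real grooming bouts, matching unrestricted
sampling "throughout the session". A consequence: when grooming occupies
≈ 4% of the session, the windows that land on bouts populate the extreme
upper tail of the null, so the 97.5th percentile sits near grooming-level
activity itself. An ensemble's response is therefore judged significant by a
contiguous run of at least 2 warped bins outside the band (a configurable
rule), not by demanding most bins exceed it — an escape criterion that a
strongly modulated ensemble meets over the bout core while an unmodulated
ensemble's trace stays inside the band at ≥ 95% of bins.

Peak times are the argmax of the bout-averaged [0, 1]-normalized trace
(ties → earliest bin, logged). The percent-active-units variant counts the
fraction of member units with ≥ 1 spike per 1.5 s bin ("active" is not
otherwise defined; the threshold is configurable). Across-session summaries
report cluster counts, sizes, percent clustered and SPN/FSI composition,
with ordinary least-squares fits of cluster count and mean size against
unit count (R², two-sided slope p).

## Trajectories

Trajectory inputs concatenate activity during all padded bouts at 250 ms
bins, Gaussian-smoothed (σ = 0.5 s) within each segment and min-max scaled
per row — choices that keep the inputs non-negative and units comparable;
the temporal resolution for this step is not externally constrained and is
exposed in config. Four matrices share this time base: all units, clustered
units, unclustered units, and ensemble means.

The rank-3 NMF minimizes the Frobenius loss by multiplicative updates from
an NNDSVDa start (nonnegative double SVD with zeros filled with the matrix
mean), stopping at a relative loss change below 1e-6 or 500 iterations. The
solver is implemented in-package so the per-iteration loss sequence is part
of the result (it is non-increasing by construction of the updates, and the
test suite cross-checks the final reconstruction error against
scikit-learn's NMF on the same initialization). The initialization is
deterministic, so factorizations are reproducible without a seed. Factors
are reordered by the time of their peak score so that factor 1 rises first
(onset), factor 2 next (maintenance), factor 3 last (return).

## The synthetic-session generator

The generator emulates the statistical structure the analysis assumes, with
defaults matching spontaneous grooming in a 2 h session:

- **Bout schedule.** Durations log-normal with mean 12.4 s (log-space
  σ = 0.5); gaps exponential with mean 258 s (4.3 min). Right-skewed
  families match empirical bout-duration and gap histograms qualitatively;
  only the means are pinned. Bouts live in `[5 s, duration − 5 s]`. These
  means imply an expected grooming fraction of ≈ 4.6%, consistent with the
  ≈ 4.1% target within its tolerance (the three printed statistics are not
  exactly mutually consistent; the schedule is driven by the two means).
- **Spike trains.** Inhomogeneous Poisson per unit. Baselines uniform in
  0.2–7 Hz (SPN; the cap leaves headroom so grooming modulation cannot push
  a session mean over the 10 Hz classification bound) and 5–25 Hz (FSI).
  Each ensemble has a response profile scaling the rate in its active epoch:
  step_up ×gain over the whole bout; step_down / sustained_suppressed
  ×1/gain; transient_start and transient_end ×gain in ±1 s around the
  transition; none — no epoch modulation. Default gain 5.
- **Co-activity.** Two mean-one multiplicative processes on a 1.5 s grid
  within padded (±5 s) bout epochs. (1) *Shared co-activation events* per
  ensemble: in each grid cell the whole ensemble is co-active with
  probability 0.4 (gain 2.2) or quiescent (compensating gain ≈ 0.2) — the
  discrete synchronous-event structure visible in real population rasters,
  and the signal that makes an ensemble detectable as such. (2) A *private*
  log-normal gain per unit and cell (σ = 0.85) for every unit: real units
  are never homogeneous Poisson, and the private variability is what makes
  "fluctuating unit" different from "ensemble member" (shared fluctuation).
  Both processes are confined to grooming epochs, so ensemble correlations
  are grooming-specific, and both are independent across grid cells —
  aligned with the analysis bins — so the eigenvalue test's bin-shuffle
  null remains exact. The amplitudes were fixed once from the geometry they
  induce (within-ensemble distances ≪ cross-ensemble ≈ unstructured-pair
  distances) and from closed-loop recovery, before the validation suite was
  frozen.
- **Waveforms and positions.** Waveform features are drawn well inside the
  classification regions per true type (SPN 180–300 µs width, 550–900 µs
  interval; FSI 80–140 µs, 250–450 µs), so classification reproduces the
  planted labels exactly; an optional full-waveform mode synthesizes
  biphasic templates with prescribed trough FWHM and trough-to-peak time so
  the feature-extraction path is exercised too. Probe positions sit on four
  shanks at 200 µm pitch; with spatial structure enabled, members of an
  ensemble share a shank and scatter (σ = 40 µm) around a common depth.
- **Pose.** 15 named keypoints at 125 fps. Outside bouts the animal
  locomotes smoothly in a stretched, low-snout posture that violates the
  rearing predicates in every frame; inside bouts it freezes in place in a
  hunched rearing posture with the paws oscillating near the snout (4 Hz),
  satisfying every predicate. Keypoint noise is isotropic Gaussian with
  configurable σ. Predicate margins are several times the default noise, so
  detection degrades gracefully.

### What the synthetic validation does and does not show

Passing the closed-loop tests shows the pipeline's stages are internally
consistent, correctly calibrated under their own null assumptions, and able
to recover structure of the kind they model. It does not show the heuristics
or thresholds transfer to a particular rig (arena geometry and units
differ), nor that real striatal co-activity follows a two-state event
process, nor how the methods behave under nonstationarities the generator
omits: electrode drift, bursting and refractoriness, behavioral states other
than grooming that co-modulate many units, within-bout syntactic phase
structure (bouts are generated as homogeneous epochs), or pose-estimation
failure modes beyond isotropic jitter and missing keypoints.

## Validation problem sizes

The test suite exercises the pipeline at deliberately modest scales chosen
to keep the feedback loop tight while leaving the statistics meaningful:
2 h sessions with 60 units for ensemble analyses (50 seeds × 1000 shuffles
for the eigenvalue calibration), 200-unit populations for response typing,
125 fps pose over 10-minute sessions for detection, and 1000-window
bootstrap bands. The full suite runs in a few minutes on one
CPU.
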