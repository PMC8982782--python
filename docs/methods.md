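# Methods

This note documents the models, conventions and design choices behind
`faceattn`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were resolved.

## Landmark schema and features

The face is represented by 34 named landmarks (index -> name map in
`faceattn.schema.LANDMARK_NAMES`). The numbering is the tracker's own and
is not spatially sequential; it is kept verbatim so feature identifiers
remain comparable with published threshold tables, whose free-text
descriptions are occasionally inconsistent with the index map — indices,
not descriptions, are authoritative here.

All C(34,2) = 561 unordered pairs are used as distance features, indexed
by lexicographic rank ((0,1) -> 0 ... (32,33) -> 560). Published accounts
of this feature space sometimes quote 560 distances; 561 is
combinatorially forced, so the package implements 561 and offers
`session_feature_matrix(..., drop_pair=...)` to drop one named pair for
strict 560-column replication.

Coordinates are continuous 2D points in mm in the image plane; no pixel
indexing convention applies. A frame with any missing/NaN coordinate, or
with its validity flag cleared, is invalid: it is kept in the stream but
contributes to nothing downstream (no imputation), mirroring the
confidence gating of the upstream tracker.

## CPT annotation

Each letter presentation (1400 ms) defines a slot. A slot is labeled
attention iff the subject was looking at the screen **and** responded
correctly (`is_target == clicked`); every other combination — miss, false
alarm, or gaze off screen — is inattention. The full 8-row truth table is
in `faceattn.annotation`. Two operationalizations are worth noting:

- Observational cues (gaze, calling letters aloud) are collapsed into a
  single `looking_at_screen` boolean in the event log; the artifact has no
  video or audio channel.
- A correct rejection (non-target, no click, looking) counts as attention,
  since inattention is tied to incorrect responses or looking away.

Slot -> frame mapping: a frame belongs to a slot iff its full exposure
interval `[t, t + 1/rate)` lies inside `[onset, onset + duration)`. At
16 Hz this puts floor(1400 x 16 / 1000) = 22 frames in each 1400 ms slot;
the frame straddling a slot boundary belongs to no slot and is labeled
invalid. The timestamp-membership alternative would yield 23 frames and
assign boundary frames ambiguously; full containment keeps slots
non-overlapping by construction.

## Standardization and the MAE check

Features are z-scored with training-fold statistics only. The standard
deviation uses the population convention (divide by n; `ddof`
configurable) — the convention is not fixed by the published formula, and
at the sample sizes involved the difference is negligible. Features
constant on the training fold have no defined z-score and are dropped
(recorded in `StandardizationParams.dropped_feature_ids`).

The landmark-distortion check is the mean absolute difference of a
sentinel pair's distance (default: right top jaw <-> left top jaw) across
consecutive same-class valid frames; invalid frames break the pairing. On
a zero-noise, fixed-pose synthetic session every pair's MAE is exactly 0;
at the default generator noise it is of order 1 mm, the same order as the
published per-participant values (0-1.06 mm). Distances are always
computed per frame; the sequence-based variant (displacements between
frames) is out of scope.

## Distance-threshold selection

The selection statistic is gf = mean distance in inattention minus mean
distance in attention, per pair, computed by pooling all training frames
(a per-participant-mean variant can be built from the per-bundle API). Two
readings of the "class mean" step exist — mean landmark coordinates versus
mean per-frame distances; the pipeline uses mean distances because the
published per-pair tables are in distance units, while `class_mean_face`
provides the coordinate version for mean-face visualization.

Ranking is by signed gf, descending (an absolute-value mode exists but is
off by default, matching the published tables where all selected
thresholds are positive); ties break toward the smaller feature id so
selection is deterministic, and the top-k menus nest (top-10 is a prefix
of top-20, etc.). Selection always runs inside the training fold of
whatever evaluation regime is active, never on pooled train+test data.

## Classifiers

**SVM.** RBF kernel on the selected standardized features. Grid search is
exhaustive over C in {1..26} x gamma in {0.001, 0.01, 0.1, 1, 10}, scored
by mean stratified k-fold accuracy (k = 10), ties to smaller C then
smaller gamma; the defaults (C = 11, gamma = 0.1) are the published final
values and are used when tuning is off. No class weighting: imbalance is
addressed at the metric level (AUC, F1). Grid-search folds are stratified
by class; a participant-blocked variant can be had by tuning on
participant-level splits externally.

**CNN.** Landmarks are rasterized to 32x32 binary images. The
normalization box is per-frame (landmark bounding box plus a one-pixel
margin) by default, which makes the raster invariant to head translation
and scale but also *removes* global pose cues; a fixed global box can be
passed to preserve them. This choice materially affects what the network
can learn and is the main free parameter of the raster representation.
Dot size is one pixel; coincident landmarks share a pixel.

The network follows the published topology exactly — two valid 3x3
convolutions of 32 and 64 maps, each followed by 2x2 max-pooling, dense
62 then 1, ReLU hidden activations, 20% (inverted) dropout before the
output, sigmoid output thresholded at 0.5 — giving spatial sizes
32 -> 30 -> 15 -> 13 -> 6 and exactly 161,789 parameters. The training
regimen is not fixed by the published description; the defaults here are
Adam at 1e-3, batch 32, 30 epochs, logit binary cross-entropy, 10% of the
training rows as a seeded validation split, all configurable. The network
is implemented directly on numpy in float64 (im2col convolutions,
analytic backprop); evaluation-mode predictions are deterministic given
the seed and agree across batch sizes to well under 1e-6.

## Evaluation protocol

Metrics: accuracy; rank-based AUC (probability a random attention score
exceeds a random inattention score, ties one half — equal to the
trapezoidal ROC area); F1 with attention as the positive class (the
published summaries do not name the positive class; attention, the
majority class, is the default and is configurable). Confusion matrices
have truth on rows (attention, inattention).

- *Participant-specific*: 10 repeated stratified 80/20 row splits per
  participant ("repeated splits", not 10-fold), averaged per participant
  and then across participants.
- *Leave-one-participant-out*: one fold per participant; selection,
  standardization and the classifier are refit in every fold. Folds whose
  held-out participant lacks a class report AUC as undefined and are
  excluded from the AUC average (counted in `n_auc_excluded`).
- *Within/cross-group*: four cells (train/test on group A/B in both
  directions), 50 iterations by default, each with fresh participant-level
  80/20 splits per group; the two cells sharing a test group see the same
  held-out participants in a given iteration. Cell summaries report mean
  and sd of F1 and AUC over iterations.

Participant independence is asserted at split time in every
participant-independent regime.

## Synthetic cohort

The generator renders a bilaterally symmetric 3D face template (cross-face
distances ~75-175 mm) through a per-slot two-state Markov chain
(P(stay attention) = 0.90, P(recover) = 0.65, stationary attention
fraction 0.867, matching the strong imbalance of real CPT data). Attention
pose: yaw ~ N(0, 3) deg; inattention: yaw ~ N(25, 5) deg with the sign
fixed per participant (all positive by default — everyone averts toward
the same screen corner; `yaw_sign_mode="random"` draws the side per
participant). Pitch jitters by N(0, 2) deg in both states. Heterogeneity
enters as an additive N(0, 2 mm) per-participant 3D shape offset
(8 mm in the `heterogeneous()` preset), per-frame coordinate noise is
N(0, 1 mm), and 2% of frames are dropped as tracking failures. Projection
is orthographic: simpler than perspective and sufficient to reproduce the
qualitative projected-distance geometry under yaw. Event logs are sampled
to be consistent with the latent state, so the annotation pipeline can be
verified to reproduce the generated truth exactly.

Positive yaw is defined as the turn that swings the deep-set left-jaw
landmarks toward the image plane, which *lengthens* projected
left-jaw-to-right-face distances — the published pattern (positive
thresholds concentrated on left jaw x right brow/eye/nose pairs). The
planted ground truth ranks pairs by this signed analytic shift, computed
by Gauss-Hermite quadrature over the yaw distribution (not at the mean
pose; the distance is nonlinear in yaw, and the quadrature expectation is
what the empirical class means estimate). Signed ranking is the
self-consistent choice: under orthographic yaw a mirror pair always
shrinks at least as much as its partner grows, so an absolute-value ground
truth would be dominated by shrinking pairs that the signed descending
selection — the method under test — never picks.

What the generator does *not* emulate: facial expression and action-unit
dynamics, blinks/occlusions, perspective foreshortening, tracker-specific
error correlations, and any appearance (texture) information. Passing
parameter-recovery and regime-gap tests on this cohort therefore shows the
pipeline's statistical machinery is correct under the pose-driven model of
attention, not that the classifier reaches any particular accuracy on real
children.

## Problem sizes and numerical conventions

The standard synthetic cohort is 8 + 8 participants x 3000 frames (16 Hz,
~3 min of video each), the scale used for parameter-recovery runs; the
regime-gap and training demonstrations use smaller cohorts (3 + 3 x 600
frames) and a 260-image raster task, sizes chosen to keep a full
reproduction run in the minutes range on a single CPU. Distances and
standardization are float64 throughout; equality tolerances are 1e-6 mm
for CSV round-trips (coordinates are written with six decimals), 1e-9 for
oracle comparisons, 1e-6 for CNN batching invariance. Degenerate inputs
fail loudly: empty classes, single-participant LOPO, misaligned feature
ids, degenerate raster boxes and out-of-range top-k all raise typed
errors rather than returning silent defaults.

## Known limitations

- The pose -> distance mechanism is the *only* attention signal in the
  synthetic data; real attention shifts also involve gaze without head
  motion, which landmark distances cannot see.
- The per-frame raster normalization removes exactly the pose cue the
  distance features exploit, so the CNN path is at an intrinsic
  disadvantage on the synthetic cohort; use a global box to compare the
  two fairly.
- Grid search at the published grid size (130 cells x 10 folds) is
  expensive on large cohorts; tuning is off by default.
- F1 and accuracy depend strongly on the class balance set by the Markov
  chain; comparisons across configs should hold the chain fixed.
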