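# Methods

This note documents the models behind each pipeline stage, the knobs that
matter, what the synthetic data does and does not exercise, and the
numerical and design choices a maintainer would want written down.

## Dataset model and manifests

Images carry zero or more face annotations: a box (left, top, width,
height; 0-based pixel coordinates, x right, y down), named continuous
landmarks (`leye`/`reye` = outer eye corners; the map is extensible),
and optional identity, species, capture-date and age metadata. Manifests
serialize to an imglab-style XML dialect with deterministic element and
attribute order, so `write(read(f))` is byte-identical; part coordinates
round-trip to 4 decimal places, box geometry and labels exactly. Unknown
box attributes are preserved verbatim so externally edited manifests
survive a round trip.

Train/test splitting is stratified with largest-remainder apportionment:
the overall test count is exactly `floor(fraction × N)`; each stratum
receives `floor(fraction × n)` seats plus at most one leftover seat,
assigned by descending fractional remainder (ties to the
lexicographically first stratum). With a single stratum this is the plain
floor split (609 → 488/121 at 20%); across strata the totals still match
the global floor (the per-stratum-floor alternative undercounts). An
optional grouping flag keeps all images of one individual taken on the
same calendar day on one side of the split, for image-independence
experiments; images with no date act as singleton groups. The identity
filter applies an optional minimum-age cut first (annotations without age
metadata are excluded and counted in a report — their handling is
surfaced rather than guessed), then drops identities with fewer than the
required number of images; it is idempotent.

## Synthetic faces

The generator renders 2-D faces: a head ellipse with two ear discs, a
muzzle, two dark eye discs, and a per-identity fixed set of up to 12
elliptical markings with signed contrast — the stable facial patterning
that makes marked individuals distinguishable. Four species families set
head aspect ratio, ear size, muzzle proportion and tone range. Nuisance
parameters per render: in-plane rotation (default range ±18°), face
width in pixels (scale; minimum 24 px, default 0.34–0.55 of the canvas),
translation, illumination gain/offset, Gaussian pixel noise (default
sd 0.02), background tone and clutter ellipses (default 0–3), and an
optional occlusion bar covering ≤20% of the face. Eye landmarks and the
head bounding box follow in closed form from the layout, so ground truth
is exact before rasterization; renders whose eye corners leave the canvas
are rejected (both eyes visible is the inclusion criterion).

Per-identity image counts for range configs are drawn from a triangular
distribution with mode near the minimum — most individuals photographed
rarely, a few heavily, as in real photo-ID archives. The default
dataset config (32 identities, 7–40 images each, 160 px canvas) has a
mean of ≈19 images per individual and ≈600 images in total, the scale of
a single-species photo-ID subset.

What the generator does **not** emulate: out-of-plane pose (approximated
only implicitly through eye-spacing variation across identities), fur
texture, lighting direction, color, camera blur, and scene-level
confounds such as an individual photographed repeatedly in the same
enclosure. Passing tests therefore demonstrate that the algorithms and
the evaluation machinery are correct and learnable at this scale — not
that the pipeline reaches any particular accuracy on real photographs.

## Detector

HOG features: 8-px cells, 9 unsigned orientation bins, 2×2-cell blocks,
L2-Hys normalization; the window is 6×6 cells (48×48 px), giving a
900-dimensional window descriptor. The image pyramid uses a 5/6 scale
step, so faces from 48 px up to the canvas size are reachable. Training
warps each ground-truth box (squared up, edge-replicated) to the window
and fits a linear SVM (C = 1.0) against random face-free windows
(IoU ≤ 0.3 with any face), followed by 3 rounds of hard-negative mining:
the current model is run over the training images and its false positives
(up to 10 per image) join the negative set before refitting. Detection
scores every window at every level, keeps those above the operating score
threshold (default 0.5, set from a precision/recall sweep on synthetic
validation data; average precision itself is computed from the full
ranked list and does not depend on it), maps boxes back to original
coordinates, and applies greedy NMS at IoU 0.5 with deterministic
tie-breaking (score, then left, then top).

The production systems this mirrors use a CNN detector; here the
gradient-histogram + max-margin scorer keeps the same interface and
evaluation surface while remaining trainable in minutes on one CPU.

## Shape predictor

A cascade (default depth 8) of gradient-boosted regression trees predicts
the box-normalized shape, starting from the mean training shape. Each
stage samples 120 box-relative pixel positions and 300 random
pixel-difference features from them, then fits 40 depth-3 trees with
shrinkage ν = 0.1 on the shape residual (greedy variance-reduction
splits via decision-tree regression). Training oversamples each face 10×
with jittered boxes (±6% shift, ±10% scale) to emulate detector box
noise. Features are indexed to the *box*, not to the current shape
estimate — a simplification of the classical shape-indexed cascade that
is exactly covariant under joint translation of image and box and
approximately covariant under scaling; with only two landmarks it loses
little. Out-of-image feature reads use edge replication.

## Chipping

The two-point similarity transform has the closed form `z → a z + b` in
the complex plane with `a = (c_r − c_l)/(s_r − s_l)`; no reflection can
arise, and left/right is taken from landmark names, never geometry
(coincident eyes raise a degenerate-geometry error). Chips are 150×150
with canonical eyes at 25%/75% of the width and 40% of the height,
sampled by bilinear interpolation through the inverse map with edge
replication. Transformed eye landmarks land on the canonical positions to
well under 1e-4 px for every chip.

## Embedder

Chips are standardized per-chip (mean 0, variance 1; skipped for constant
chips) and described by HOG with 15-px cells (2916 dimensions). Training
centers the descriptors, projects onto up to 256 principal components
(SVD with deterministic sign fixing), initializes the D = 128 projection
as the identity over the leading components scaled so the mean matching
and non-matching training-pair distances straddle τ, and then runs
full-batch gradient descent on the pairwise hinge loss (margin 0.1,
step 0.05, up to 300 epochs, early stop when the loss improves by less
than 1e-6 for 20 consecutive epochs). Up to 1000 matching and 1000
non-matching training pairs are sampled without replacement under the
seed. The stored model is a single affine map (center + D×F projection),
so embedding is one matrix product.

τ defaults to the fixed value 0.6; a config flag instead tunes τ on the
training pairs by balanced-accuracy maximization. Cross-validated
verification uses the tuned mode by default, so each fold's operating
point is chosen without seeing its held-out pairs. A pair is predicted to
match when distance ≤ τ (the boundary counts as a match).

The reference systems in this area use deep CNN encoders; the fixed
descriptor + learned linear projection here keeps the same pairwise
objective family and the identical verification interface at desk scale.

## Classifier

One-vs-rest linear SVM (C = 1.0) over embeddings; class labels are kept
sorted and ties in the per-class scores resolve to the lexicographically
first label. The output label is always from the training set (closed
set); there is no unknown-individual rejection.

## Evaluation

Detection matching is greedy in descending score; each detection claims
the unmatched ground-truth box of highest IoU if that IoU ≥ 0.5 (ties to
the earlier box); duplicates are false positives, unclaimed boxes false
negatives. Precision is reported as 1.0 when nothing was detected.
Interpolated AP takes the running-maximum precision envelope from the
high-recall end and integrates over achieved recall only. Pair sets are
sampled without replacement (all matching pairs are used, with a warning,
when fewer exist than requested; an exhaustive mode is available since a
printed pair count could arise either way). Balanced accuracy uses the
pair-set class ratios (0.5/0.5 for the balanced sets built here). ROC
curves take one point per distinct distance plus both endpoints;
trapezoidal integration of the curve equals the pairwise-comparison AUC.
Fold construction: by-chip folds deal each identity's shuffled chips
round-robin (identity-stratified); by-identity folds partition the
shuffled identity list. SDs across folds and faces use the n−1 sample
estimator. Percentages are printed to one decimal, rounding half up. The
end-to-end report excludes erroneous (unmatched) detections from identity
scoring under the default policy and counts them separately.

## Problem sizes and runtime

The reference study (`wildface.experiments.andean_study`, also what
`scripts/acceptance.py` runs) uses the default 32-identity dataset
(~600 images, 160 px), an 80/20 split, full default training configs, a
230-pairs-per-class golden verification set, and fivefold
cross-validation with 214 (by-chip) and 400 (by-identity)
pairs per class — a few minutes on one CPU. The regime-gap comparison
repeats both regimes on ten 16-identity datasets of 8 images each. The
unit-test fixtures use the same algorithms with smaller budgets
(shallower cascades, one mining round); those budgets are fixture
choices, not recommended settings.

## Known limitations

* The detector is single-scale-window and single-class; heavily occluded
  or profile faces (no second eye visible) are out of scope by design.
* The linear embedder cannot model nonlinear appearance changes (aging,
  seasonal coat change); on synthetic data this does not bind, on real
  data it would.
* By-identity generalization is markedly weaker than by-chip
  verification (the expected direction for a novel-individual setting);
  the fixed-τ operating point transfers poorly to unseen individuals, and
  tuning τ on training pairs only partially closes that gap.
* End-to-end accuracy is visibly below golden-chip accuracy: detector box
  noise propagates through landmarks and chipping into the embedding —
  the cumulative-error effect the accounting report is designed to
  expose.
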