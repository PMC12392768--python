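# Methods

This note documents the models and procedures implemented in `fdiarch`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test bed does and does not show
about real intraoral scans (IOSs).

## Coordinate conventions and the standard pose

All coordinates are millimetres. A scan in the *standard pose* satisfies:

- the vertex centroid is at the origin;
- the two first-molar centroids differ only in x, with the
  patient-right quadrant (1 or 4) on the −x side;
- the occlusal-plane normal on the coronal (crown) side is +z;
- anterior teeth therefore lie toward −y, i.e. the forward direction is
  `(0, −1, 0)` and the up direction `(0, 0, 1)`.

The occlusal plane is defined by three landmarks: the two first-molar
centroids and the mean of the two central-incisor centroids
(`align.standard_pose_from_landmarks`); scans missing any of the four
landmark teeth cannot be standardized this way and raise a
`LandmarkError`. Which side of the plane is coronal is decided by the
vector from the gingiva centroid to the tooth centroid (falling back to
the overall vertex mean when no gingiva vertices are labelled). Upper
and lower arches end up oriented identically, so one offset prior per
arch suffices and left/right mirroring is simply x-negation.

"Centred on the origin" means the mean of *all* vertices. This matches
the crop step's recentering, and makes the standardization of a freshly
generated arch exactly idempotent — a property the test suite relies on.

`align.pca_rough_align` maps principal axes (descending variance) onto
x, y, z. Signs are fixed deterministically: each axis is flipped so the
coordinate skewness along it is nonnegative (for near-zero skewness the
largest-magnitude loading is made positive), then the last axis is
flipped if needed to make the rotation proper. PCA alignment is a rough
initializer only; it cannot recover the true pose of partial arches,
which is why the loss functions below exist to supervise a learned pose
regressor.

## Alignment losses

For ground-truth directions `f', u'` (unit, orthogonal) and predicted
`f^, u^` (arbitrary nonzero):

```
L_orient = 2 − cos(f', f^) − cos(u', u^) + |cos(f^, u^)|
L_align  = L_orient + SmoothL1(c', c^) + BCE(s', s^) + Dice(s', s^)
```

`L_orient` is nonnegative, zero exactly when the predictions are
parallel to the truth and mutually orthogonal, and invariant to positive
rescaling of the predictions. Reductions and constants are the dominant
conventions: smooth-L1 with β = 1 and mean reduction over the 3
translation coordinates; binary cross-entropy with mean reduction and
scores clamped at 1e-7; Dice loss as 1 − soft-Dice with additive
smoothing 1e-6. `align_loss` returns the per-term breakdown alongside
the total, and the decomposition is exact by construction.

At inference (`align.apply_standardization`) the predicted translation
is applied in reverse, the forward direction is Gram-Schmidt
orthogonalized against the (kept) up direction, and the left-right axis
completes a right-handed orthonormal basis that rotates the scan into
the standard frame. A rigid motion round trip through this path is
exact to floating-point precision.

## Partial-arch crop augmentation

Full-arch scans are converted into realistic partial-arch training
inputs in four steps: choose a run of consecutive teeth along the arch
sequence, crop with an oriented bounding box around the selected teeth,
keep only the largest connected surface inside the box, and recenter the
result at the origin. The recentering translation is recorded as the
ground-truth target `c'` for the alignment regressor. The augmentation
is applied with probability 0.9.

Parameters (`crop.CropConfig`):

- `apply_probability` = 0.9;
- tooth count drawn from a truncated geometric on {2..12},
  `P(n) ∝ 0.75^(n−2)` — the simplest monotone distribution with higher
  probability for fewer teeth; the ratio is configurable. A drawn count
  exceeding the available teeth is clipped.
- `box_margin_mm` = 2: padding of the box so the gingival collar around
  the selected teeth survives.

The box is *upright*: its horizontal axes are the principal axes of the
selected vertices' xy coordinates, its third axis is z. A full 3D PCA
box is unreliable here — for anterior segments the tooth-height variance
is comparable to the anterior-posterior variance, so the principal axes
mix y and z and the tilted box slices through the gingiva. Since crops
operate on standardized scans, an upright box is the natural choice.

Surface connectivity uses the face-edge graph for meshes and an
ε-radius neighbour graph (ε = 2× median nearest-neighbour distance) for
bare point clouds. Ties between equal-size components keep the one
nearest the selected teeth's centroid.

Known limitation: on arches with interior missing teeth the box can span
the edentulous gap and the curved gingiva band may exit the box, so the
"one connected surface with exactly the selected teeth" guarantee holds
for continuous arches; crops across tooth gaps may keep fewer teeth than
selected, just as crops of real pathological scans would.

## Gaussian tooth-pair offset prior

From annotated scans in standard pose, for every ordered pair of
co-occurring FDI labels `(i, j)` the offset `centroid(j) − centroid(i)`
is stored; each offset is also mirrored across the midline (x negated)
onto the reflected pair, doubling the sample count. Offsets between the
disconnected components of a single annotated tooth (a tooth split by a
restoration or an incomplete scan is still one tooth) are pooled per
arch and shared by every same-label pair `(i, i)`, allowing the sequence
model to keep two fragments on the same FDI number.

Fitting (`postprocess.fit_offset_model`): per pair with k ≥ 1 samples,
μ is the sample mean and Σ the maximum-likelihood covariance (divide by
k) plus a ridge εI with ε = 0.01 mm². Pairs with k < 4 first blend
their covariance with the pooled within-arch covariance,
`Σ ← (k/4)·Σ_ML + (1−k/4)·Σ_pooled`, so near-empty pairs are not
degenerate. Pairs never observed use a fallback cost: the negative log
density under the pooled-arch Gaussian, floored at 50 (configurable) —
unobserved pairings are strongly but finitely discouraged.

## FDI relabeling by dynamic programming

Given predicted instances (centroids + 32-class logits) in the standard
frame:

1. The arch (upper vs lower) is chosen by total softmax mass over the
   two 16-label blocks (ties go to upper).
2. Teeth are ordered along the arch: the first tooth is the centroid
   with maximum y (ties: maximum x); each next tooth is the unvisited
   centroid whose origin-anchored xy direction has maximum cosine
   similarity to that of the last appended one. On a centred,
   standardized scan this is nearest-angular-neighbour traversal; it is
   validated against a polar-angle-sort oracle on synthetic arches. The
   sequence may run left-to-right or right-to-left; because offsets are
   stored for both orders of every pair, the costs are direction-
   agnostic.
3. Unary costs are −log softmax over the selected arch's 16 logits
   (restrict-then-softmax, keeping each row normalized); pairwise costs
   are −log Gaussian densities of the consecutive-tooth offsets under
   the prior, a (T−1)×16×16 table.
4. A forward dynamic program over the 16 labels computes the
   minimum-cost label sequence with predecessor backtracking, O(T·16²).
   Repeated labels are permitted; ties break toward the lower canonical
   label index for determinism. The DP is verified exactly against
   exhaustive enumeration of all 16^T sequences for T ≤ 4.

The mechanism that makes this work: a mislabelled but correctly located
tooth pays a bounded unary penalty (the softmax margin), while an
anatomically inconsistent label pair pays a Mahalanobis penalty that
grows quadratically with the offset mismatch — one inter-tooth spacing
under a sub-millimetre covariance is dozens of nats. The optimum is
therefore the anatomically consistent run anchored by the confident
majority, which is why postprocessed accuracy dominates per-tooth argmax
accuracy on every tested arch.

## Evaluation metrics

- **Matching**: point-wise IoU between every annotated/predicted tooth
  pair, optimal one-to-one assignment (Hungarian algorithm), pairs with
  IoU < 0.5 discarded; the 0.5 threshold is inclusive. Matching by
  optimal assignment rather than greedy pairing is deterministic and
  order-independent.
- **Detection F1** = 2TP/(2TP+FP+FN); **tooth Dice** = mean point-wise
  Dice over matched pairs; **label macro-F1** = unweighted macro-F1 of
  predicted vs annotated labels over matched pairs (classes present in
  the annotations); **macro-IoU** = unweighted mean over FDI labels
  (present on either side) of the per-label point-wise IoU.
- **Challenge metrics**: TLA_raw is the mean over annotated teeth of the
  distance from the annotated centroid to the closest predicted
  centroid, normalized by the annotated tooth's size (bounding-box
  diagonal; configurable), with a penalty of 5 per tooth when nothing
  was predicted. Because published leaderboards report localization on
  a higher-is-better scale, the transform TLA = exp(−TLA_raw) is
  reported alongside the raw distance. TSA is the F1 over the binary
  tooth-vs-background vertex partition. TIR is the percentage of
  annotated teeth whose closest predicted tooth lies within normalized
  distance 0.5 ("closely predicted"; configurable) and carries the same
  FDI label. Score = (TLA + TSA + TIR/100)/3.
- Degenerate edges: metrics over empty-vs-empty sets return their
  perfect value with a logged warning; means over zero matched pairs are
  reported as missing (`None`) rather than invented.

## Synthetic arch generator

The generator produces what the algorithmic stages actually consume —
plausible geometry with exact annotations — not photorealistic anatomy.

- **Arch curve**: parabola `y = d(x/w)² − d` (w = half of
  `arch_width_mm` = 55, d = `arch_depth_mm` = 45), anterior at −y.
  Each of the 16 FDI positions owns an arc-length slot proportional to
  its mesiodistal width, so missing teeth leave anatomically positioned
  gaps and pair offsets are label-specific.
- **Teeth**: anisotropically scaled icospheres (42 vertices by default)
  with class-dependent widths (molars ≈ 10 mm mesiodistal, premolars
  ≈ 7 mm, incisors 6.5–8.5 mm, 8 mm crown height), oriented along the
  local arch tangent. Teeth fill 65% of their slot mesiodistally; the
  resulting ~2–3 mm gaps are wider than natural interproximal contact —
  a deliberate stylization that keeps adjacent teeth out of each other's
  crop boxes. Tooth positions are jittered isotropically
  (`centroid_jitter_mm` = 0.3).
- **Gingiva**: a two-row triangulated ribbon along the whole curve at
  the tooth-base level, bridged to each tooth by a triangle to the two
  concave-side ribbon vertices directly beneath the tooth centre. This
  bridging is deliberate: any crop box containing a tooth contains its
  bridge, while a clipped fragment of a neighbouring tooth always loses
  its bridge and is removed by the largest-component rule, making the
  crop invariants structural rather than statistical.
- **Standard pose**: after assembly the scan is snapped through
  `standard_pose_from_landmarks`, so generated scans are exactly in the
  standard frame (the generator/alignment round trip is the identity)
  and their centroid polar angles are strictly monotone along the arch —
  the oracle for the ordering step.
- **Default dentition**: 14 teeth (third molars absent), the most common
  full-arch pattern.

The mock predictor (`perturb_predictions`) converts ground truth into
network-like output: per-instance logits peaked at the true label with
peak 5/temperature (softmax probability ≈ 0.91 at temperature 1);
with probability `label_confusion_rate` the peak moves to a neighbouring
label along the arch — the realistic failure mode of a segmenter;
centroids get isotropic Gaussian noise; boundary vertices can flip to
the adjacent instance; whole instances can be dropped; spurious small
instances appear at a Poisson rate on the gingiva.

What passing tests on this bed shows: the ordering, prior, DP, crop and
metric implementations are correct, and the postprocessor's claimed
mechanism (pairwise geometry overriding confused per-tooth labels)
works. What it does not show: performance on real scanner meshes —
scanner noise, abrupt partial-scan boundaries, restorations, crowding
and natural contact points are all absent, and real segmentation
networks make correlated errors the noise model does not emulate.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 50 training arches for
the offset prior; 100 evaluation arches (1400 teeth) for end-to-end
label recovery at 0.5 mm centroid noise and 10% label confusion; 200
random cost tables per sequence length for the DP/enumeration
equivalence at T = 1..4; 1000 crops (plus 30,000 sampler draws for the
count distribution and 10,000 for the application rate); 500 samples
per pair for Gaussian parameter recovery; 100 random rigid motions for
the standardization round trip. All randomness flows from explicit
integer seeds; the generator and mock predictor are deterministic given
their configs.

Float tolerances: rotations are validated to 1e-9; the standardization
round trip is exact to ~1e-13; PLY files store float32 coordinates, so
mesh round trips are compared at 1e-4 mm.
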