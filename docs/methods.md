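# Methods

This note records the models, algorithms and numerical choices behind
budtrack, including the decisions made where the design was genuinely open.

## Tracking by intersection over area

For consecutive frames with previous objects *x*₀…*x*ₙ₁ and current objects
*y*₀…*y*ₙ₂, the cost matrix holds c(i, j) = |*yᵢ* ∩ *xⱼ*| / |*xⱼ*| — overlap
normalised by the *previous* object's area, so a full column sums to at most
one. The assignment proceeds in two steps: (1) any current object whose
best IoA over all previous objects is **strictly below** the new-object
threshold (default 0.4; a score of exactly 0.4 keeps its identity) is
declared new; (2) each remaining object claims its best predecessor unless
that predecessor overlaps some other remaining object more strongly, in
which case the loser is deferred and ends up with a new ID. Deferred
objects do **not** retry with their second-best predecessor: the rule is a
single pass, which keeps it O(n²), order-independent and equal to the
brute-force statement of the rule (verified against an independent
loop-based implementation on random frames).

Ties are broken deterministically: among equally good predecessors the
lowest previous label wins; between two current objects competing at equal
IoA the lowest current label wins. New IDs are allocated as
max-label-ever-used-in-the-output + 1, monotonically, so identities are
never recycled — a requirement for pedigree links to stay unambiguous.

## Mother–bud pairing

New objects at frame *n* are treated as buds to be assigned to cells in G1.
The cost of pairing new cell *aᵢ* with G1 cell *bⱼ* is the single-linkage
distance: the minimum Euclidean distance between their contour pixels
(contour = 8-connected boundary rim). The optimal injective assignment is
the LSAP solution, computed with `scipy.optimize.linear_sum_assignment`
(Jonker–Volgenant). With more new cells than G1 cells the rectangular LSAP
assigns the lowest-total-cost subset and an `insufficient_G1` warning is
emitted; the unassigned cells are recorded as unknown-history cells.
Pairing uses the emergence frame only — no look-ahead — matching real-time
annotation while navigating a movie.

## Annotation table and state machine

One row per (frame, cell): stage (`G1` / `S/G2/M`), generation number,
relationship (`mother` / `bud`), reciprocal `relative_ID`, emergence and
division frame indices, and a history-known flag. Invariants enforced by
the validator: unique (frame, cell); buds are in S/G2/M with a real mother
and generation 0; an S/G2/M mother has exactly one reciprocating bud at the
same frame; presence is contiguous from emergence to last frame. All edits
return violations as data, never as partial writes.

*Division annotation* at frame *n* flips mother and bud to G1 from *n*
through every later frame still marked S/G2/M for this pair; the mother's
generation increments, the bud becomes a generation-1 mother and keeps its
`relative_ID` as the pedigree link. *Undo* reverts the G1 stretch created
by a division — forward until either cell re-enters S/G2/M, backward to the
division frame. The pre-division state is restored from the pair's most
recent S/G2/M row (buds are always generation 0 with no division of their
own, so their restore values are constants); this makes
undo ∘ annotate the identity, a property the test suite checks directly and
under 1 000 randomised edit sequences. *Mother correction* requires the new
mother to be in G1 at the pairing frame and bud-free over the bud's whole
lifetime, then rewrites every frame of that lifetime; the wrong mother is
restored to its pre-assignment link.

Conventions where no rule was printed anywhere: frame-0 cells carry
generation 2 with `is_history_known = False` and emergence −1 (an arbitrary
but documented stand-in for unknown replicative age); a bud whose label
disappears mid-movie while still a bud is closed as washed away (history
flagged unknown at its last frame) and its mother returns to G1. Headless
propagation always runs to the movie end — there is no interactive notion
of a "last visited frame" here.

## Merged-object splitting

The splitter targets one constriction between two roughly convex cells.
The outer contour of the target label (largest 8-connected component,
holes ignored) is extracted at sub-pixel resolution, simplified by
Douglas–Peucker with tolerance = `epsilon_fraction` × contour arc length
(default 0.10), and the convexity defects — per hull edge, the deepest
contour point between consecutive hull vertices — are computed. Defects
shallower than 1 px are raster noise and are ignored. If **exactly two**
defects remain, the object's pixels are partitioned by the straight line
through the two defect points (pixels exactly on the chord join the larger
side; the larger side keeps the original label, the other receives
max-label + 1); any other defect count returns a no-split signal and the
frame is untouched. The cut is a partition — pixel sets are conserved
exactly, never eroded.

One deliberate design point: at the default 10% tolerance the simplified
polygon of a typical merged mother–bud mask is convex — the simplification
exists to suppress spurious separation planes from boundary irregularities,
and at that strength it also flattens the neck itself. The defect search
therefore runs on the simplified contour first and falls back to the
full-resolution contour when the simplification has removed every
concavity, with the 1-px depth floor doing the noise rejection there. This
keeps the parameter meaningful at small values while making the method
actually find the mother–bud neck (verified on 100 random two-disk
dumbbells with bud/mother area ratio ≤ 0.3: 100% exact partitions, ≥ 90%
of cases with both fragments at ≥ 70% Jaccard against the generating
disks).

## False-positive filter

Objects are removed when area < `min_size`, solidity < `min_solidity`
(solidity = object pixels / convex-hull pixels) or elongation >
`max_elongation` (major/minor axis of the second-moment ellipse, from
`skimage.measure.regionprops`). A degenerate minor axis yields elongation
+∞ so any finite cap removes single-pixel-wide lines. The filter is
idempotent and monotone in its parameters.

## Volume estimation

A single-object 2D mask is rotated (nearest-neighbour, so labels stay
binary) to put its second-moment major axis vertical, then treated as a
solid of revolution: each 1-px-high row contributes π·(w/2)² where *w* is
the number of foreground pixels in the row (pixel count rather than extent,
which is more robust to small concavities). Volumes in femtolitres are
voxels × (pixel size in µm)³, assuming isotropic pixels; the default pixel
size of 1.0 leaves everything in pixel units. Accuracy on closed forms:
rasterised disk of r = 20 px within 2% of the sphere volume, 30×11
rectangle within 3% of the cylinder, k³ scaling within 5% for k = 2, 3,
rotation of an ellipse changes the estimate by < 3%.

## Fluorescence metrics

Per frame, the background is every pixel with label 0 and the correction
subtracts the **median** background intensity from the in-mask mean; a
frame with no background pixels is an error (crop to include background).
Amount = corrected mean × area (exactly, by construction); concentration =
amount / volume in voxels (the fL-based concentration differs only by the
constant (pixel size)³ and both scales are derivable from the emitted
columns). Reported signal summaries: mean, median, max and the 0.05, 0.25,
0.5, 0.75, 0.95 quantiles. Mother+bud aggregation sums the amounts (and
volumes) of reciprocated pairs frame by frame, so totals are conserved;
trace alignment re-indexes each mother at t = 0 = its first bud's
emergence frame, excluding (and logging) cells that never bud.

## MOT metrics

Per-frame matching between ground truth and prediction is the optimal
one-to-one IoU matching keeping pairs with IoU > 0.5 (the MOT-challenge
convention). MOTA = 1 − Σ(FN + FP + IDSW)/ΣGT. An identity switch is
counted only the first time a ground-truth trajectory transitions to a
given predicted identity — each distinct (trajectory, new identity) pair
counts once, even if the trajectory later returns to its original identity
— while `switch_duration_frames` counts every frame spent matched to a
non-original identity (one permanent switch = 1 IDSW but many frames of
manual repair). Link scores: a link is two consecutive frames of one
trajectory; c = ground-truth links whose endpoints match the same predicted
identity, R and G the predicted and ground-truth link counts, precision =
c/R, recall = c/G, F = harmonic mean, with 0/0 conventions resolved to 0.

## Synthetic colonies

The generator emulates what the tracker and annotator actually consume:
elliptical cells (founder radius 8 px, aspect 1.0–1.3) growing 5% in area
per frame, a tangent bud emitted after 4 G1 frames at 25% of the mother's
area, bud-biased growth (20%/frame for attached buds, so daughters are
born at a realistic ≈ 60% of the mother's area), division a fixed 6 frames
after emergence, ±0.5 px centroid jitter, and collision resolution by
pairwise centroid repulsion (ellipse-support-radius geometry; pushes on an
attached bud move the whole mother–bud unit; 50 iterations, failure raises
an overcrowding error). Rasterisation is paint-once in label order, so
masks never overlap. All randomness flows from one seeded generator:
identical configs give bit-identical datasets.

Perturbations are constructed to be non-interacting so that injected error
counts are recovered exactly by the metrics: dropped object instances →
false negatives; 3×3 background blobs with fresh labels → false positives;
a permanent relabeling of one full-length trajectory from a random frame on
→ exactly one identity switch each (a pairwise label *swap* would count two
first-time switches under the switch-counting rule above, so the injector
uses single-trajectory reassignment); merging a mother–bud pair at one
frame produces exactly the union objects the splitter expects (and one
false negative, which is why merges are not mixed into metric-calibration
runs).

What the generator does **not** emulate: intensity texture and noise,
focus drift, segmentation errors along boundaries, cell death, irregular
cell shapes, microfluidic trap geometry. Passing tests on these fixtures
certify the algorithms' contracts (exact identity recovery, exact error
calibration, conservation laws) — not segmentation robustness on real
images.

## Problem sizes and budgets

Defaults used throughout the tests and the acceptance script: 3-founder,
30-frame, 256×256 colonies (≈ 24 cells, 336 object-frames), 200 random
frame pairs for the tracking oracle, 500 random ≤ 6×6 LSAP problems, 100
random dumbbells, 1 000 random annotation edits. These sizes exercise every
code path while keeping a full run in tens of seconds; all quantities are
invariant to scaling the colony up, and the generator accepts larger
configurations directly.

## Known limitations

- The tracker is strictly two-frame and greedy-by-rule; an object that
  loses its predecessor to a competitor is not re-matched to its
  second-best candidate (this mirrors the single-pass semantics stated for
  the method, and the brute-force oracle encodes the same reading).
- Pairing ignores future frames; a bud that drifts before its first
  annotation can pair to the wrong G1 neighbour.
- Volume estimation assumes rotational symmetry about the major axis —
  adequate for yeast, biased for strongly non-convex cells.
- The annotation state machine tolerates only two-party divisions
  (mother + one bud); symmetric division is out of scope.
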