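# Methods

## The measurement problem

Stem-related traits of mature soybean — plant height, node (pitch) number,
internodal lengths, branch number, branching angle, main-stem length and
stem curvature — drive material selection in breeding programs, but
measuring them by ruler and protractor is slow and error-prone.  When a
plant is photographed flat on a light background, an object detector can
return the pixel positions of its stem nodes; what remains is a geometry
problem: order an unordered 2-D point set into a botanically plausible
topology (one main stem, branches attached low on it) and convert the
reconstructed polylines into calibrated trait values.  `stemtrace`
implements that second half: everything downstream of the detector.

## Skeleton reconstruction

**Input.** Node centers `(y, x)` in raster coordinates (y grows downward).
All sequences are canonically ordered from the plant base upward — y
strictly descending, ties broken by x ascending — because the acquisition
protocol keeps the cotyledon node tangent to the bottom image edge.

**Single/multi classification.** Mature stems are nearly straight: the
angle at a node between its two chain neighbours is close to 180°.  For
each index `i` in the judged scope the consecutive-triplet angle
`∠(nodeᵢ, nodeᵢ₊₁, nodeᵢ₊₂)` is compared with the skip-triplet angle
`∠(nodeᵢ, nodeᵢ₊₁, nodeᵢ₊₃)`.  On one smooth chain both measure almost
the same bend; a branch node interleaved in the y-order produces a large
discrepancy.  The plant is single-stemmed iff every judged discrepancy is
below the error angle α.  The default scope is the bottom ⌈n/2⌉ triplets:
branching happens low on the stem while curvature concentrates at the top,
so judging the lower half separates the two phenomena.  α defaults to 10°,
slightly above the largest lower-half discrepancy observed on smooth
stems.  Plants with ≤ 3 nodes are single by convention.

**Corridor.** For multi-branched plants a vertical corridor is drawn
through the full image height, horizontally spanning the base and top node
columns widened by `expand_pixels` (default 30 px, enough to hold every
main-stem node of a typical plant).  Nodes inside the corridor are the
main-stem candidates; nodes outside are branch material.

**Main-stem tracing.** The two bottom-most corridor nodes seed the chain.
At each step the next three unvisited corridor nodes are scored by the
continuation angle at the chain tip (between the previous chain node and
the candidate); the candidate with the largest angle wins, except that all
candidates within α of the best compete on Euclidean distance to the tip
(nearest wins, ties to the earlier candidate).  The widened tie-break
matters: a "chord" that skips the true next node averages out the local
bend and frequently scores the top angle, so restricting the distance
tie-break to the top two angles would systematically drop genuine nodes.
Candidates farther than `max_gap_factor` (default 2.0) reference internodes
from the tip are ineligible; during main-stem tracing the reference is the
median consecutive spacing of the whole corridor array (the stem's own
internode set is not yet known).  Passed-over nodes become branch
candidates.

**Branch tracing.** Leftover nodes split into a left and a right group
relative to the corridor (in-corridor leftovers join the nearer side).
Each chain starts at the bottom-most unassigned node of its group, seeded
with the direction from its nearest main-stem node, and extends upward by
the same candidate-selection rule.  Chains need at least two nodes — an
attachment segment needs a direction — and shorter remnants are reported
as `discarded` rather than invented into branches.

**Reattachment.** Each branch returns to the main stem at the node nearest
to the branch's lowest point, among main-stem nodes at or below that point
(with one reference internode of vertical slack); ties go to the node
closer to the plant base, and if no node is eligible the globally nearest
one is used.

Every input node ends up in exactly one of main stem / a branch /
discarded; this partition is enforced by property tests on arbitrary point
clouds.

## Phenotypes

With `labelsize` = pixels per centimeter estimated from the 1-cm circular
scale marker (mean box side over all detected marker boxes):

* plant height = ‖base − top‖ of the main stem (a vertical-drop variant
  `vertical_height_cm` = |Δy| is reported alongside, matching the
  height-above-baseline reading of the trait);
* pitch number = node count per chain; internode count = one less;
* internodal lengths = consecutive node distances per chain / labelsize;
* branch number = number of branch chains (the chain count including the
  main stem is reported separately as `chain_count`);
* branching angle = angle at the attachment node between the branch's
  first node and the local main-stem direction (the next stem node above
  the attachment; extrapolated when the branch attaches at the top).  An
  alternative convention (`stem_base` mode) measures at the branch base
  toward the stem's second node and is kept for comparison;
* main-stem length = sum of main-stem internodes;
* stem curvature = plant height / main-stem length ∈ (0, 1]: 1 for a
  perfectly erect stem, smaller the more it bends (chord ≤ path by the
  triangle inequality; floating-point overshoot above 1 beyond 1e−9 is an
  error, below that it is clamped);
* morphology from the mean branching angle: convergent < 30°,
  semi-open in [30°, 60°] (boundaries assigned to the closed middle
  interval for determinism), open > 60°; `not_applicable` without
  branches.

Without a scale marker the report is produced in raw pixels and flagged
`units="px"`.

## Cotyledon node

The plant is dark on a white light-absorbing background, so foreground =
intensity ≤ threshold.  Two thresholds are computed from the 256-bin
histogram: Otsu's level (maximizing between-class variance of `{≤t}` vs
`{>t}`, smallest level on ties) and the triangle level (maximizing the
perpendicular distance from the histogram curve to the line joining the
peak with the far end of its longer tail; equal tails resolve toward the
brighter side, a flat histogram to mid-range 127).  The two dark-side
masks are intersected — each method's false foreground tends to be
disjoint, so the intersection suppresses both — and the cotyledon node is
the mean column of foreground pixels on the bottom image row.  An empty
bottom row is an error (the protocol requires tangency); multiple disjoint
bottom-row runs are flagged.  RGB converts to luma with Rec. 601 weights.
Both threshold routines are verified against exhaustive 256-way
brute-force search on a thousand random histograms.

## Detection metrics

Detections match ground truth greedily in descending confidence at IoU ≥
0.5; each ground-truth box is consumed once, unmatched detections are
false positives, unmatched ground truth false negatives.  AP is the plain
cumulative sum `Σ precision(k)·Δrecall(k)` over the ranked list, with no
11-point or all-point interpolation — comparisons with detection toolkits
that interpolate will differ slightly.  mAP is the unweighted class mean.
Counting agreement reports MAE, MSE, RMSE, the coefficient of
determination `1 − SSres/SStot` (undefined for constant truth) and
Pearson's r separately, because the two are routinely conflated under the
name "correlation coefficient".

## Synthetic plants

The generator is the package's study condition, not a convenience: its
defaults encode the geometry the method assumes.

* Main stem: 12 nodes from the bottom image row upward, internodes
  U(60, 140) px, initial tilt U(−5°, 5°) from vertical.
* Turns: at each interior node the direction bends by `180° − a` where the
  triplet angle `a` follows a normal law truncated to [160°, 180°] with
  sd 4° and **post-truncation** mean 173.3774° — the location of the
  underlying normal is solved numerically, since truncating at the stated
  mean would shift the realized average by ≈ −0.4°.  The bend side is
  random, flipped when it would push the tilt past ±15°; if neither side
  fits the chain is redrawn, which prunes ~1.4 % of turns (> 15°) and
  raises the realized battery mean by ≈ +0.06°.
* Branches: one per plant by default, four nodes, attached at a random
  main-stem node in the bottom half, departing at U(20°, 80°) from the
  local stem direction and continuing with the same turn law.
* Scale marker: a 40-px box (= 1 cm), so ground-truth phenotypes are in
  centimeters at 40 px/cm.
* Rejection sampling keeps the ground truth unambiguous: chains stay in
  the canvas (2000×1400 px), all main nodes inside the 30-px corridor and
  all branch nodes outside it, the stem top is the plant's topmost node,
  and the true attachment node must win the distance-based reattachment
  rule by at least 15 px so that a few pixels of detection noise cannot
  flip it.  The attachment-margin rejection skews accepted branch angles
  toward larger values (shallow branches hug the stem and are re-drawn
  more often).

Detector noise is modeled as isotropic Gaussian jitter of box centers
(clamped to the canvas, as a detector clips boxes to the image), uniform
misses and Poisson-count spurious boxes.  `render_plant_mask` rasterizes
the skeleton dark-on-light with the base on the bottom row, providing
images for the cotyledon pipeline.

What the generator does **not** emulate: leaves, pods and their
occlusions; perspective and lens distortion; detector confidence
correlated with appearance; bifurcated tops or broken stems; branches that
cross the corridor or each other.  Passing round-trip tests therefore
shows the reconstruction is correct under the method's stated geometric
assumptions, not that a detector's real error distribution is survivable.

## Problem sizes and measured behavior

Test batteries use 500 plants (topology recovery) and 1,000 plants (angle
calibration, `scripts/acceptance.py`); a battery of 1,000 generates in
about a second.  On 500 noiseless default-parameter plants the
reconstruction recovers the exact ground-truth topology (main-stem and
branch membership plus attachments) for 100 % of plants at the default
seeds; under 2-px jitter recovery is ≈ 95–97 % depending on the seed, the
residual failures being single mid-stem nodes where a jittered chord beats
the true continuation by more than α.  The 1,000-plant battery mean
triplet angle reproduces the configured 173.3774° within ±0.15°.

## Numerical choices

Angles via the cosine rule with the cosine clamped into [−1, 1] only when
it strays by ≤ 1e−9 (beyond that is an error).  Canonical ordering and all
tie-breaks (candidate index, lower attachment index, smallest threshold
level, first histogram peak) are total and documented, so every routine is
deterministic given its inputs and seed.  All randomness flows through
`numpy.random.Generator` seeded explicitly; batteries derive per-plant
seeds below 2³¹ from the battery seed.

## Known limitations

The α = 10° rule cannot distinguish a genuine node from a chord that wins
by more than α — visible as the few-percent jitter failures above.  The
corridor assumes the stem's horizontal wander stays within ±30 px of its
endpoint columns; strongly bowed stems violate this.  Branch chains that
re-enter the corridor, double tops, or stems broken by handling are out of
scope, as is everything upstream of detection (the CLI accepts any
VOC/JSON detection source).
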