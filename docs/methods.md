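# Methods

This note records the models and procedures implemented in `fascx`, the
conventions adopted where the underlying definitions are genuinely open,
the defaults and why they were chosen, and what the synthetic benchmark
does and does not demonstrate.

## Image model and conventions

A micrograph is a 2-D array of finite non-negative intensities with an
optional physical scale *s* in µm/px; areas convert as
`area_µm² = area_px · s²` (at the default s = 0.12 µm/px a 10 px object is
0.144 µm²). Coordinates are 0-based `(row, col)`; exported centers are
`(x, y) = (col, row)` with sub-pixel centroid precision. Orientations are
measured counter-clockwise from the image x-axis with y pointing up
(i.e. against the row axis) and folded into [0°, 180°). Objects are
8-connected, matching common particle-analysis defaults.

## Pre-processing and thresholding

Filters operate in float and preserve shape. Gaussian smoothing uses
reflective borders (the global mean is preserved to float tolerance).
The Laplace filter is the discrete 4- or 8-neighbor stencil; its
"strength" parameter is a multiplicative gain on the stencil response,
after which the response is linearly rescaled to the input range (the
original tool's parameter semantics are unpublished; gain is the simplest
reading consistent with the values 1 / 1.5 / 3 used in practice). The
Line-Gauss and cross-correlation filters are documented stand-ins with the
stated intent — ridge enhancement: an elongated Gaussian kernel,
respectively a zero-mean 1-px line template, swept over 12 orientations
with max-pooling.

Histogram thresholds are computed on a 256-bin histogram of the min–max
rescaled image regardless of bit depth, so levels live on the familiar
0–255 convention for 8-bit data; the chosen bin is mapped back to the
image's own intensity scale. Intermodes smooths the histogram with a
3-point moving average until exactly two interior modes remain and cuts at
their midpoint; a histogram with exactly two nonzero bins short-circuits
to the spike midpoint (interior-peak detection cannot represent
border-bin spikes). Otsu maximizes between-class variance over all cut
points. Triangle and Li delegate to scikit-image. Foreground is strictly
`intensity > level`. Closing (3×3 square, one iteration) and hole filling
(background regions not connected to the border) are optional,
order-fixed, and never remove foreground: a plaque fragmented by a 1-px
gap becomes one object with closing on and stays two with it off.

## Adhesion descriptors

For each object the convex hull of its pixel centers is computed. The
**main axis** is the farthest hull-vertex pair — the hull diameter, which
provably equals the maximum pairwise distance over all pixels (the unit
tests check this against an exhaustive scan). The **side axis** is the
maximum perpendicular distance of hull vertices on one side of the
main-axis line plus the maximum on the other side, i.e. the total
orthogonal extent. (The alternative reading — twice the single largest
perpendicular distance — would overestimate asymmetric objects and is not
used.) The fitted ellipse takes the two axis lengths as full axes,
`area = π/4·a·b`. Degenerate objects (singleton or collinear) get a 1-px
floor on both axes so the aspect ratio stays finite. Ties for the
farthest pair break by smallest angle, then lexicographically smallest
endpoints, making output deterministic; note that for objects with tied
diameters in different directions the reported angle is one of several
equally valid axes.

## Fiber tracing

The actin channel is thresholded, skeletonized to a 1-px medial axis, and
decomposed into branch-free arcs between skeleton "nodes" (pixels whose
8-neighbor count differs from 2, clustered by adjacency). At each
junction, incident arc ends are greedily re-paired when their outgoing
directions (averaged over the first 5 px) are within 20° of a straight
pass-through; paired arcs are concatenated into one polyline. The 20°
tolerance is configurable; it is an open parameter with no published
value. This resolves the crossing-fiber ambiguity (an 'X' of two fibers
traces as two fibers) without reproducing the prior line-sensor algorithm;
the output contract — descriptors, filters, tables, external import — is
what downstream stages consume.

Skeletonization retracts fiber tips — on oblique, tapering tips by well
over the local half-width — which would make the polyline miss an adhesion
sitting exactly at the fiber end. Each polyline end is therefore extended
by a greedy foreground walk: step to the 8-neighbor best aligned with the
running tangent (alignment floor 60°), following staircase wedges to their
apex, stopping on meeting another skeleton pixel (so an end abutting a
junction cannot run along the crossing fiber) or after 15 steps. With
this correction, end-attached adhesions are reliably reached by the
correlation walker and traced lengths sit within a few percent of the
planted geometry.

Length is the arc length of the polyline after a 5-px moving-average
smoothing with pinned endpoints: raw 8-connected pixel chains overestimate
oblique lines by up to ~8% (chain-code bias), while smoothing keeps errors
within ~2.5% on synthetic fibers and preserves `length ≥ chord`. Width is
twice the mean distance-transform value along the skeleton; curvature is
the mean absolute tangent-angle change per px of the smoothed polyline
(rad/px). Filters (min/max length, max curvature, max width, cell-area
mask) apply after tracing; results sort by length descending with ids
assigned in that order.

Known limitation: skeletonization is not exactly equivariant under 90°
rotation on thick fibers — endpoints can shift by ~2 px, which on a 60 px
fiber exceeds 2% of length. Orientation and count are rotation-stable;
exact length equivariance holds on already-thin input.

## Correlation

Fibers are processed longest-first, adhesions largest-first (the result is
order-independent; a test permutes inputs). Candidates are adhesions with
`main_axis < fiber length` — an adhesion is assumed never to outsize its
fiber. The adhesion's representation (raw pixels, convex hull, or fitted
ellipse) is dilated by the square neighborhood of half-width *n* and
tested against the fiber polyline points, walking from both ends inward
(an early-exit order; the pair set is exhaustive). Because the
neighborhood is a square, dilation is Chebyshev: pixel sets use a square
structuring element and convex polygons an exact Minkowski sum with the
square (convex hull of the four corner-translates), which makes the
nesting guarantee `pairs(pixels) ⊆ pairs(hull)` exact. Each (fiber,
adhesion) pair is recorded at most once. Default representation/neighborhood
is ellipse / 1. Classes follow association counts (0/1/≥2): NAAF/SAAF/MAAF
for fibers, AANF/AASF/AAMF for adhesions — the transverse-arc / dorsal /
ventral proxy taxonomy. A fiber is *verified* with ≥1 associated adhesion
in `single` mode, ≥2 in `multiple` mode.

## Evaluation and the similarity coefficient

Object matching is many-to-many: a (truth, eval) object pair matches when
its pixel overlap reaches `min_overlap_pct` (default 1%) of the reference
size. The reference is the **smaller** of the two objects by default —
the symmetric choice; `truth` or `eval` bases are available. Truth objects
split over several eval objects increment `multi_one_to_n`; eval objects
spanning several truth objects increment `multi_n_to_one`. Optional
pre-thickening dilates both masks (the whole mask, not only outlines — the
simpler reading, flag-controlled). Pixel-wise TP/FP/FN counts are computed
independently of objects and partition the union of foregrounds exactly;
swapping the masks swaps FP and FN.

`SC = found / (missed + fp)` with areas taken from the truth mask's
object sizes (found/missed) and the eval mask's unmatched object sizes
(fp). `SC = 0` when nothing is found and `inf` when the denominator is
zero with nonzero found area — a sentinel rather than an error so batch
tables stay rectangular; pooled variants should sum areas before dividing.

`threshold_finder` scans all 256 candidate levels of the pooled rescaled
range for the level maximizing pixel F1 against the annotated masks (F1 is
the combining rule for the found/false-positive/false-negative rates, which
are reported at that level), and reports per method the level it would
pick without mask input plus the F1 that level achieves, ranking methods
by it.

## Synthetic benchmark

The generator emulates a ventral-plane two-channel field of view:
elliptical adhesion blobs (paxillin analog) and gently curved bright
fibers (phalloidin analog) on a dark background. Defaults, chosen once as
realistic for this kind of data and fixed: 384×384 px at 0.12 µm/px; 6
fibers of 60–150 px (7–18 µm) with half-width 1 px; 12 adhesions with
main axes 6–13 px (areas roughly 0.3–1.3 µm²) and peak amplitudes 40–170
over background 20 (so dim adhesions exist); one third of fibers carry
adhesions at both ends, one third at one end (ventral/dorsal/arc mix);
attached adhesions sit within 2 px of their fiber endpoint, aligned with
the local tangent. Rejection sampling enforces a 20 px Chebyshev clearance
between fibers and 16 px between free adhesions and any fiber, so the
planted attachment map is unambiguous and exact class-count recovery is a
well-defined target. Defocus analogs are Gaussian blurs of σ = 0 / 2 / 4 px
for the in-focus / mild / severe conditions (a fixture convention — the
pinhole-to-σ mapping is not physically derived); detection noise is
additive Gaussian. Scenes are bit-reproducible from the seed.

What passing these tests shows: the geometry, pairing, bookkeeping and
classification code paths are exact (they match independent brute-force
oracles), and the pipeline's qualitative response to defocus — similarity
to the reference mask degrades monotonically with blur under one fixed
routine — has the expected direction. What it does not show: performance
on real micrographs, which have textured background, intensity gradients,
overlapping adhesions, fiber networks denser than the planted clearance,
and point-spread physics none of which the generator models.

## Fixed analysis routines in the acceptance script

Noiseless recovery and oracle scenes use a manual threshold of 32 — just
above the generator's background of 20 with zero noise — with the 10–5000
px object window, pixel representation, neighborhood 2, and a 20 px
minimum fiber length. The "unoptimized" routine for the blur trend is no
filters plus one fixed manual level (70) applied unchanged to all three
blur conditions, so dim adhesions are missed increasingly as blur lowers
peak intensities; this mirrors applying a single fixed-level routine
across datasets of varying quality. Problem sizes (3 recovery scenes, 20
oracle scenes at 200×200, 10 scenes per blur level) keep the whole script
within seconds while exercising every stage.

## Known limitations

- The Line-Gauss and cross-correlation filters are intent-level stand-ins,
  not reimplementations of the original (unpublished) kernels.
- The fitted ellipse need not contain the whole pixel set for concave
  objects; only the convex hull carries a containment guarantee.
- The tracer merges at most one continuation per arc end; a fiber crossing
  a dense junction of more than four arms may fragment.
- Curvature is a smoothed polygonal estimate; it under-reports true
  curvature at wavelengths below the 5-px window.
- `threshold_finder` assumes one global level describes all supplied
  images (they are pooled); per-image optima are not reported.
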