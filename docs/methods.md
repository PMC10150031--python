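# Methods

## Overlap reconstruction

The reconstruction assumes the scene contains exactly two elongated
objects, one partially covering the other, and that instance masks are
pixel-disjoint (each pixel belongs to at most one instance). Occlusion is
detected purely topologically: the covered object's visible mask has ≥ 2
8-connected components, the covering object's has 1. 8-connectivity is
used so that thin diagonal necks do not spuriously split an instance.

The hidden region is modelled as the quadrilateral between the two largest
fragments of the occluded mask:

* **Maximum inscribed circle.** For each fragment, the exact Euclidean
  distance transform is computed on the fragment padded with a one-pixel
  background ring, so the image border counts as background and the circle
  can never extend past the canvas. The center is the arg-max pixel (ties
  broken by smallest row, then smallest column, for determinism); the
  radius is that maximum distance. The phrase "smallest inscribed circle"
  sometimes used for this construction is read as the *maximum* inscribed
  circle: a literally smallest inscribed circle would have radius 0.
* **External tangents.** With unit vector `u` from center 1 to center 2
  and center distance `d`, the two tangent-line unit normals solve
  `n·u = (r2 − r1)/d` with opposite perpendicular components; tangent
  points are `c_i − r_i·n`. The construction requires `d > |r1 − r2|`;
  for inscribed circles of two disjoint fragments this always holds
  (`d ≥ r1` since the other fragment is background to the first), so the
  convex-hull fallback below is purely defensive.
* **Quad closure.** The region is closed by the chords joining the two
  tangent points on each circle (not by arcs), yielding a simple,
  counter-clockwise quad. Chord closure slightly under-covers near the
  circles and the tangent width `2r` slightly over-covers a ribbon whose
  half-width is below `r`; on the canonical perpendicular crossing these
  effects net to about +5% of the true hidden area.
* **Rasterization.** A pixel is inside the quad iff its integer-coordinate
  center lies inside or on the polygon boundary (boundary-inclusive
  even–odd rule, via exact point-in-polygon tests restricted to the
  bounding box). Zero-area polygons rasterize to an empty mask.
* **CD.** The fitted mask is intersected with the covering instance's
  mask and counted. Because instance masks are disjoint, the occluded
  instance's own visible pixels can never be double-counted. CD is not
  clipped when CAR would exceed 1: over-estimation is information the
  report should retain.

Edge behaviour: if neither instance is occluded the hidden area is 0 by
construction (valid output, not an error). If both are occluded — e.g.
mutual interleaving — each is processed against the other and the CDs
summed, with a warning, since the two-fragment geometry is then less
reliable. Samples with three or more stacked objects are out of scope.

## Metrics

`AAR = AD/(Area_1+Area_2)` and `CAR = (AD+CD)/(Area_1+Area_2)` are
computed from raw values; rounding (half-up, as report tables print) is
applied only at display time. "Negative optimization" is formalized as
`|CAR − 1| > |AAR − 1|`; the phrase is used in the field without a formula
and CAR may legitimately exceed 1, so the distance-to-1 comparison is the
faithful reading. Summaries report n, the two averages, the
min/mean/max correction increase `CAR − AAR`, and the
negative-optimization count; `CAR − AAR = CD/(Area_1+Area_2)` exactly.

The bundled 24-sample reference benchmark prints per-sample ratios to 3
decimals only; per-row AD and CD are reconstructed from them
(`AD = AAR·ΣArea`, `CD = (CAR−AAR)·ΣArea`), exact up to that printed
rounding. The benchmark's summary text elsewhere quotes a worst AAR of
0.648 for sample PG-4 where the table prints 0.684, and a mean correction
increase of 8.8% where the tabulated rows yield 8.7%; the package computes
from the tabulated values and leaves the discrepancies as they are.

## Preprocessing

Raw photographs are mostly dark background. Foreground extraction uses
Otsu's threshold on Rec.601 luminance — standard, parameter-free, and
checkable against an exhaustive 256-level between-class-variance scan —
keeping the brighter class, then removes connected specks smaller than
`min_blob_px` (default 25 px: sensor noise is smaller, thin shred tips are
larger; configurable). The crop is the axis-aligned square around the
minimum enclosing circle of the foreground pixel centers plus a `pad`
(default 10 px, preserving contour context), rounded outward and clamped,
so no foreground pixel is lost. The enclosing circle itself is computed
with Welzl's move-to-front algorithm after a convex-hull prefilter, giving
expected linear time in the hull size; a uniform image yields an empty
mask and a warning rather than an error.

## Synthetic generator

A ribbon is a quadratic Bézier spine, sampled densely (< 0.5 px spacing)
and thickened to all pixels within `width/2` of the continuous polyline —
an exact disc dilation, so a straight ribbon's area matches the stadium
formula `L·w + π(w/2)²` and spines on half-integer coordinates make even
widths exact. Defaults: 192 × 256 px canvas, width 14–22 px, mild
curvature (middle control point displaced up to 15% of the canvas). These
emulate elongated, gently curved shreds at a desk-scale image size; they
do not emulate texture, colour, self-winding, or ≥ 3-way stacking, so
passing tests demonstrate geometric correctness of the reconstruction, not
robustness to real segmentation noise.

Regimes: *inter-overlapped* draws one canvas-spanning horizontal ribbon
(on top) and one vertical ribbon, resampling until they intersect and the
covered ribbon shows ≥ 2 visible fragments; *adhesion* draws two roughly
parallel ribbons and slides the second vertically to the placement with
the smallest nonzero intersection not exceeding 5% of the smaller ribbon's
area; *none* places two ribbons in disjoint halves. Each benchmark sample
uses its own stream keyed by `(seed, index)`, so sample `i` is identical
regardless of how many samples are requested. Ground-truth identities
(`AD = Area_1 + Area_2 − overlap`; substituting the true overlap for CD
gives CAR = 1 exactly) are asserted in tests.

Problem sizes used by the shipped benchmark and acceptance script — 100
synthetic samples on the default canvas, 50 random blobs for the
inscribed-circle oracle, 1000 circle pairs for tangency residuals, point
sets up to 60 for the O(n³) enclosing-circle oracle — were chosen so the
whole evaluation runs in well under a minute on one core while keeping the
oracle comparisons exhaustive at their scale.

## Anchors and pyramid topology

Anchors are parameterized area-preservingly: size `s` and ratio `q = h/w`
give `w = s/√q`, `h = s·√q`, so every anchor's area is exactly `s²` — the
reading consistent with describing a stride-4 cell as covering 16 px. The
two bundled sets are the stock `[128, 256, 512] × [0.5, 1, 2]` (9 per
position) and the small-object `[32, 64, 128, 256] × [0.5, 1, 1.5, 2]`
(16 per position); where source descriptions swap the labels "sizes" and
"aspect ratios" for these two lists, the dimensionally coherent assignment
is used. Coverage is measured shape-only (best centered IoU over the
anchor set), which isolates the parameterization from placement effects.

The fusion topology is emitted as data, not as a network. The U-shaped
variant is modelled as two passes to keep the graph acyclic: top-down
intermediates `T2..T6` (laterals from the DenseNet-121 dense-block taps
`C2..C5` at strides 4/8/16/32, top-down upsampling, `T6` a stride-2
subsample of `T5`), then bottom-up outputs `P2..P6` where each of `P3..P6`
fuses its top-down map with a 3×3/stride-2 edge from the previous final
`P` level, and `C3` feeds `P3` through an extra 3×3 lateral (a switch
extends this to `C2 → P2`). Per-level channel widths beyond the 256
default and any `C`-lateral into deeper levels are unspecified upstream
and left as overrides. Validation checks operator vocabulary, stride
doubling `P2=4 … P6=64`, acyclicity, and lossless JSON round-tripping.

## Known limitations

* The quad model assumes the hidden region is roughly a ruled band between
  two fragments; strongly curved hidden sections are under-covered (the
  quad cuts the corner) and wide coverings over narrow ribbons are
  over-covered (tangent width exceeds ribbon width).
* Only the two largest fragments participate; additional small fragments
  contribute area but not geometry.
* CD inherits any segmentation error in the covering mask, since the fit
  is clipped to it.
* The CLI's `cot --sample` directory mode enforces disjointness by letting
  the first-listed mask win contested pixels, matching the annotation
  convention; masks that overlap heavily therefore lose area from the
  second instance.
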