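# Methods

## Input model and conventions

The pipeline operates on segmented images: 2-D integer matrices with at most
three category codes. For binary input, 1 is foreground; for three-class
input (e.g. empty / non-malignant / malignant tissue) the user names the
foreground categories and everything else becomes background, so
non-foreground classes enclosed by tissue turn into holes, which the
topological features then count. When decoding PNG/GIF rasters without an
explicit mapping, distinct pixel values are sorted ascending and mapped to
categories 0, 1, 2 — the darkest value is background. More than three
distinct values is an error, not a warning: silently merging classes would
corrupt every downstream area.

All modules share one coordinate convention: 0-based (row, col), origin at
the top-left, rows increasing downward. Orientation-sensitive quantities
(counterclockwise order, turning angles, box and axis angles) are measured in
the right-handed frame (x, y) = (col, −row), so a positively oriented simple
boundary has turning angles summing to +2π and angles are reported in
degrees in [0, 180).

## Region labelling

Foreground regions are maximal 4-connected components: two pixels belong to
the same ROI only if a chain of edge-adjacent foreground pixels joins them.
Diagonal contact does not merge regions; dually, background (hole)
connectivity is 8-connected. Components are labelled 1..k from largest to
smallest pixel count; equal areas are ordered by the raster-scan position of
each region's topmost-leftmost pixel, which makes labels reproducible.

Two size filters are offered as alternatives (never composed): a minimum net
area, or keeping the n largest regions. The quarter-rule quality-control
filter removes regions whose net area is *strictly* less than one fourth of
the image's largest region; a region at exactly one quarter survives. The QC
step is exposed separately from the size filters so either order can be
scripted explicitly; the slide-aggregation workflow applies QC first, then
averages.

## Shape representations

Per region, six representations are derived from the tightly cropped mask:

* **Boundary chain.** Moore-neighbour tracing from the topmost-leftmost
  pixel, counterclockwise, with Jacob's stopping criterion (terminate when
  the trace re-enters the start pixel about to repeat its first move). The
  boundary is the chain of *pixel centers*, not the inter-pixel crack
  boundary: chain codes and radial lengths are classically defined on pixel
  centers. Thin structures legitimately revisit pixels (a 1×3 bar yields a
  4-edge out-and-back chain); a single-pixel region yields a degenerate
  1-vertex chain.
* **Freeman chain code.** One code per edge, cyclic, with
  0=(+1,0), 1=(+1,−1), 2=(0,−1), 3=(−1,−1), 4=(−1,0), 5=(−1,+1), 6=(0,+1),
  7=(+1,+1) in (Δcol, Δrow).
* **Curvature code.** Turning angle per vertex:
  θ = wrap(code_{i+1} − code_i) · π/4 mapped into (−π, π], computed
  cyclically; on every traced simple boundary the angles sum to +2π (the
  test suite asserts this to 1e−9).
* **Radial lengths.** Distances from the region centroid (mean coordinate of
  all foreground pixels — robust to boundary revisits) to each chain vertex,
  normalized by their maximum.
* **Convex hull.** Andrew monotone chain over the chain vertices with exact
  integer cross products; hull area by the shoelace formula, hull perimeter
  as the Euclidean edge sum. (Shapely's hull serves as an independent oracle
  in the tests, never as the implementation.)
* **Minimum-area bounding box.** Rotating calipers over hull edges (the
  optimal rectangle has a side collinear with a hull edge). Side lengths are
  pixel-footprint extents — caliper span of the centers plus one — so an
  axis-aligned w×h block reports exactly w×h. Coordinates are centered on
  the first hull vertex before projecting, making the box exactly
  translation invariant. Area ties break toward the smaller angle.

Regions smaller than the degeneracy threshold (default 5 px) skip radial,
hull and box construction; their geometric and boundary features are
reported missing (NaN) while the two topological counts are still computed.

## Feature definitions

Nineteen geometric features, with A_net the foreground pixel count, A_fill
the count after hole filling (scipy's binary_fill_holes), and P the
perimeter:

* **Perimeter** uses the Vossepoel–Smeulders corrected chain length
  0.980·n_cardinal + 1.406·n_diagonal − 0.091·n_corner (corners = direction
  changes). The raw 1/√2 chain length overestimates smooth contours by ~5%
  on average over orientations, which would bias circularity of a disk to
  ~0.91 forever; the corrected estimator converges to the true contour
  length (disk circularity 1.04 at r=25, 1.007 at r=100, halving with each
  doubling of r). Raw per-edge lengths are still used where a local length
  is needed (curvature, arc-length weights).
* **Circularity** = 4π·A_fill/P²; filled area by default because holes are
  counted separately by the topological block and should not make a region
  less circular (configurable to net area).
* **Fibre length/width** solve the ribbon model P = 2(L+W), A_fill = L·W:
  L = (P + √max(0, P² − 16·A_fill))/4, W = A_fill/L.
* **Convex area** converts the hull's shoelace area to the pixel-count scale
  by Pick's theorem (A + B/2 + 1, B = lattice points on the hull boundary);
  without this the hull polygon through pixel centers undercounts by the
  half-pixel boundary ring and solidity exceeds 1 for convex regions. With
  it, solidity = A_fill/A_convex ≤ 1 holds exactly.
* **Axis lengths** are 4√(eigenvalues) of the foreground-pixel coordinate
  covariance (population normalization), i.e. the axes of the
  moment-equivalent ellipse: a solid ellipse with semi-axes a, b reports 2a
  and 2b within discretization error. Eccentricity = √(1 − (minor/major)²);
  roundness = 4·A_fill/(π·major²); the axis angle is the principal
  eigenvector's direction.
* **Elongation** = box length/width; **bounding box area** from the calipers
  box; **thickness** = twice the maximum of the Euclidean distance transform
  of the filled mask (twice the inradius); **curl** = major axis
  length/fibre length, capped at 1 (a straight ribbon has curl 1; bending
  lowers it).

Eight boundary features. Curvature at vertex i is κ_i = θ_i/s_i with s_i the
incoming edge length; bending energy = mean κ², total absolute curvature =
mean |κ|. The radial statistics (mean, SD, 10-bin entropy with natural log
and empty bins skipped, area ratio = mean-normalized positive excess mass,
and the normalized moment classifier √(m₂ − m₁²)/m₁ on raw radii — a
coefficient of variation) are **arc-length weighted**: each vertex carries
half of its two adjacent edge lengths. Chain vertices are denser along
cardinal runs than diagonal ones (a diagonal step covers √2 but adds one
vertex), so unweighted statistics drift 6–7% between 0° and 45°
rasterizations of the same ellipse; weighting removes the bias (worst drift
~2%) while keeping the descriptor parameter-free — no resampling count to
choose. The zero-crossing count stays a plain cyclic count of sign changes
of r_i − mean (exact zeros dropped). Note that on near-circular digital
shapes this count is dominated by raster-scale oscillation of the radial
profile (a radius-100 disk shows ~280 crossings over ~800 vertices); it
discriminates spiky from smooth shapes (a 5-point star gives exactly 10) but
its absolute value on smooth shapes is resolution-dependent.

Two topological features: hole count = 8-connected background components not
reachable from the border (the connectivity dual of 4-connected foreground),
and protrusion count = convexity defects — chain segments between
consecutive hull vertices — whose maximum perpendicular depth below the hull
edge is at least the threshold (default 2 px; a 5-point star yields exactly
5).

Tunables (`FeatureConfig` / estimator parameters): `entropy_bins` (10),
`protrusion_depth_threshold` (2.0 px), `degenerate_area_threshold` (5 px),
`circularity_area_choice` ("filled" | "net").

## Slide-level aggregation

`aggregate_slide` averages each feature across a slide's regions, skipping
missing values (a degenerate region contributes only its topological
counts), and records the number of contributing regions. With the
quarter-rule QC enabled, filtering precedes averaging.

## Synthetic fixtures

`synthetic_shapes` rasterizes disks, annuli, rectangles, ellipses and
alternating-radius stars by testing pixel centers against the analytic
inequality — no anti-aliasing — so measured areas obey exact
perimeter-order discretization bounds and identical parameters give
byte-identical rasters. Scenes composite primitives in painter's order into
category codes (a category-0 primitive punches a hole), and a seeded
generator places non-overlapping random disks reproducibly.

What the fixtures do *not* emulate: segmentation noise on boundaries,
anisotropic resolution, texture, or the size/irregularity distributions of
real tumors. Passing tests therefore demonstrate geometric correctness of
the measurements, not robustness to segmentation error in real slides.

## Numerical choices and limitations

* Hull construction and orientation tests use exact integer arithmetic;
  caliper projections are float but translation-exact by centering.
* The brute-force oracles (flood fill, 0.1° box sweep, border-reachability
  hole count) are independent re-implementations used only in tests and in
  the acceptance script.
* Test problem sizes: radii 25–200 px, canvases up to 400², 200 random
  32×32 labelling images — large enough that discretization error is below
  the asserted tolerances, small enough that the whole suite runs in
  seconds.
* Features are not scale-normalized: area-like features grow with
  resolution by design; only the dimensionless subset (circularity,
  roundness, convexity, solidity, eccentricity, elongation, radial mean/SD,
  entropy, area ratio, normalized moment classifier, curl) is comparable
  across magnifications.
* Regions touching the image border are measured as-is; their boundary
  along the border is treated as a real edge.
* Exactly one foreground connectivity (4) and hole connectivity (8) are
  supported; watershed splitting of touching regions is out of scope.
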