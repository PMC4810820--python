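# Methods

This note records the model behind each pipeline stage, the defaults and why
they are what they are, what the synthetic generator does and does not
emulate, and the numerical choices that were genuinely open.

## Imaging model and height recovery

The pipeline assumes reflected-light z-stacks of light objects on a black
background: slice `k` is the focal plane at height `k·Z` above the slide,
slice 0 lowest. Defaults mirror a 5× compound-microscope setup: `s = 31`
slices, `Z = 31.1 µm` (the depth of focus of the objective, and therefore
the depth resolution of everything downstream), and a lateral calibration
of `0.975 µm/px`, resampled to exactly 1 µm pixels before mesh extraction
so that volumes are pixel-height sums.

The focus operator is plain local intensity variance in a `kernel × kernel`
window (default 11), the classic shape-from-focus choice: it is
scale-covariant (height maps are invariant to uniform intensity scaling),
cheap, and monotone in defocus under any blur model that only widens the
point spread. The per-pixel argmax over slices is stored 8-bit:

    encode:  H = round(255·b/(s−1))
    decode:  height = round(H·(s−1)/255)·Z

with **round-half-away-from-zero everywhere** (banker's rounding would make
the encoding parity-dependent). The pair round-trips exactly for every
slice index; the test suite checks this exhaustively for s = 31 and
property-tests it for other slice counts. Heights are consequently
quantized to multiples of `Z`: a surface point is recovered at the nearest
focal plane, so ±Z/2 is the irreducible height error.

Known limitation: within ~one focus-window of the footprint rim, and
wherever the surface drops by more than ~`Z` across a single window, the
window mixes focus information from different heights (and from the
background edge) and the argmax can be off by a slice or two. This is the
same pathology that leaves "a rim of background" on real meshes; the
z-level pruning stage exists to cut it off. Accuracy guarantees are
therefore stated for the resolvable interior.

## Cleaning

*Background and aperture.* The 2D outline of the focused (EDF) image —
threshold, largest 8-connected component, hole filling — is multiplied
element-wise against the height map. Extracting the outline a second time
with hole filling skipped leaves interior holes (apertures) out of the
footprint; `filled AND NOT unfilled` is the aperture mask. Aperture pixels
are excluded from the initial mesh and re-inserted after cleaning at the
object's lowest retained height, terminating the aperture in a flat floor
roughly mid-specimen.

*Quartile filter.* For each valid pixel, the first/third quartiles of the
valid pixels in the surrounding `n × n` window (default 45) are computed;
values outside `[Q1, Q3]` are replaced with the window mean. Choices the
description leaves open, fixed here:

- **One pass over a frozen copy** — replacements never feed back into later
  windows. This makes the filter order-independent and deterministic.
- **Invalid/background pixels are excluded** from window statistics;
  including zeros would drag the quartiles toward the background at object
  edges and shave the rim.
- **Quartile estimator:** linear interpolation between order statistics
  (the `numpy.percentile` default); tested against a brute-force sorting
  oracle on random windows.
- Windows are truncated at the image border.

The filter is aggressive by construction (roughly half of a noisy surface
lies outside its local IQR) — that is what lets it delete multi-pixel spike
artifacts and smooth the mesh at the same time. It can never produce a
value outside the pre-filter min/max, since replacements are window means.
The implementation exploits the small number of distinct z-levels (≤ s
before filtering) to compute all windowed quartiles with one integral-image
pass per level, so the 45×45 default costs the same as a 3×3 one.

*Pruning.* After filtering, heights are re-quantized to the nearest z-level
and levels holding < 1% of the object's pixels are deleted; then the
bottom-most remaining level is dropped (it usually holds the residual
background rim). The 1% rule is applied first, the bottom-drop second, so
"bottom-most" refers to the already-thinned object.

## Mesh and size

One vertex per valid pixel (no downsampling); every 2×2 block of mutually
valid pixels becomes two triangles split along the NW–SE diagonal — a
heightfield grid admits this exact, deterministic triangulation, so no
point-cloud meshing heuristics are involved. Export: ASCII OBJ (1-based
faces), OFF, and a raw x/y/z CSV, written at full float64 precision
(`%.17g`) so write→read round-trips are bit-exact.

Top-hull measures are exact given the grid: `V_top = Σ heights·px²`,
`SA_top = Σ` triangle areas. (A literal per-pixel "area sum" would reduce
to the 2D outline area and carry no relief information, so the triangulated
area is used for `SA_top`.)

Back-half estimators, from outline area `A2D`, perimeter `P2D`, axes, and
base height `H` (the lowest retained level):

- cylinder: `V = A2D·H`, `SA = P2D·H + A2D` (includes one flat cap, as the
  formula is conventionally written);
- cone: `V = A2D·H/3` — exactly one third of the cylinder, which the tests
  assert to 1e-12 — and lateral surface from a triangle fan over 100
  arc-length-equal perimeter points to the apex above the centroid (the
  midpoint-rule limit of summing the trapezium strips; < 0.5% from the
  closed form for a right circular cone at n = 100);
- spheroidal dome: half-ellipsoid with semi-axes `(major/2, minor/2, H)` —
  `V = ½·(4/3)π·s_x·s_y·s_z` — and Thomsen's surface approximation with
  `k = 1.6`, which is exact when the three semi-axes coincide (the test
  asserts 2πr² to 1e-10 relative). Lateral-only; no base annulus.

The uncertainty statistic is `U = 100·(E_cyl − E_con)/E_dom` per volume and
per area, computed on completed-object estimates (top + back). `U_vol ≥ 0`
always (the one-third identity); `U_sa` may be negative. The sign
convention (signed, not absolute) is this package's choice.

Assemblage censuses use the dome-based volume, Gaussian KDEs with Silverman
bandwidth per site, and report quantile tables plus pairwise
fold-differences of a chosen quantile.

## 2D outline measurements

Area is the pixel count; axes come from the
equal-second-moments ellipse; eccentricity from those axes. Two quantities
the field leaves underdetermined are fixed as: `aspect_ratio =
minor/major`, `rugosity = perimeter / convex-hull perimeter` — both
dimensionless, bounded and standard.

Perimeter is measured on the marching-squares contour smoothed by four
iterations of 1-2-1 local averaging. The natural-looking alternative — the
8-neighbour pixel chain with √2 diagonal weights — overestimates smooth
perimeters by ~5-6% (its segment directions are quantized to 45°; a
digitized disc of r = 100 px measures +5.5%), and Crofton(4) underestimates
axis-aligned rectangles by a similar margin. The smoothed contour is within
~1% on discs, squares and ellipses, and since the convex hull of a closed
polygon never has greater perimeter than the polygon, rugosity ≥ 1 holds by
construction. The same contour, resampled to n arc-length-equal points
(default 100) and ordered by increasing polar angle from 0, feeds the cone
fan; for non-star-convex outlines the angle cannot be monotone and a
warning is raised while keeping arc-length order.

## Segmentation

Binary mask `EDF > threshold` (default 0.18 — in practice re-tuned per
slide, e.g. 0.14-0.20, to absorb glare and illumination differences; the
absolute value is unimportant downstream), 8-connected labelling
(4-connectivity would split thin diagonal bridges), and a size filter
keeping objects whose bounding-box **maximum dimension** is 125-2000 µm —
"width" is deliberately read as the rotation-insensitive larger box side.
Coordinates are 0-based, row-major, half-open throughout.

## Synthetic data

The generator renders analytic shapes — hemispheroids, spheres resting on
the slide plane (the sphere's visible hull rises to a full diameter, the
worst case for one-viewpoint height recovery), elliptical cones, blocks and
terraced blocks — with closed-form ground-truth volumes and
numerically-integrated surface areas (grid integrals agree with the closed
forms to 0.5% at 1 µm pixels).

Optics: the in-focus image is the object's base intensity (default 0.6)
modulated by a fixed multiplicative speckle texture (amplitude 0.15,
correlation length 1 px). The texture is not optional decoration: a
perfectly uniform surface carries no focus signal, so some fine-scale
albedo structure — standing in for the wall texture and pores of real
shells — is a precondition of shape-from-focus. Each slice blurs that image
with an isotropic Gaussian of `σ = blur_coefficient·|h − k·Z|` px (default
0.05 px/µm: ~1.6 px one slice out of focus, enough to separate adjacent
slices' focus scores cleanly), implemented with a 15-level blur bank and
per-pixel linear interpolation in σ. Additive Gaussian noise (default sd
0.01) follows; background pixels are exactly 0 before noise. Everything is
driven by one seeded generator, so equal seeds give bit-identical stacks.
Optional "smear" artifacts — patches of slice-independent constant blur —
reproduce the focus-stacking pathology in which part of an object is
sharp on no slice and the recovered heights there are garbage.

What the generator does **not** emulate: physically accurate point-spread
functions, refraction through calcite shells, inter-frame brightness drift,
tiling seams, glare, or specimen tilt. Passing tests therefore demonstrate
that the *reconstruction chain* is correct under a faithful geometric model
of acquisition, not that any particular microscope is characterized.

## Tree comparison

Species-mean matrices use arithmetic means in first-appearance order.
Jaccard distances one-hot encode the categorical traits (one indicator per
trait level — the 15-species table carries 3 symbiont, 5 depth and 4 range
levels) and use `1 − |A∩B|/|A∪B|`; the original trait coding behind the
published ecological distances is not recorded anywhere, so exact
reproduction of those numbers is not claimed.

Clustering: the five standard linkages via the Lance–Williams recurrences
(McQuitty = WPGMA). "Ward" defaults to the **classic unsquared-distance**
variant (the behaviour of `hclust`'s "ward" in the R versions contemporary
with this pipeline's original environment), obtained by running the
squared-distance machinery on √d and squaring the merge heights — an exact
algebraic identity, verified against a naive agglomeration oracle on all
matrix sizes ≤ 5 for every linkage. `ward_variant="d2"` selects the
squared-distance convention.

Majority-rule consensus keeps rooted clades present in **strictly more**
than `p` of the input dendrograms (ties at exactly 50% drop out); the
result may be multifurcating. Consensus is computed on the rooted
dendrograms — the natural reading for clustering trees — and merge heights
are discarded before any topology comparison.

Path difference: each tree becomes a vector of leaf-pair path lengths in
edge counts on the unrooted topology (the dendrogram root, a degree-2
node, is spliced out); the metric is the Euclidean distance between
vectors. It is defined only for binary trees, so every polytomy is resolved
uniformly at random and the mean over 2000 replicates is reported (one
replicate when both trees are binary). Verified against a brute-force
shortest-path oracle on all 15 labelled 5-leaf unrooted topologies.

## Problem sizes used in tests and the acceptance script

The sphere accuracy check uses seven spheres at diameters 300-900 µm on
~1 µm grids (stacks up to 980² × 31), the hemisphere end-to-end check a
600 µm hemisphere — sizes chosen to match the real specimen range while
keeping a full run in tens of seconds. The quartile-filter spike study uses
100 seeded trials on a 121² dome. All randomness is seeded; the acceptance
script derives per-object seeds from its `--seed` argument.
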