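# Methods

## Scope and model

`rodmorph` measures rod-shaped cells in 2D masks. Its unit of analysis is a
connected foreground component of a refined binary mask; its outputs are
per-cell area, length and width in physical units, two segmentation-accuracy
surfaces (pixel IOU and centroid detection matching), and distribution
statistics over measurement tables. Segmentation itself is delegated to a
*backend* — any callable mapping an 8-bit image to an 8-bit confidence mask
(bright = cell). A deterministic classical backend ships with the package;
neural backends plug in as callables, and no training code or weights are
included.

## Synthetic scene generator

Real micrograph collections are large, binary, and carry no pixel-exact
ground truth, so the package includes a generator whose scenes *are* their
own ground truth.

A cell is a 2D stadium: the set of points within distance W/2 of a central
axis segment of length L−W. A pixel belongs to the cell iff its center lies
in that set (pixel-center point convention, matching the morphometry below).
The stadium is the natural idealization of a rod cell and gives closed-form
oracles: area (L−W)W + π(W/2)², maximum Feret diameter L, minimum W.

Defaults emulate a fission-yeast monolayer: lengths uniform on 7–20 µm,
widths uniform on 3–5 µm (length ≥ width enforced by redrawing), orientation
uniform on [0°, 180°), calibration 0.1258125 µm/px (a 1920-px frame spanning
241.56 µm), cells dark (level 90) on a bright background (level 200) with
additive Gaussian noise of sd 4 clipped to [0, 255]. Cells are placed by
rejection sampling, wholly inside the frame (a flag permits border clipping),
with boundary-to-boundary separation ≥ `min_gap_px` (default 5 px) computed
as segment–segment distance minus the two radii. Placement failure after a
per-cell attempt cap raises an error naming how many cells were placed. All
draws come from one `numpy` generator seeded from the spec, in a fixed order
(per cell: length, width, orientation, center row, center col; then one
noise field), so identical specs reproduce bit-identical scenes.

What the generator does **not** emulate: point-spread blur, defocus and the
bright halo of real brightfield optics, uneven illumination, septation and
branching morphologies, cell debris, and overlapping (non-monolayer) growth.
Tests passing on synthetic scenes therefore validate the *computational
chain* — thresholding, morphology, measurement, evaluation, statistics — not
the difficulty of segmenting real micrographs, where accuracy is dominated
by the backend's handling of optics and crowding.

## Reference backend

The built-in classical segmenter is deterministic: (1) subtract a local mean
over a 201-px square window (flattens slow illumination gradients; the
window is clipped to the image for small inputs), (2) orient the residual so
cells are positive, choosing the polarity whose residual tail is heavier,
(3) split by global Otsu threshold (512 bins). Two numerical choices matter:

- **Gap repositioning.** Between-class variance is nearly flat across an
  empty histogram gap, so the raw Otsu cut can land at either gap edge; when
  ~20% of the frame is cells, the local mean sits several levels below the
  true background and background far from any cell can end up on the wrong
  side of an edge-parked cut. The final cut is therefore the midpoint of the
  two class means — an Otsu-equivalent cut within the same gap, stable to
  that artifact.
- **Contrast gate.** If the residual span, or the gap between the two class
  means, is under 16 gray levels, the image is declared cell-free and the
  whole mask is emitted at confidence 20. Pure sensor noise splits a few
  levels apart; genuine cell contrast is tens of levels.

Selected pixels are emitted at 230 and rejected at 20, so the default
binarization threshold of 170 separates them with margin.

## Refinement chain

Binarization is strict-greater (foreground ⇔ value > threshold; equality is
background). Refinement applies, in order: `erosion_iterations` erosions and
`dilation_iterations` dilations with a square kernel (defaults 2, 2, 3×3),
hole filling, small-object removal, then the border policy. Erosion-first is
what severs 1–2 px bridges between adjacent cells; since
erosion-then-dilation is an opening, the result never extends beyond the
dilation of the eroded set and separated cells cannot re-merge. A hole is a
background component not 4-connected to the frame border (the dual of the
8-connected foreground default; both connectivities are configurable).
Small-object removal drops components with strictly fewer than
`min_area_px` pixels (default 100 px ≈ 1.6 µm², far below any real cell; a
component of exactly the minimum area is kept). The border policy defaults
to `keep`; `drop` removes frame-touching regions, which otherwise bias
length statistics low.

## Morphometry

Regions are labeled 1..N in raster-scan order of first pixel. Distances are
between pixel centers: the convex hull is built by monotone chain (collinear
vertices dropped, lexicographic tie-break), the maximum Feret diameter is
the largest pairwise distance over hull vertices, and the minimum Feret
diameter is the smallest caliper width, realized normal to a hull edge
(rotating-calipers theorem). Degenerate conventions: a singleton region has
both diameters 0; a collinear region has minimum 0.

The point convention understates calipers by up to ~1 px per side relative
to treating pixels as unit squares — and by ~2 px in the measure-zero worst
case of an axis exactly aligned with the pixel grid. An optional
`perimeter_correction_px` adds a constant back; it is off by default so that
the measured value is exactly the declared point-set statistic. Length and
width scale linearly with the microns-per-pixel calibration and area
quadratically.

## Evaluation

IOU is the pixel-count area of intersection divided by the area of union;
when both masks are empty the union is 0 and the IOU is reported as 0 with
an `empty_union` flag. Centroid matching rounds the mean pixel coordinate
half-up to an integer pixel; per predicted region, foreground at that pixel
in the reference mask is a true positive, otherwise a false positive, and
false negatives are counted symmetrically from reference regions. Known
quirks, kept deliberately because they are the rule as defined: a concave
region whose centroid falls in its own cavity is scored as missed even under
perfect overlap, and two predicted regions whose centroids land in one
reference cell both count as true positives (pooled counts can therefore
exceed the reference cell count). Precision and recall are always emitted
with the raw counts; a zero denominator yields 1.0 when the opposing mask is
also empty and 0.0 otherwise. Batch evaluation pools tp/fp/fn by summation
and averages IOU unweighted across pairs.

## Statistics

- Summary: sample sd (divisor n−1), CV = sd/mean, skewness m₃/m₂^{3/2} with
  central moments using divisor n (the adjusted Fisher–Pearson variant
  behind `bias_correct`), quantiles by linear interpolation. n ≥ 3 is
  required (the skewness precondition); constant samples have CV 0 and
  undefined skewness.
- Two-sample KS: D is the exact supremum of |F̂ₓ−F̂ᵧ| over the pooled sample
  values; the p-value is the plain asymptotic Kolmogorov distribution at
  D·√(nₓn_y/(nₓ+n_y)), with no small-sample continuity correction — D is
  the primary surface, the p-value a convenience.
- Welch t with Satterthwaite degrees of freedom, as a convenience statistic.
- Two-component Gaussian mixture by EM: default initialization at the 1/3
  and 2/3 sample quantiles with equal weights and the pooled sd; variances
  unconstrained (not forced equal); σ floored at 10⁻³ × sample range to
  prevent likelihood collapse; stop when the log-likelihood gain falls below
  `tol` (default 10⁻⁸) or at `max_iter` (default 500); components relabeled
  so μ₁ ≤ μ₂. The log-likelihood path is retained so monotonicity is
  assertable per run. Requires n ≥ 10 and a non-constant sample.
- The density plot is a Gaussian-KDE presentation convenience (Silverman
  bandwidth), not a tested statistic.

## Pipeline and reproducibility

`run_pipeline` executes confidence → binarize → refine → label → measure →
CSV for each input, writing per-image refined masks, a pooled
`measurements.csv` (floats at 6 significant digits) and a `manifest.json`
with the effective parameters, per-image cell counts and per-stage
foreground pixel counts (making the erosion/dilation chain auditable).
Manifests contain no timestamps or machine state, so identical config and
inputs reproduce byte-identical outputs. Unreadable inputs are recorded as
failures and the run continues. Benchmarking pairs predicted and reference
mask files by filename stem and fails loudly on orphans.

## Problem sizes in the test and acceptance runs

The shipped suite and acceptance script use scenes of 8–50 cells on frames
up to 768×1024 px, 500 random regions for the Feret oracles, 100 random
sample pairs for the KS oracle, and n = 2000 draws for mixture recovery —
sizes at which every analytic comparison is exact or tightly bounded while
a full run completes in seconds on one CPU.

## Known limitations

- No watershed or distance-transform instance splitting: touching cells are
  separated only as far as erosion/dilation can sever necks, which fails for
  broad contacts.
- The Feret point convention systematically understates dimensions by a
  sub-pixel amount; comparisons across conditions are unaffected, absolute
  values carry the bias unless the correction flag is used.
- The KS p-value is asymptotic and anti-conservative for very small samples.
- EM finds a local optimum; for well-separated modes the default quantile
  initialization is reliable, but heavily overlapping components can settle
  into a one-component solution (weights near 0/1).
- The reference backend assumes roughly uniform cell contrast against a
  slowly varying background; it is a baseline and a test harness, not a
  competitor to trained segmentation models on real micrographs.
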