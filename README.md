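# rodmorph

Morphometry of rod-shaped cells (fission yeast and similar organisms) from
segmentation masks. Cell-cycle stage in *Schizosaccharomyces pombe* tracks
cell length — cells grow from ~7 µm to ~14 µm before dividing — so length
and width distributions extracted from brightfield micrographs are a
workhorse readout for growth, stress and checkpoint phenotypes. `rodmorph`
takes a grayscale *confidence mask* (from any segmentation backend, neural
or classical), turns it into clean per-cell measurements, and provides the
evaluation and statistics layers needed to trust and interpret those
measurements.

## What it computes

**Mask refinement.** A 0–255 confidence mask (dark = background, bright =
cell) is binarized at a global threshold *t* (foreground ⇔ value > *t*,
default *t* = 170) and refined by erosion ×2 and dilation ×2 with a 3×3
square kernel (severing thin bridges between touching cells), hole filling
(background components not 4-connected to the frame border), and removal of
components below a minimum area (default 100 px).

**Morphometry.** Each 8-connected component is measured as:

- area  *A* = (pixel count) · mpp², with mpp the microns-per-pixel
  calibration (default 0.1258125 µm/px);
- length *L* = max Feret diameter · mpp — the largest caliper extent,
  max_θ w(θ) where w(θ) is the extent of the region's projection onto
  direction θ;
- width  *W* = min Feret diameter · mpp = min_θ w(θ).

Pixels are treated as points at their centers; the maximum is the largest
pairwise distance between convex-hull vertices and the minimum is realized
normal to a hull edge (rotating calipers).

**Evaluation.** For a predicted/reference mask pair: IOU = AOI/AOU by pixel
counts, and centroid detection matching — a predicted region is a true
positive iff the reference mask is foreground at the region's rounded
centroid, false negatives symmetrically from reference centroids — with
precision = TP/(TP+FP) and recall = TP/(TP+FN).

**Statistics.** Summary statistics (CV = s/x̄, moment skewness m₃/m₂^{3/2},
quantiles), the two-sample Kolmogorov–Smirnov test D = sup|F̂ₓ−F̂ᵧ|, a Welch
t statistic, and a two-component Gaussian mixture π·N(μ₁,σ₁²) +
(1−π)·N(μ₂,σ₂²) fit by EM for biphasic length distributions.

**Synthetic scenes.** A seeded generator renders monolayers of 2D stadium
cells (rectangle capped by semicircles — closed-form area (L−W)W + π(W/2)²,
max Feret = L, min Feret = W) with exact ground-truth masks and per-cell
records, so the whole chain is testable against analytic oracles without
real micrographs.

## Worked example

```sh
rodmorph simulate --out-dir scene --seed 11 --n-cells 30
rodmorph run --input scene/scene.tif --out-dir out
rodmorph evaluate --pp out/scene_mask.png --manual scene/scene_mask.png --out report.csv
rodmorph stats out/measurements.csv --out stats.csv
```

prints

```
wrote scene/scene.tif, scene/scene_mask.png, scene/scene_truth.csv (30 cells)
measured 30 cells -> out/measurements.csv
wrote report.csv: mean IOU 0.9992, precision 1.0000, recall 1.0000
wrote stats.csv (quantiles: linear interpolation)
```

`out/measurements.csv` holds one row per cell:

```
cell_id,source_image,area_px,area_um2,length_um,width_um,centroid_row_px,centroid_col_px
1,scene,3580,56.6671,17.4376,3.37418,42.2489,327.504
...
```

— cell 1 covers 3580 px = 56.7 µm², is 17.4 µm long and 3.4 µm wide. The
evaluation line says the refined masks overlap the ground truth at IOU
0.9992 and every one of the 30 cells was detected with no spurious regions.
The stats table summarizes the length distribution (mean 13.06 µm, CV 0.31).

The same operations are available as a library:

```python
from rodmorph import SceneSpec, sample_scene, segment_image, label_regions, measure, Calibration

image, truth = sample_scene(SceneSpec(n_cells=30, seed=11))
mask = segment_image(image, "reference")
cells = measure(label_regions(mask), Calibration())
```

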