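# Methods

This note documents the models, measurement conventions, parameter choices
and known limitations of `gliamorph`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic microglia silhouettes

The generator emulates the *geometry* of segmented single-cell masks, not
fluorescence physics. A cell is a filled soma disk at the centre of a
340×340 frame plus recursively branching processes drawn as integer
Bresenham strokes of fixed width (2 px). Growth at each node draws a
segment of length `mean_segment_length_px × U(0.7, 1.3)` at the parent
angle plus uniform jitter of half-width `tortuosity` (radians); with
probability `branch_probability` the process bifurcates (split angle
`U(0.3, 0.7)` rad), otherwise it continues, down to `max_branch_depth`
levels. Branches leaving the frame are clipped; the result is always one
8-connected component rooted on the soma.

Determinism: all geometry is integer raster (midpoint-rule disk fill,
Bresenham strokes); one `numpy` Generator is derived per object from
`SeedSequence(master_seed, spawn_key=(index,))`, so images are reproducible
bit-for-bit across platforms and under parallel generation.

Two frozen presets bracket the biology:

| preset | soma r (px) | primaries | segment (px) | branch p | depth |
|---|---|---|---|---|---|
| ramified | 10 | 6 | 28 | 0.7 | 4 |
| ameboid  | 16 | 2 |  9 | 0.1 | 1 |

Per-class population means of real microglia are not published, so the
presets are calibrated only to reproduce the *directions* of the
activated-vs-surveilling contrast (activated: lower fractal dimension,
roughness, perimeters and hull size; higher density and circularity) with
clear statistical separation at 50 cells/class — not any particular
magnitudes. Synthetic masks lack real-data features such as uneven
staining, touching cells, out-of-focus blur and varying process width, so
passing tests demonstrate correctness of the measurement machinery, not
segmentation robustness on real microscopy.

`degrade_to_grayscale` produces the grayscale inputs for the preprocessing
stage: foreground 200 / background 20, Gaussian edge softening (σ = 0.5 px)
and additive Gaussian noise (σ = 10 intensity units), clipped to [0, 255].
The softening is kept below the finest process width so the silhouette is
recoverable by thresholding; with the matched preprocessing default
(smoothing σ = 0.5) mask recovery achieves Jaccard ≥ 0.95 over the preset
seed banks, which the tests verify.

## Image preprocessing

`preprocess` smooths (Gaussian, σ = 0.5 px default) and thresholds
(Otsu by default; a fixed threshold can be supplied in place of the
interactive brightness/contrast adjustment of desktop workflows).
Foreground is strictly-above-threshold, so raising the threshold can only
shrink the mask. `crop_and_isolate` extracts a 340×340 window and keeps
the connected component nearest the window centre, ignoring components
under 20 px — a deterministic, conservative stand-in for manual speckle
editing. Conventions used throughout: 8-connectivity for foreground,
outline = filled pixels 4-adjacent to background (frame border counts as
background). Inputs are single 2-D planes; z-stacks are out of scope.

## Morphometric panel

Twelve parameters have standard definitions (fractal dimension,
lacunarity, roughness, cell/hull perimeter, cell/hull area,
bounding-circle diameter, max span, mean radius, density, cell
circularity); the panel is completed to 15 with hull circularity, span
ratio and radius CV, following the conventional output set of box-counting
morphometry tools. Every formula is documented so the panel is auditable:

* **Box-counting dimension** — on the *outlined* image (configurable):
  least-squares slope of log N(ε) vs log ε over box sizes ε = 2, 4, …,
  frame/4 (powers of two). Per scale, four grid origins are tried — (0, 0)
  plus three frozen seeded offsets — and the **minimum** count is used
  (grid-offset minimal cover). Averaging over offsets was rejected: offset
  grids need ~(m+1)² boxes where an aligned grid needs m² on a filled
  square, which biases the large-box end and drags the plane-filling
  estimate from 2.0 to ≈1.91; the minimal cover restores the analytic
  values (1.0 line, 2.0 filled square, log3/log2 Sierpinski) within ±0.05.
  The fit R² is reported as a QC field.
* **Lacunarity** — on the *filled* image: mean over scales and origins of
  (σ/μ)² of per-box pixel mass, over complete boxes intersecting the
  foreground bounding box. The mean-Λ convention is used (slope-based
  variants exist; the convention is labelled).
* **Perimeter** — length of the marching-squares 0.5-level contour of the
  Gaussian-smoothed (σ = 1 px) mask. Chain-code-style estimators
  (axis + √2·diagonal steps) overestimate a digital disk's perimeter by
  ≈5.5% on average over orientations, which would push disk circularity
  down to ≈0.89; the smoothed sub-pixel contour is accurate to ~1–2% on
  disks, squares and crosses. Consequence: structures thinner than ≈1.5 px
  do not contribute (package silhouettes use 2-px strokes), and perimeter
  is only scale-covariant for features resolved above the smoothing scale.
* **Convex hull** — over the *corners* of boundary pixels (pixels as unit
  squares). The hull therefore contains every foreground pixel, which
  guarantees `cell_area ≤ hull_area` and `density ∈ (0, 1]` (a pixel-centre
  hull violates both: a filled 100×100 square would have density 1.02) and
  reproduces analytic values exactly (square hull area s², plus-sign hull
  7L²). Max span is the largest pairwise vertex distance; the bounding
  circle is Welzl's minimal enclosing circle over hull vertices in
  deterministic hull order; mean radius and its CV are measured from the
  hull's polygon centroid; span ratio = max span / (2·mean radius).
* **Ratios** — density = cell area / hull area; roughness = cell perimeter
  / hull perimeter; circularity = 4πA/P² for the cell and the hull.

Degenerate inputs raise: empty masks, zero-radius somata, fewer than two
usable box scales, collinear hulls, zero perimeter.

## Clustering

Features are standardized per column (sample sd) before Euclidean
distances by default — the panel mixes px² areas with dimensionless
ratios, and raw distances would be dominated by area terms. Ward linkage
is implemented as the greedy Lance–Williams recurrence on squared
distances with a documented lowest-index tie-break; heights follow the
`sqrt(2·ΔESS)` convention (two singletons merge at their Euclidean
distance) and the output matrix is SciPy-compatible, so cutting and
dendrogram plotting use standard tools. Tests verify merge-order equality
with an exhaustive ESS oracle (n = 12) and height agreement with SciPy's
independent nearest-neighbour-chain implementation.

The cluster count is a majority vote of silhouette, Calinski–Harabasz,
Davies–Bouldin and Dunn over k = 2..10, ties toward smaller k. This is a
deliberate reduction of the 30-index battery popular in R workflows to
four well-defined, reproducible indices; the full battery is out of scope.
Trees serialize to Newick (branch lengths = height differences) plus a
flat merge CSV so any plotting layer can redraw the dendrogram.

## Statistics

* 1.5×IQR outlier rule, single pass, applied per group per measure before
  testing; quartiles by linear interpolation between order statistics
  (the convention affects borderline points and is pinned).
* Unpaired t-test: pooled-variance Student by default (Welch by flag),
  two-sided. Type-I calibration at α = 0.05 over 2,000 null simulations is
  asserted to 5% ± 1.5% in the acceptance suite.
* Two-way 2×2 ANOVA with Type II sums of squares (pinned for unbalanced
  designs; the choice is a package decision, not a claim about any
  particular desktop software's convention), followed by Tukey HSD over
  the four cells. An all-constant table returns F = 0, p = 1 (0/0 defined
  to zero for this degenerate input).
* ΔΔCt: ΔCt = Ct(target) − Ct(reference) per sample; fold = 2^(−ΔΔCt)
  from group-mean ΔCt differences; per-sample −ΔCt is returned for
  mean ± SEM reporting.

## Omics integration

Coordinates are 0-based half-open (BED). A condition peak is *unique* when
no reference peak on its chromosome overlaps it by ≥ `min_overlap_bp`
(default 1 bp — peak callers do not define the overlap notion, so it is
exposed). The sweep uses start-sorted references with a running-max end
bound; a quadratic scan is the test oracle.

Annotation is by peak **midpoint** with a fixed promoter-first priority:
promoter-TSS ≻ TTS ≻ 5′UTR ≻ 3′UTR ≻ CpG-island ≻ exon ≻ intron ≻ others.
Windows are strand-aware: promoter −1000..+100 bp around the TSS, TTS
−100..+1000 bp around the TTS, both along the direction of transcription,
end-inclusive. Without a CpG-island track that category simply never fires.
The priority makes assignment total and single-valued; the toy genome's
fixed gene layout (10 kb genes, 30 kb spacing, three exons, intergenic
islands) provides planting regions where the category is unambiguous, so
generator ground truth is recovered exactly.

Consensus targets: each database contributes its deduplicated (best-rank)
top 50; genes in ≥ 2 databases are selected, with supporting-database sets
retained. GO binning maps term ids through a user-supplied mapping into the
10 biological-process subcategories (unmapped → "others", logged); how any
particular curated mapping was built is outside the package — the mapping
is an input. Venn region counts are exclusive and partition the union;
more than 3 sets is an error.

## Problem sizes and defaults in the test suite

The suite exercises the full image→profile→cluster path on 50 + 50
generated cells (the size at which the directional contrast is asserted at
p < 0.01 per parameter), oracle equivalences at n ≤ 12 (exhaustive Ward)
and n = 200 (peaks), a 2,000-replicate t-test calibration, and a
10,000-shuffle permutation check of the ANOVA F. These sizes give stable
verdicts for deterministic seeds while keeping a full run under a minute
of compute for everything except the statistics calibrations.

## Known limitations

* The silhouette generator does not model optics (PSF, shot noise,
  z-projection artifacts); robustness on real micrographs is untested.
* Fractal dimension from a finite scale window is an estimate; for small
  smooth blobs it legitimately drifts toward 1 as resolution increases,
  so it is not resolution-covariant the way areas are.
* The 4-index cluster-count vote can disagree with larger index batteries
  on weakly separated data.
* Whole-field segmentation and cell detection are out of scope: inputs
  are per-cell crops or centre coordinates.
* Enrichment statistics (GO/KEGG) are consumed, never recomputed.
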