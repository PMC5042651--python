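# Methods

## The measurement problem

Early fly embryos internalize their mesoderm in one of two ways: by
*invagination*, a coordinated infolding of the intact ventral blastoderm
epithelium that forms a deep ventral furrow, or by *ingression*, in which
individual cells detach stochastically from the epithelium over a shallow
ventral groove and translocate inward one by one.  In fixed, stained embryos
the two modes cannot be told apart by eye from single sections — cell
behavior varies substantially along the anterior–posterior (AP) axis — so
the distinction must be made quantitatively, from the 3D positions of
nuclei relative to two reconstructed reference surfaces:

* the **virtual egg shell** — the vitelline envelope is lost during
  fixation, so it is approximated by a 3D alpha hull cast over the nucleus
  centroids.  With the default probe radius this is the convex hull: the
  smallest-area surface enclosing all nuclei, which deliberately levels out
  the furrow indentation.  Because nuclei touch the shell but their centres
  sit half a diameter inside it, the ventral-facing hull vertices are
  displaced outward by half a nucleus diameter.
* the **ventral epithelium surface** — nuclei are blurred into a connected
  layer, the largest connected component is kept, holes are closed, and the
  lower (shell-facing) boundary mesh of the layer is taken as the apical
  epithelial surface.

Each nucleus is then classified by two independent distance thresholds of
one nucleus length `d`:

* **internalized**: distance to the egg shell `d_shell > d`;
* **ingressed**: distance to the apical epithelium surface `d_epi > d`.

The ventral region of interest (ROI: 25–75 % egg length along AP, ventral
30 % of the circumference) is cut into equal-width transversal slabs
(9 by default; 17 for the variation analysis), and each slab is summarized
by five parameters:

| parameter | definition | unit |
|---|---|---|
| internalization | % of slab nuclei internalized | % |
| integrity | % of internalized nuclei not ingressed | % |
| furrow depth | max `d_shell` over internalized, non-ingressed nuclei | nuclear diameters |
| max cell depth | max `d_shell` over all slab nuclei | nuclear diameters |
| furrow width | ML span of internalized non-ingressed centroids + 1 diameter, relative to embryo width | % |

For phenotypes without internalization (snail-knockdown-like), integrity is
undefined under this definition and is instead computed over all ROI cells
(`all_cells` variant).  Mitosis is counted by overlap of nucleus objects
with positive phospho-Histone-H3 staining (≥ 50 % of the nucleus's voxels
above the channel's positivity threshold).

Sections become points in a z-score-normalized morphospace.  Group
comparisons use the two-sided Wilcoxon rank-sum test on per-section values;
PCA (on the five parameters for wild-type comparisons, or the four
time-independent parameters — internalization, integrity, furrow depth,
max cell depth — for variation analysis) summarizes which parameters
separate the modes.  Developmental robustness is measured as Euclidean
morphospace variation: mean pairwise section distance within a group, mean
distance of one embryo's sections to all other embryos' sections (plus an
embryo-centroid variant; both are reported), and the standard deviation of
within-embryo pairwise distances.  Internalization efficiency is the
percentage of internalized ROI cells in embryos staged at 15–25 % germband
extension (GBE, percent egg length displacement of the posterior midgut —
the staging clock).

## Synthetic embryos and their ground truth

No raw imaging data is publicly deposited for this system, so the package
ships a generator whose outputs have known per-nucleus truth.  Nuclei form
a single-layer shell over an ellipsoid (default half axes 170 × 100 × 85 µm,
nucleus diameter 10 µm), packed at one diameter spacing over a dense
ventral band (45 % of the circumference) and sparsely (2.5× spacing)
dorsally so the hull closes over the whole embryo.  Rows are staggered by
up to half a diameter in AP, as in real blastoderms.  The default density
gives roughly 28–30 ROI nuclei per transversal section, matching the
section occupancy of the imaging data this analysis style was developed on.

Three phenotype presets:

* **invagination** — a Gaussian furrow profile in the arc coordinate
  (σ = 28 µm, ≈ 18 % of the circumference internalized), displacing the
  coherent sheet inward along the surface normal; depth 2.5 diameters by
  default.
* **ingression** — a narrow flat-topped groove (super-Gaussian, σ = 12 µm,
  ≈ 10 % of circumference, depth 1.5 diameters) plus stochastic
  detachment: each internalized sheet position spawns ingressed nuclei
  below the epithelium with Poisson odds `p/(1−p)`, placed 1.5–2.5
  diameters under their site (deeper on collision — cells cannot overlap),
  so the expected integrity is `100·(1−p)`.  The epithelium stays nucleated
  under each detachment, as neighbors close the gap in vivo.
* **flat** — no displacement (knockdown-like control).

**Depth calibration.** Because the convex shell levels the furrow mouth,
depth measured against it under-reports the raw displacement by the chord
sag over the vacated mouth.  Furrow depth is therefore *defined* — for the
ground truth exactly as for the measurement — relative to the virtual
shell: the generator calibrates its displacement amplitude by fixed-point
iteration on the noise-free positions (against its own hull, within the
ROI AP range) until the realized depth of the deepest coherent nucleus
(invagination) or the groove-core median (ingression) equals the requested
value.  Ground-truth internalization flags are noise-free shell distances
exceeding one diameter, restricted to displaced nuclei.  With this
convention the recovery tests measure pipeline error (noise, meshing,
segmentation), not a clash of two depth definitions; `true_furrow_depth`
records the realized depth if the requested one is geometrically
unattainable.

Positional noise (0.5 µm sd, segmentation-scale jitter) is added last.
Cohorts draw per-embryo seeds `base_seed + i` and mild between-embryo
parameter jitter (5 % sd relative on furrow depth/halfwidth and detachment
probability; GBE stage ±0.5 percentage points sd), representing biological
and staging variability.

Rendering produces 2-channel 8-bit stacks (pHisH3, DNA) of isotropic
Gaussian blobs (sd = diameter/4) with additive Gaussian noise — adequate
for validating the segmentation path, with no point-spread-function or
photon-statistics modeling.

## What the generator does and does not emulate

Passing tests establish that the *measurement pipeline* is internally
consistent and recovers known geometry under realistic density, noise and
stochasticity.  They do not certify performance on real micrographs: real
nuclei are textured, anisotropic and unevenly stained; real epithelium
boundaries require a trained pixel classifier rather than intensity
thresholds; and real embryos deviate from ellipsoids.  For real data the
intended entry point is the pre-segmented centroid table (CSV), produced by
whatever segmentation tool fits the images; everything downstream of
centroids is shared with the validated synthetic path.

## Numerical and design choices

* **Segmentation** is deterministic threshold/connected-components: Otsu's
  threshold (or a configurable intensity quantile) on the normalized DNA
  channel, 26-connectivity, component size filter, intensity-weighted
  centroids.  Touching nuclei are not declumped; rendered validation
  stacks therefore use nuclei ≥ 2 diameters apart, where count recovery is
  exact.
* **Epithelium reconstruction** runs, for both stack and table inputs, on
  a Gaussian-blob rasterization of the segmented nuclei (2 µm grid,
  ventral half only).  The fusion blur adapts to the observed median
  nearest-neighbor distance (`sd = max(3 µm, (nn/2)/√(2 ln(2/f)))`, with
  threshold fraction f = 0.45 of the analytic blurred blob peak) so the
  layer stays connected for any monolayer packing.  The closing radius
  rescales the configured `hole_max_gap` (20 px at the 0.28 µm acquisition
  pitch) to the grid.  The apical surface is the lower boundary of the
  ventrally shadow-filled component; columns rising more than ~0.6
  diameters above the lower-quartile height of their one-diameter
  neighborhood are treated as nucleus gaps in a continuous epithelium and
  sealed at the quartile level.
* **Point-to-mesh distances** are exact over all triangles (face, edge and
  vertex cases), with a centroid-radius bound pruning large meshes and a
  cancellation-free refinement for near-surface points; agreement with a
  brute-force per-triangle oracle is 10⁻⁹ µm or better.
* **Alpha hull**: the default probe radius yields the convex hull (the
  observed outcome of the original approach); a finite radius selects the
  alpha complex of Delaunay tetrahedra with circumradius below the probe,
  and an open or multi-component boundary raises a geometry error.
* **Centerlines** (shortest left-to-right path through all section nuclei)
  are solved exactly by Held–Karp dynamic programming up to 12 nuclei and
  by nearest-neighbor construction with 2-opt and Or-opt refinement above
  that; on random instances of ≤ 11 points the heuristic matches the exact
  optimum.
* **Wilcoxon rank-sum**: exact null enumeration when `n+m ≤ 20` without
  ties, otherwise the normal approximation with tie and continuity
  correction (mid-ranks for ties); delegated to `scipy.stats.mannwhitneyu`
  and cross-checked against a full enumeration oracle and a
  100 000-resample permutation oracle in the tests.
* **PCA** is an SVD of the centered matrix with a deterministic sign
  convention (largest-magnitude loading positive); tests verify it against
  an independent eigendecomposition of the covariance.
* **Ties and degeneracies**: AP slab boundaries are half-open with the
  boundary nucleus assigned to the lower-AP slab; empty slabs are skipped;
  integrity of a slab without internalized nuclei is NaN under the default
  variant and such sections are dropped from morphospace analyses.
* **Sampling sizes.** Validation simulations use 3–10 embryos per cohort
  and full-size embryos (~900 nuclei); the oracle-equivalence and
  invariant checks use compact embryos (< 200 nuclei).  These sizes give
  stable directions and tight recovery errors while keeping a full run of
  the suite in the minutes range.

## Known limitations

* The hull-based furrow depth is a *definition*, not the raw displacement;
  for very deep, wide furrows on small embryos the requested depth can be
  geometrically unattainable and the ground truth records the realized
  value instead.
* Integrity recovery carries a few-percentage-point classification
  allowance from groove-rim nuclei that sit within measurement noise of
  the one-diameter threshold.
* Per-section values in sparse embryos are quantized by small counts; a
  single nucleus crossing a slab boundary changes a section percentage by
  tens of points, which is why path-consistency checks compare embryo-level
  aggregates.
* Statistical comparisons treat sections as independent samples, ignoring
  within-embryo correlation (per-embryo pseudoreplication), exactly as in
  the analysis style this package reproduces; p-values are therefore
  anti-conservative for embryo-level claims.
* No multiple-testing correction is applied; reported p-values are raw.
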