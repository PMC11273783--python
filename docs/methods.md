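# Methods

## Overview

The package implements a pathomics pipeline that turns H&E-stained
histopathology tiles into a case-level feature matrix and a cross-validated
SVM prediction of a binary treatment outcome.  Because the intended imaging
cohort (post-treatment ovarian-cancer slides from bevacizumab-treated
patients) cannot ship with the code, a synthetic cohort generator with
exact ground truth is a first-class component: every stage is validated
against masks the generator guarantees, and the statistical behavior of the
whole pipeline is checked under controlled class effect sizes.

## Synthetic cohort model

A tile is rendered in optical-density (OD) space and converted to RGB by
Beer–Lambert mixing, `I = I0 · 10^-(c_H·s_H + c_E·s_E)` per channel, with
the Ruifrok–Johnston H&E absorbance vectors by default.  Compartment
concentrations (hematoxylin, eosin in OD units):

| compartment | c_H  | c_E  | total |
|-------------|------|------|-------|
| nucleus     | 0.85 | 0.15 | 1.00  |
| cytoplasm   | 0.10 | 0.40 | 0.50  |
| stroma      | 0.05 | 0.32 | 0.37  |

These were chosen once so that every compartment of a doubled-OD tissue
fold (stroma 0.74, cytoplasm 1.0, nucleus 2.0) is heavier than any
unfolded compartment, which is what "disproportionately heavy staining"
means physically: a fold doubles the optical path length.

Nuclei are area-preserving ellipses (radius ~ N(μ, 0.12μ), eccentricity and
orientation randomized) placed by rejection sampling inside a smooth random
tissue region; whole cells are concentric ellipses scaled by 1.6.  Cells
never overlap (circumradius disjointness with a 1000-try budget per
nucleus), which keeps ground-truth label counts exact.  Texture comes from
a low-frequency multiplicative modulation field plus per-pixel Gaussian OD
noise (default SD 0.05); folds are elliptical patches (~5% of the tile)
centered on tissue with all concentrations doubled, drawn with probability
0.1 per tile.

Default cohort shape is 44 responders vs 35 non-responders with 1000 px
tiles, matching the clinical cohort the pipeline targets; the two classes
are identical unless an effect size is requested (class-dependent nuclear
radius, eccentricity, or noise).  The bench-scale conditions used by the
analysis scripts and tests (chosen once for CPU economy and stated here as
the package's own scale) are 10 + 10 cases, one 144 px tile per case, 7
nuclei of mean radius 4 px, granularity truncated to 8 scales.

What the generator does **not** emulate: chromatin texture with spatial
structure inside nuclei, overlapping/touching cells, stain variation
between slides, scanner defocus (beyond what blurring tests apply
explicitly), pen marks, and tissue-type heterogeneity.  Passing tests
therefore demonstrate correctness of the measurement and modeling
machinery and its statistical calibration — not segmentation robustness on
real tissue.

## Stage-by-stage choices

**Tissue filter.**  A pixel is tissue if HSV saturation > 0.05 or gray
level < 220/255; a tile is kept if ≥ 50% tissue (inclusive).  The rule is
the standard whitespace heuristic; both constants are configurable.

**Stain deconvolution.**  `OD = -log10((I + 1)/I0)` (the +1 guards
saturated black pixels), clamped non-negative; two-stain least-squares
unmixing via the pseudoinverse of the 2x3 unit-norm stain matrix, negative
concentrations clamped to 0, the third residual channel discarded.  No
automatic stain estimation (Macenko/Vahadane) and no cross-slide
normalization.  All intensity/texture features downstream are computed on
OD concentration channels, not re-inverted intensities.

**Fold removal.**  Li's minimum-cross-entropy threshold on the
Gaussian-smoothed (σ = 2 px) total OD of tissue pixels; components smaller
than `min_fold_area` are discarded (folds are macro-scale; the default
2500 px = 0.25% of a 1000 px tile scales with tile area via
`fold_area_fraction`).  Smoothing is essential: pixel noise otherwise
fragments a fold below the area floor.  Near-constant histograms define the
threshold as +inf (no folds).  Total OD rather than hematoxylin alone is
used, and is configurable.

**Nuclei.**  Otsu threshold on the hematoxylin channel (fold pixels
excluded), equivalent-diameter band 8–60 px at 20x (0.5 µm/px),
distance-transform watershed seeded at h-maxima (h = 2 px) for declumping.
Labels are canonicalized by raster order of centroids, so identical inputs
give identical masks.

**Cell propagation.**  The published propagation cost
`sqrt((g(p)-g(q))² + λ²·d(p,q)²)` with λ = 0.05 and 4-connectivity,
explored in Dijkstra order from all nucleus pixels over the foreground
(Li threshold on total OD, unioned with the seeds).  Large λ reduces to a
nearest-seed Voronoi partition; the implementation is validated against an
independent sparse-graph Dijkstra solver.  The per-pixel priority-queue
loop is pure Python — fine at bench scale, the known hotspot for 1000 px
tiles.

**Features.**  Implemented from their literature definitions rather than
chasing any particular tool's inventory; the emitted columns are
enumerated in a manifest (`compartment_family_measure` naming).  Notable
conventions:

- *Haralick*: 8 gray levels, per-region min–max quantization, symmetric
  GLCMs for 1 px offsets in 4 directions, 13 statistics averaged over
  directions.  Constant regions: contrast/entropy/correlation-type
  features are 0 (ASM and IDM are 1, the deterministic single-level GLCM).
- *Zernike*: magnitudes to degree 9 (30 values) of the least-squares
  projection of the object indicator onto the Zernike basis sampled on the
  object's minimum enclosing disk (centroid center, max-distance radius).
  The least-squares form was chosen over the plain discrete sum because it
  preserves two exact properties on the pixel lattice: a full disk has
  zero magnitude for every n ≥ 1, and 90° raster rotations leave all
  magnitudes unchanged.  In the continuum limit it equals the standard
  `(n+1)/π⟨f, V_nm⟩` moment, which is what the quadrature oracle in the
  tests integrates.
- *Radial distribution*: 4 equal-width rings of centroid distance
  normalized by the object's maximum centroid distance; RadialCV over 8
  angular wedges.
- *Granularity*: spectrum of volume removed by openings with L1-ball
  (diamond) structuring elements of radius 1..n.  Diamonds — iterated
  Minkowski sums of the unit cross — form a true granulometry, so the
  spectrum is provably non-negative and sums to ≤ 100%; rasterized
  Euclidean disks do not (their opening volumes are not monotone in
  radius).  Border samples outside the image are ignored rather than
  reflected.
- *Shape*: Crofton 4-direction perimeter (unbiased for smooth outlines)
  in the form factor `4πA/P²`; solidity uses the convex hull of pixel
  centers so convex rasterized objects score ~1; minimum Feret diameter by
  projection over 180 angles.
- *Focus score*: slope of the log-log radially averaged power spectrum out
  to the corner (diagonal Nyquist) radius, with a relative floor on empty
  bins; a completely flat image scores −20 (documented floor).
- *Colocalization*: Pearson r (0 for a zero-variance channel), overlap
  coefficient, Manders M1/M2 with Otsu auto-thresholds, over tissue pixels.

**Aggregation.**  Object rows are pooled across all of a case's tiles
before statistics ("a nucleus is a nucleus regardless of its tile"), then
every feature column yields 12 statistics: mean, median, SD, and the nine
interior deciles (linear-interpolation quantiles).  Columns are sorted
before summation so the aggregate is bitwise invariant to tile/object
order.  A compartment with zero objects in a case contributes zeros plus a
raised `*_empty_flag`.  Pruning removes exact duplicates (first column by
manifest order wins) and columns whose variance after median scaling is
below 1e-10.

**Modeling.**  MI scores use the continuous/discrete k-nearest-neighbor
estimator (Ross 2014; k = 3): per sample, the distance to its k-th nearest
neighbor within its own class sets a radius, the cohort count inside that
radius enters a digamma average.  The implementation is vectorized across
feature columns (scoring thousands of aggregated features per
cross-validation fold is the pipeline's modeling hotspot) and agrees with
scikit-learn's reference estimator to machine precision on tie-free data;
tie-breaking jitter (1e-10 relative) reuses one seeded noise vector for
every column so duplicated columns score identically.  Scores are clamped
non-negative.  Selection is top-k (default 100) or
an inclusive score threshold (default 0.29); ties break by manifest column
order.  SVMs: stratified nested 5-fold CV, inner grid over
C ∈ {0.01, 0.1, 1, 10, 100} (and γ ∈ {scale, 1e-4..1} for RBF) maximizing
inner mean AUC; features z-scored with training-fold statistics.  Reported
AUC is the mean ± SD of outer-fold AUCs; the pooled-score AUC is also
recorded.  The confusion matrix thresholds pooled decision scores at 0;
metrics with zero denominators are reported as 0 and flagged.

Feature selection inside each outer training fold is the default because
whole-dataset selection leaks test information into the model; the leaky
variant is retained (`selection_scope="whole_dataset"`) for comparability
with select-then-validate studies.

## Statistical calibration

On zero-effect cohorts the full pipeline's mean nested-CV AUC sits in the
chance band.  With selection and scaling confined to each outer training
fold the procedure is exactly unbiased under the null — test-fold scores
are independent of test-fold labels — but a single 20-case cohort's AUC is
coarse (per-replicate SD ≈ 0.18), so only means over tens of replicate
cohorts are informative.  AUC rises monotonically with the
nuclear-radius effect size and saturates near 1.0 by a 2 px offset at
bench scale — 20 cases with ~7 measured nuclei each make large
morphological effects easy; the interesting regime for method comparisons
is 0.5–1.5 px.

## Known limitations

- The propagation stage is O(N log N) in Python; full-scale 1000 px tiles
  take tens of seconds each.  A compiled kernel would be the first
  optimization.
- Per-fold AUC on 20-case cohorts is quantized (4-case test folds); single
  replicates are noisy and only replicate means are meaningful.
- The synthetic cohort cannot certify behavior on real stain variation,
  touching cells, or scanner artifacts (see generator scope above).
- Haralick features on very small objects (< ~20 px) quantize coarsely;
  they are still deterministic and finite but carry little information.
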