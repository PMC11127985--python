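# Methods

## Measurement model

All measurements operate on a canonical grid: axis 0 increases toward
patient-left, axis 1 toward posterior, axis 2 toward superior, so an axial
slice is `data[:, :, z]` and "leftmost" means minimum index along axis 0 —
the lateral margin of the right hepatic lobe under the radiological display
convention (image-left = patient-right). Voxels are point samples at their
centers; every physical distance is computed between voxel centers with the
per-axis spacing in mm. Inputs are resampled to 0.7 × 0.7 × 2.5 mm
(trilinear for CT, nearest-neighbor with re-binarization for masks,
grids aligned at the first-voxel center) and the mask is reduced to its
largest 26-connected component before measurement.

### Attenuation estimators

- **Volumetric** — arithmetic mean HU over all mask voxels. Unbiased only
  if the segmentation contains nothing but parenchyma; vessels, which run
  ~30–60 HU above parenchyma, bias it upward by (vessel fraction)·(vessel
  contrast).
- **Axial** — mean HU over mask pixels of the slice with the largest
  in-plane mask area (area ties go to the most inferior slice). Same bias
  mechanism, higher variance.
- **Parenchymal** — emulates the manual protocol. Slices are ranked by
  in-plane mask area and chosen greedily subject to pairwise axial
  separation ≥ `min_axial_separation_mm` (default 5 mm), up to `n_slices`
  (default 3). Per slice, the leftmost mask column is found; among the
  rows attaining it the lower median is the center row; the ROI center is
  `center_offset_mm` (default 20 mm) to the right of the leftmost column,
  rounded to the nearest pixel (hence an offset quantization of ±½ pixel,
  0.35 mm at default spacing). Member pixels are those whose centers lie
  within `radius_mm = sqrt(roi_area_mm2/π)` (7.9788 mm for 2 cm²) of the
  center in physical mm — 405 pixels at 0.7 mm spacing, 198.45 mm², within
  1% of the nominal area. The estimate is the **unweighted mean of per-ROI
  means**; pooling pixels would weight slices by pixel count, but ROI
  counts are identical by construction so the distinction only matters for
  clipped ROIs. ROI pixels are *not* clipped to the mask by default (a
  manual circular ROI averages everything in the circle, and the 2 cm
  offset is designed to keep the circle ~1 cm interior to the contour);
  a `clip_to_mask` flag covers over-segmentation edge cases and a warning
  fires when the in-mask fraction drops below 0.9.

The sentence describing the protocol admits two readings of "0.5 cm": the
spacing between the three chosen slices, or an offset from the single
largest slice. We implement the former (greedy largest-area selection with
a 5 mm pairwise separation floor), which reproduces "three largest slices"
exactly when those are naturally ≥ 5 mm apart and enforces the stated
spacing otherwise; both parameters are configurable.

### Steatosis classification

`attenuation < threshold` with a strict inequality and a 40 HU default;
a reading of exactly 40.0 HU is normal. The parenchymal value drives the
category in the pipeline.

## Statistics layer

- **KS** — two-sample two-sided statistic (sup of the ECDF difference);
  p-value from the classical Kolmogorov limiting distribution at
  `sqrt(nm/(n+m))·D`. This is the textbook asymptotic p, slightly
  conservative at small n.
- **Bland–Altman** — mean difference ± 1.96·SD of paired differences,
  sample (n−1) SD.
- **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures, from the ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`; 95% CI via the
  F-distribution method with Satterthwaite degrees of freedom. A constant
  ratings matrix has no defined ICC and raises.
- **MAE / MSE** — both are reported under unambiguous names (method
  summaries in the field sometimes conflate the two labels).
- **AUC / sensitivity / specificity** — the classifier predicts positive
  iff score < threshold; AUC uses the rank (Mann–Whitney) formulation on
  the negated score with tie credit ½. CIs are percentile bootstrap
  (case resampling, seeded, default 1000 replicates, 2.5/97.5
  percentiles); replicates that lose a class are skipped and counted.
  BCa was not used: the percentile method is the simplest consistent with
  plain bootstrap resampling, and the skip count makes degenerate
  small-sample behavior visible instead of silently biased.

## Segmentation metrics

DSC and Jaccard by voxel counting. Surfaces are mask voxels with ≥ 1
non-mask 6-neighbor (border voxels count as surface); HD is the exact
bidirectional maximum of nearest-surface distances, ASSD the mean over the
pooled union of both directed distance sets (surface-size weighted). These
conventions match the de-facto standard of the common medical-image
metrics packages; distances respect anisotropic spacing. Both are checked
against exhaustive O(|S₁|·|S₂|) pairwise-distance oracles in the tests.

## Synthetic phantom

The phantom emulates the data regime the measurement stack targets, not
thorax anatomy: an ellipsoidal liver (default semiaxes 45/55/55 mm) in
uniform 20 HU soft tissue on a 160×192×56 grid at 0.7/0.7/2.5 mm.
Parenchyma voxels draw i.i.d. from Normal(μ, σ), default μ = 56 HU (the
normal-liver cohort regime) and σ = 10 HU (typical parenchymal noise on
unenhanced chest CT). Vessels are straight cylinders (default radius
2.5 mm) along randomized chords of the 0.85-scaled ellipsoid, offset
+45 HU, rasterized until the vessel compartment holds exactly
`round(vessel_fraction · liver_voxels)` voxels — the last cylinder is
trimmed deterministically along its axis, so the realized fraction is
voxel-exact and the volumetric estimator's expected bias is analytically
`fraction · delta` (2.25 HU at defaults). With `vessel_placement =
"central"` no vessel voxel lies within `vessel_clearance_mm` (default
30 mm) of the liver's leftmost margin; 30 mm = ROI offset (20) + ROI
radius (8) + margin, which guarantees default parenchymal ROIs are
vessel-free by construction. Everything is a pure function of the spec
(seed included): equal specs give bit-identical volumes.

What the phantom does **not** model: ribs/lungs and surrounding anatomy,
curved or branching vessels, bile ducts and focal lesions, partial-volume
blur at compartment boundaries, scanner physics (beam hardening, dose
noise texture), and inter-patient shape variability. Tests passing on
phantoms therefore demonstrate the correctness of the geometry,
estimators, and statistics — not clinical performance on patient CT.

`perturb_mask` provides controlled degradations (dilate/erode, rigid
shift, spurious disconnected blob) for exercising the metrics and the
largest-component filter.

## Numerical choices and tie-breaks

- Slice-area ties: lower (inferior) slice index wins, both in axial slice
  choice and in ROI slice ranking.
- Leftmost-column row tie: lower median of the attaining rows.
- Largest-component tie: component containing the smallest flattened
  raster index.
- Circle membership uses `d² ≤ r² + 1e-9` to make boundary pixels
  platform-stable.
- Masks resample by nearest-neighbor; linear-then-threshold was the
  alternative, nearest-neighbor was chosen as the common default for label
  images (documented as a potential deviation from any specific upstream
  pipeline).
- Monte-Carlo suites (estimator bias and unbiasedness over 50 seeds) run
  on a compact phantom grid (112×128×40, semiaxes 32/42/40 mm) with the
  same physical regime; the reference geometry checks use the full
  default grid.

## Limitations

- "Leftmost" anchoring assumes the right hepatic lobe is present and
  lateral; atypical anatomy (situs inversus, resection) would misplace
  ROIs.
- ROI placement assumes the canonical orientation codes in the NIfTI
  header are correct; the package reports, but cannot detect, mislabeled
  orientations.
- The ICC confidence interval is asymptotic in the ANOVA framework and
  can be anticonservative for very small n.
- The axial-separation constraint is enforced on slice-index distance ×
  slice thickness; sub-slice liver tilt is not modeled.
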