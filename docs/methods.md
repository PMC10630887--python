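# Methods

This note documents the models, parameter choices and numerical decisions
behind `avatarquant`, and what its synthetic benchmarks do and do not show
about real data.

## Movie pipeline

### Pre-processing

Bleed-through of one channel into another is corrected as
`max(target − k·source, 0)`; the coefficient `k` is user-supplied (default
0) or estimated by least squares on voxels known to contain only the source
signal.  Autofluorescent pigment structures, which appear in both the tumor
and GAM channels of older embryos, are removed with a pixel classifier: a
random forest (50 trees, depth ≤ 12) over a multiscale feature bank —
Gaussian-smoothed intensity, gradient magnitude and Laplacian of Gaussian
at pixel scales {1, 2, 4} per channel — trained on sparse annotations of
the four voxel classes (background, tumor, gam, autofluorescence).  Voxels
predicted autofluorescent are set to zero and every other voxel is left
untouched; zeroing is the conservative reading of "removal" and keeps the
operation idempotent.  By default the correction is applied to both the
tumor and GAM channels (configurable), since pigment shows in both.
Training subsamples at most 10 000 voxels per class; all randomness is
seeded.  An `OraclePixelClassifier` backed by known labels isolates
downstream stages from classifier error in tests.

### Tumor segmentation and volume

Per frame, the tumor channel is blurred with a Gaussian (default σ = 1 px
in-plane, scaled by the spacing ratio along z so the blur is roughly
isotropic in physical space) and binarised at Otsu's threshold computed on
that frame — a per-frame threshold absorbs photobleaching and expression
drift over 8–16 h recordings.  When the volume has at most 4096 distinct
intensity levels the Otsu histogram is built on the exact observed levels,
making the threshold identical to an exhaustive maximizer of inter-class
variance; larger volumes use the standard 256-bin histogram.  All connected
components are kept by default (invasive tumors fragment); a
largest-component (26-connectivity) mode is available.  Volume is voxel
count × voxel volume in μm³.

### GAM detection and morphotypes

GAMs are segmented on the max-intensity projection of their channel.  The
default classical backend:

1. Gaussian smooth (σ = 0.7 px).
2. Hysteresis threshold: detection at the high threshold (Otsu unless
   fixed), extent down to 0.4× that value for pixels connected to a
   detection.  The low tier keeps the dim, thin processes of ramified cells
   attached to their soma; the high tier decides existence, so background
   never enters on its own.
3. Watershed split of touching cells, seeded at the h-maxima of the mask's
   Euclidean distance map (prominence ≥ 3 px, height ≥ 2 px).
   Prominence-based seeding is the load-bearing choice: two touching
   compact cells each keep a prominent distance peak and are split, while
   the ridge along a thin process is never prominent relative to its soma
   and therefore cannot shatter a ramified cell into fragments.  Maximum
   plateaus are labelled with 8-connectivity so a diagonal plateau yields
   one seed, and mask components without any seed become single objects.
4. Objects under 20 px² are discarded (noise specks).

Other segmenters (e.g. a trained deep model) plug in through
`register_backend`; the backend name and perimeter estimator are recorded
with the outputs because the morphotype thresholds are sensitive to both.

Morphometrics use circularity c = 4πA/p² with the Crofton (4-direction)
perimeter estimator.  The naive boundary-step estimator overestimates
perimeters of rasterized disks by up to ~30%, biasing c far below 1 and
pushing genuine disks under the round threshold; Crofton is low-bias and
rasterized disks converge to c = 1 as the radius grows.  Classification is
strict: round if c > 0.6, ramified if c < 0.35, otherwise *intermediate*.
Intermediates are excluded from round/ramified counts but retained in the
records, making the treatment of the ambiguous band explicit and
reversible.  Objects touching the image border are kept and flagged.

### 3D centers and distance to the tumor

The (y, x) center of a GAM is the intensity-weighted centroid of its
footprint on the projection.  Its z is the intensity-weighted centroid of
the z-profile summed over the footprint columns, after subtracting the
profile's median: the cell occupies a few slices while the camera floor is
present in all of them, and without the pedestal removal the centroid is
dragged toward mid-stack by several slices.  A profile with two or more
prominent peaks (two cells overlapping in projection) flags the record
`low_confidence`.  An alternative z-estimator (slice of maximum mean
intensity) is selectable; the method used is recorded in the run config.

Distance to the tumor is the anisotropic Euclidean distance transform of
the tumor-mask complement (scipy's EDT with `sampling=spacing`), evaluated
at the center's nearest voxel.  The map is 0 on tumor voxels, so contact
and interior both read 0 μm; there is no signed interior distance.
Distances are center-to-center without sub-voxel surface interpolation —
the error is bounded by half a voxel diagonal (≈ 1.6 μm at the default
spacing), small against the 30 μm proximity scale.  The proximity subset
uses an inclusive cut, d ≤ 30 μm.

### Metric tables and trend tests

The per-movie table has one row per retained frame: tumor volume, round /
ramified / total GAM counts, mean and median distance (NaN when a frame has
no GAMs), and the count within 30 μm.  A frame flagged out-of-focus removes
itself and all subsequent frames.  When the injection time is supplied,
frames are labelled start (24–26 or 114–116 hpi), mid (30–32 hpi) or end
(37–39 or 117–119 hpi).

Trends use the Mann–Kendall test: S = Σ_{i<j} sign(x_j − x_i), τ as the
tie-corrected normalisation.  For tie-free series with n ≤ 10 the two-sided
p-value is exact, computed from the permutation-null distribution of S via
the inversion-count generating function ∏_{i<n}(1 + x + … + x^i); with
ties, or longer series, the tie-corrected variance

    var(S) = [n(n−1)(2n+5) − Σ_j t_j(t_j−1)(2t_j+5)] / 18

with continuity correction feeds a normal approximation.  A constant series
returns S = 0, τ = 0, p = 1.  The median (not mean) distance is the default
trend input, being robust to the skewed distance distributions that arise
when a few GAMs sit far from the tumor.  Group comparisons across cultures
are exported as tidy CSV for external statistics rather than re-implemented.

## IHC pipeline

Pre-stain images are registered onto the stained scan with Harris corners,
BRIEF descriptors, cross-checked matching and a RANSAC-fitted projective
homography; fewer than 4 inliers raises a registration error with
diagnostics.  Background is flattened with the rolling-ball algorithm
(radius 50 px by default; a free parameter since section illumination
varies) and tissue autofluorescence removed by subtracting the registered
pre-stain image, clipped at zero.  Quantile normalization (rank-wise means;
stable-sort rank assignment, quantile interpolation for unequal lengths) is
available to harmonise intensity distributions across sections; applied
per channel across samples by default.

Nuclei are segmented from DAPI by local mean thresholding (window 51 px,
configurable offset), distance-map watershed splitting of touching nuclei,
and a 40 px minimum size.  Labels are expanded by 5 px (growth stops where
competing labels meet) to capture cytoplasmic marker signal, and each
cell's marker expression is summarised by the 95% quantile of its
expanded-mask pixels under the linear-interpolation quantile convention —
markers are not expressed over the whole cell surface, so a high quantile
is more faithful than the mean.

Patient GAL1 scores: SOX2-positive tumor cells are gated per sample (Otsu
on the per-cell SOX2 summaries by default; fixed and quantile rules
available), GAL1 summaries are standardised to Z-scores within each
core/whole-slide sample and trimmed to [−5, 5] to damp outliers, and the
gated cells' scores are averaged per patient.  The standardisation
population is every segmented cell of the sample (default): the score then
measures how strongly tumor cells express GAL1 relative to their section,
which makes it comparable across sections with different staining
intensity.  Standardising within the gated subset alone is offered as an
option but its patient means are centred on zero by construction and carry
no between-patient signal.  A sample with fewer than 2 gated cells or zero
variance in its normalisation population raises an error naming the sample.

## Synthetic data

The generator produces the structures the pipeline assumes, with exact
ground truth, on a default grid of 10 frames × 40 × 256 × 256 voxels at
(3.0, 0.8, 0.8) μm spacing and 20 min frame intervals — the scale of an
overnight confocal recording through a water-dipping objective.

* **Tumor**: a sphere at the grid center whose analytic volume follows
  V_t = V₀·m^t (defaults V₀ = 1×10⁵ μm³, about the volume of a few hundred
  engrafted cells, m = 0.95).  The true volume recorded in the ground truth
  is the analytic value; the rasterized mask realises it on the grid.
* **GAMs**: 12 round + 8 ramified phantoms by default (within the tens of
  GAMs seen per field).  Round phantoms are ellipsoids of 3.4–4.8 μm
  radius, axis ratio ≤ 1.3; ramified phantoms are a 1.6–2.1 μm soma with
  3–4 gently curved processes of 5–7 soma radii length and 1.3 μm tube
  radius, mostly in-plane.  Phantom z-centers snap to slice planes so that
  thin processes rasterize continuously under the coarse 3 μm z-sampling.
  Each phantom's projected circularity is verified with the package's own
  morphometrics operator (rejection sampling): round phantoms must exceed
  0.62 and ramified stay below 0.22, so the generated classes are
  unambiguous under the 0.6/0.35 thresholds with margin for the footprint
  dilation that smoothing and hysteresis thresholding introduce (~+0.12 in
  detected circularity for thin shapes).
* **Distances**: true center-to-surface distances are drawn from a mixture
  (default 50% uniform within 30 μm, 50% uniform in (30, 55] μm — the far
  bound is what fits the field of view), the phantom is placed along a
  random, mostly in-plane direction, and the recorded true distance is
  recomputed per frame from the rasterized phantom's centroid and the
  frame's tumor radius, so it shrinks tumors increase distances.
* **Artefacts and noise**: smooth 3D Gaussian autofluorescent blobs
  (amplitude 60–90, σ 3.5–7 μm) are added to both channels and recorded in
  the ground-truth labels; signal passes through a small PSF blur, Poisson
  shot noise (gain 0.5) and additive Gaussian read noise (σ = 2), giving a
  tumor SNR near 10.
* **Placement** is dart-throwing with bounded retries and projected
  separation constraints (footprints never overlap in projection); an
  overcrowded request raises a `PlacementError` naming the phantom.
* **IHC slides**: touching elliptical nuclei (6–9 px radii; centers allowed
  within 0.95× summed radii), DAPI amplitude 140–180, SOX2 at 120 in the
  designated positive fraction vs 12 elsewhere, per-cell GAL1 means from
  two normals separated by the configured effect (defaults 40 + 30, σ = 8)
  painted over a small nucleus dilation, all on a smooth background that
  the pre-stain image reproduces exactly.

Everything is a pure function of (config, seed); identical inputs are
bytewise identical outputs.

**What the phantoms do not emulate**: real embryo anatomy and vascular
background, GAM migration between frames (phantoms are static; distance
changes come from tumor growth/shrinkage alone), intensity heterogeneity
within cells, embryo drift (a QC flag stands in for focus loss), or the
morphological continuum between round and ramified — real GAMs populate the
intermediate band, which is exactly why the pipeline reports it explicitly.
Passing the recovery suites therefore demonstrates correctness of the
measurement chain under the stated geometric and noise model, not
performance on real movies, where segmentation quality is the binding
constraint and should be validated per dataset with the IoU matching tools.

## Problem sizes in the test suite

The recovery suites run one 10-frame default-grid movie end to end
(autofluorescence removed with the oracle classifier, keeping the run to
seconds; the trained classifier is exercised on a reduced grid where forest
prediction is cheap), 100 seeded Mann–Kendall series of length 16 for power
and type-I behaviour, and 100 seeded two-patient slide pairs for the GAL1
ordering recovery.  These sizes keep the full suite to a few minutes while
leaving each statistical bound with a comfortable margin.

## Known limitations

* The classical GAM segmenter is tuned for well-separated cells typical of
  the phantom fields; dense clusters of ramified cells with interleaved
  processes will under-segment.  The backend interface exists precisely so
  a learned segmenter can replace it without touching measurement code.
* The 3D-from-2D z-inference assumes one cell per footprint; overlapping
  cells are flagged, not resolved.
* Distances are voxel-center EDT lookups; sub-voxel accuracy was not
  pursued (error ≪ the 30 μm proximity scale).
* Rolling-ball correction is exact but O(N·r²); for large slides prefer
  pre-stain subtraction (cheap) and reserve rolling ball for sections
  without a pre-stain image.
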