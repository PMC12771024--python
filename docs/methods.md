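# Methods

This note records the models, conventions and numerical choices behind
`threepmorph`, and what the synthetic phantoms do and do not establish
about real data.

## Coordinate and unit conventions

Volumes are indexed `(z, y, x)` with z = 0 the shallowest plane. Voxels are
0-based and voxel-centered; the physical position of voxel `(k, j, i)` is
`(i·Δx, j·Δy, k·Δz)` μm, and every physical distance is an index difference
times the spacing. Defaults are Δx = Δy = 0.98 μm and Δz = 5 μm, the
sampling of a 512×512 px, 500×500 μm field with a 5 μm axial step. The
reader accepts 8- and 16-bit (and float) TIFF and records the full-scale
intensity per stack rather than assuming a bit depth.

## Vessel morphometry

The unit of analysis is the **segment**: a maximal branch-point-free path
of the skeleton between terminals (branch points, with ≥ 3 neighbors under
26-connectivity, or end points). Paths shorter than 3 skeleton voxels are
discarded as thinning spurs. This is the standard vascular-graph
convention and makes "one midpoint per segment" well-posed for the
inter-vessel distance.

* **Radius and diameter.** The radius at each centerline voxel is the
  Euclidean distance to the nearest background voxel computed **in physical
  units** (anisotropic distance transform with sampling Δz, Δy, Δx). With
  Δz ≈ 5·Δx, voxel-unit distances would misstate radii by up to 5×
  depending on vessel orientation, so the physical-unit choice is load-
  bearing. Diameter is twice the median radius along the segment; the
  even-count median is the midpoint average. No exclusion is applied near
  branch points.
* **Length and tortuosity.** Length is the sum of consecutive Euclidean
  distances along the centerline; tortuosity is length over the endpoint
  chord (undefined for closed loops, reported as NaN). In the measurement
  chain the voxel path is first smoothed with a centered moving average
  (window 15 points, ≈ 3× the axial spacing at these samplings) before
  length/tortuosity are evaluated: a raw 26-connected digital path
  overestimates arc length by up to ~8% at oblique angles (and stair-steps
  by a full Δz where a vessel crosses planes), which would bias the
  tortuosity of a straight vessel well above 1. The window attenuates
  these quantization artifacts while leaving genuine curvature at the
  scale of tens of micrometres essentially intact; the standalone
  `vessel_length` / `vessel_tortuosity` functions operate on the points
  they are given, unsmoothed.
* **Skeletonization.** 3D topological thinning (Lee). One practical repair
  is applied: at 5 μm axial sampling, a capillary of ~2 μm radius occupies
  a single plane, and 3D thinning deletes such one-plane components
  entirely. Components that lose all skeleton voxels are re-thinned
  per-plane in 2D and merged back, preserving mask connectivity.
* **Total vascular volume** is the exact identity
  `N_foreground · Δx·Δy·Δz` — no smoothing or meshing.
* **Inter-vessel distance** uses the unweighted mean of each segment's
  skeleton coordinates as its midpoint and reports, per segment, the
  minimum distance to any other midpoint. It requires ≥ 2 segments.
* **Baseline segmentation and QC.** The built-in segmenter is a global
  Otsu threshold with two robustness measures for the extreme class
  imbalance of vascular volumes (foreground well under 1%): the threshold
  is recomputed on the above-threshold subset until the foreground
  fraction is plausible (≤ 20% by default), and a per-plane 3×3-cross
  binary opening strips the single-pixel noise halo without touching
  one-plane-thick structures. Components under 27 voxels are dropped.
  Masks from external segmenters can be imported instead and flow through
  the identical metric chain. Either way, a Dice coefficient against
  manual annotation below 0.70 flags the stack for manual correction.

## Plaque morphometry

Semi-automatic segmentation thresholds the whole volume with multilevel
Otsu (4 thresholds, 5 classes) and keeps the top two classes. Because
plaques are a sparse bright minority, the thresholds are recomputed on the
above-threshold subset whenever they capture more than 5% of the volume
(the same imbalance phenomenon as for vessels); if no plaque-like sparse
foreground exists at all, an empty labeling is returned with a warning.
Cleanup is per 2D plane — removal of objects under 5 px, hole filling with
a 3×3 cross — followed by 26-connected 3D labeling, matching a 2D-then-
stack workflow. A fully manual route labels an externally edited mask
directly.

The 49 μm² area filter removes a 3D component iff its **maximum
single-plane cross-sectional area** (pixel count × Δx·Δy) is strictly below
the threshold. The criterion is stated in μm² yet applied after 3D
labeling; the maximum-slice reading keeps the units literal. A summed-area
alternative is config-selectable (`plaque_area_filter_mode: total`).
Retained labels are re-indexed from 1, making the filter idempotent.

Per-plaque volume is Σ(slice areas) × Δz; the reported radius is the
equivalent-sphere radius `(3V/4π)^{1/3}`. Centroids are unweighted voxel
means in physical units, and nearest plaque-to-vessel distance is the 3D
Euclidean distance from the centroid to the nearest vessel foreground
voxel center (KD-tree; verified against a full scan).

## Preprocessing

The chain order is fixed: equalize → crosstalk-correct → dura-remove →
normalize → denoise.

* **Equalization** is per-plane CLAHE (clip limit 0.01, 8×8 tiles),
  rescaled to full scale; constant planes pass through.
* **Crosstalk** is modeled as a single scalar per channel pair,
  `observed_A = A + α·B`, and removed by clamped subtraction. The "auto"
  estimator median-subtracts both channels (robust background removal),
  selects source voxels above both the 99th percentile and a sparse-aware
  Otsu cut, and takes the median of per-voxel ratios. The median makes the
  estimate insensitive to voxels where the target's own structures overlap
  bright source voxels (e.g. a vessel crossing a plaque); on noiseless
  mixtures the recovery is exact.
* **Dura removal** drops planes above a boundary given explicitly or
  located from the THG channel: the deepest plane in the top 20% of the
  stack whose mean intensity exceeds the global mean + 2 SD, plus one. The
  top-20% restriction prevents deep bright planes from being misread as
  dura.
* **Normalization** maps each plane's [min, max] linearly onto the range of
  the reference plane — the deepest plane whose maximum is at most 95% of
  full scale (the deepest plane if none qualifies). A constant reference
  plane passes the stack through with a warning; this arises in phantoms
  whose structures do not reach the deepest plane, and in such cases
  normalization is a no-op by design.
* **Denoising** is a radius-1 3D median filter: edge-preserving and
  appropriate for tubular structures, though it erodes structures only one
  plane thick — which is why the baseline segmenter does not require a
  denoised input.
* **Motion assessment** (no correction is applied): each plane is
  binarized (per-plane Otsu by default) and 2D-labeled; structures are
  chained across consecutive planes by maximal pixel overlap with a
  nearest-centroid fallback (≤ 16 px) for frames shifted beyond overlap.
  For up to 5 tracked structures, the shift between consecutive planes is
  the distance between intensity-weighted centroids, in pixels. The
  statistic is meaningful for penetrating (near-axial) vessels, whose
  cross-sections are stationary across planes; oblique vessels drift
  geometrically and are not valid motion probes.

## Image quality

Signal strength of a frame is the mean of its k brightest pixels,
k = max(1, ⌊0.005·N⌋). SBR of a 1D profile is the mean of the 15 brightest
over the 15 darkest samples (undefined below 30 samples; an all-zero
background yields an explicit infinite value). The default profile is the
image row through the plane's brightest pixel — a line profile through the
brightest vessel. FWHM uses the profile minimum as baseline and locates
half-maximum crossings by linear interpolation; truncated peaks raise. An
effective attenuation length can be fitted as −1/slope of log signal
strength versus depth; the fit assumes the bright-structure pixel count
per plane is constant over the fitted range.

## Between-session statistics

Distribution metrics (per-segment diameter, length, tortuosity, IVD;
per-plaque radius) are compared with an unpaired two-sided Mann–Whitney U
test: U = Σ[a > b] + ½[a = b]. For min(n, m) ≤ 8, tie-free data and at most
200 000 rank assignments, the p-value is exact by full enumeration;
otherwise a normal approximation with tie correction and continuity
correction is used. Under the null at n = m = 20 the measured type-I error
is within [0.03, 0.07] at α = 0.05 over 2000 replicates. Shapiro–Wilk
normality is computed and logged but never gates the nonparametric test.
Scalar totals (vessel volume, plaque volume) are reported as percent
change, 100·(v₂ − v₁)/v₁. Stars follow p < 0.05/0.01/0.001. No
multiple-testing correction is applied by default (Holm adjustment is a
config flag), and no segment-level pairing across sessions is attempted.

## Phantom generator

The generator emulates the acquisition regime the pipeline targets:
tubes rasterized by exact point-to-segment distance in physical μm
(capsule geometry; end caps are negligible for tubes long relative to
their radius), spheres likewise; per-plane intensity scaling
exp(−depth/attenuation length); background offset; Poisson then Gaussian
noise; symmetric linear crosstalk; per-plane integer jitter filled with
background at exposed edges. Truth masks and labels are pre-noise and
pre-jitter. The default study-scale phantom is 256×256×64 at
(0.98, 0.98, 5) μm with five tubes of radius 2–5 μm (one curved) and three
spheres of radius 8–15 μm, attenuation length 300 μm, background 10,
peak intensity 100 — sizes chosen so the full chain runs in seconds while
preserving the anisotropy and sparsity that drive the hard cases.

What the phantoms do **not** model: realistic vascular trees (no
branching hierarchy by default), point-spread blurring, scattering haze,
flat-field inhomogeneity, sub-pixel or non-rigid motion, or
depth-dependent noise. Passing the recovery suite therefore demonstrates
the correctness of the geometry, estimators and statistics — not that any
particular segmenter will reach the same accuracy on real deep-tissue
stacks, where contrast and annotation quality dominate.

## Known limitations

* Diameter is a medial-axis distance statistic; for vessels below ~2
  in-plane pixels of radius it is quantization-limited, and at 5 μm axial
  steps near-axial capillaries are sampled by very few planes.
* Tortuosity of strongly kinked vessels is slightly smoothed by the
  15-point centerline window; reduce `centerline_smooth_window` for
  high-curvature analyses at the cost of digital-path inflation.
* The Otsu-based baseline segmenter is a classical stand-in: it assumes
  bright vessels on a darker background and a histogram with a separable
  signal mode. Externally produced masks are the intended high-quality
  route, with Dice QC either way.
* Inter-session comparisons treat segments as independent samples; spatial
  correlation within a field of view is not modeled.
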