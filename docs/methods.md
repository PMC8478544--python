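# Methods

This note documents the models, conventions and numerical choices behind
`aortamorph`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Grid and unit conventions

Volumes are 3-D fields of linear attenuation in cm⁻¹ on an isotropic
voxel grid (`voxel_size` in mm; the default fixtures use 0.01 mm =
10 µm). Axis 0 is the axial (cranio-caudal) axis and "slice" always
means a plane perpendicular to it. Voxel indices are 0-based with a
voxel-center convention: physical position = index · voxel_size +
origin. Attenuation calibration happens only in `read_volume`
(`units_scale`); all thresholds downstream assume cm⁻¹. Native scanner
archives and DICOM are out of scope; calibrated volumes (NIfTI, TIFF
stack) are the ingestion contract.

## Segmentation model

The workflow exploits the attenuation ordering of PTA-stained tissue:
lumen background < 2.0 cm⁻¹ ≤ stained plaque < 6.0 cm⁻¹ ≤ wall. Both
thresholds are compared inclusively (≥); this is a documented choice —
with continuous-valued reconstructions the boundary set has measure
zero, but inclusivity is applied consistently.

All "distance = n voxels" morphology uses a Euclidean ball of radius n,
implemented by thresholding an exact Euclidean distance transform
(equivalent to an explicit ball structuring element, faster at larger
radii). One deliberate exception: the ROI shell erosion is performed
**in-plane, slice by slice** (a 2-D Euclidean disc). The ROI is defined
per axial slice by the contouring process; a 3-D ball erosion would also
erode the first and last contoured slices axially and cap the vessel,
and would make the first/last ROI slices empty on every valid input.
The lumen closing, plaque opening/closing and lesion adjacency are 3-D.

Interior extraction uses 6-connectivity with largest-component
selection (ties resolved by raster-order labeling). The lumen closing
runs in a padded bounding box so it is never clipped at array borders,
and the final lumen is re-intersected with the ROI interior (the ROI
eroded by the shell width), so the lumen can never touch the ROI
border. In the wall/lumen composition, voxels claimed by both the wall
draft and the lumen (wall-bright plaque) are assigned to the lumen:
the lumen is the *anatomical* lumen bounded by the inner wall and
contains the plaque, which keeps all percentage fractions ≤ 100.

Plaque smoothing uses a Gaussian kernel of width σ (voxels) truncated
at the `support` radius and renormalized to unit sum; the default
(0.8, 1) pair is a 3×3×3 kernel. The minimum-volume filter removes
26-connected components smaller than 2% of the *post-opening* total
(scale-free; the filter runs after the complete opening). After the
closing, the plaque is re-intersected with the lumen so refinement
cannot push plaque into the wall. Lesions are exactly one voxel thick
(face adjacency to the wall), pairing with the 50% rule for the lesion
surface (one side of a quasi-planar sheet).

Manual lumen verification is exposed as voxel-patch add/remove inputs
applied between void-filling and composition (additions are clipped to
the ROI interior), keeping the pipeline scriptable and deterministic:
identical inputs give byte-identical reports.

## ROI interpolation

Sparse contours are rasterized (a voxel belongs to the interior when
its center lies inside or on the polygon) and interpolated by
shape-based blending: signed Euclidean distance fields of the two
bounding rasterizations (negative inside) are blended linearly in
fractional slice position and thresholded at ≤ 0. The fields are
sampled in centroid-aligned frames, i.e. each field is translated to
the interpolated centroid before blending, so contours that both change
radius and move in-plane (a curved vessel) interpolate smoothly without
any vertex correspondence. Contoured slices reproduce their
rasterization exactly. Interpolation is linear in slice position — the
simplest documented choice.

Branch ostia are genuine holes in the vessel wall; the manually drawn
ROI contour (tight around the outer wall) is the closure mechanism: the
2-voxel inner shell of the ROI bridges the gap so the lumen cannot leak.

## Quantification numerics

* **Volumes** are exact voxel counts × voxel_size³.
* **Surfaces** triangulate the 0.5 iso-level of the binary field after
  a 1.0-voxel Gaussian anti-aliasing blur. Raw binary marching cubes
  overestimates a digitized sphere's area by ~8.5% (staircase effect,
  roughly scale-independent); with the blur the error is ≲ 0.5% at
  radius 20 voxels and decreases with radius. Masks too thin for the
  softened field to reach 0.5 (single voxels, one-voxel sheets) fall
  back to the raw binary surface, which for flat sheets is accurate to
  the rim contribution (~1/r). Slice perimeters use the analogous
  anti-aliased 2-D iso-contour.
* **Lesion length** per slice is the summed length of lumen iso-contour
  segments whose midpoints lie within 1.5 voxels of a lesion voxel —
  an explicit approximation, since a 2-D lesion-length definition is
  not part of the segmentation model.
* **Wall thickness** is model-independent local thickness: each wall
  voxel receives the diameter of the largest inscribed sphere
  containing it. Sphere radii are taken as EDT − 0.5 voxel (distance
  from the voxel center to the interface halfway between foreground and
  background centers): a 5-voxel slab then reads exactly 5 voxels and a
  1-voxel sheet exactly 1. Even-width structures read one voxel thin
  (the optimal sphere center falls between voxel centers); the bias is
  bounded by one voxel.
* Per-slice plaque areas integrate exactly back to the plaque volume
  (both are voxel counts), which is asserted in the tests.

## Synthetic phantoms

The phantom generator emulates the *imaging situation*, not the
physics: a tube (straight or circular-arc centerline) with a
high-attenuation wall (8.0 cm⁻¹), low-attenuation lumen/background
(0.5 cm⁻¹), crescent plaques (3.5 cm⁻¹) attached to the inner wall,
optional wedge-shaped branch gaps in the wall, Gaussian blur as a
partial-volume stand-in, and additive Gaussian noise. The attenuation
values are synthetic fixture constants chosen to straddle the two
workflow thresholds; they are not measured PTA values.

Plaques are circular-segment prisms: the lumen cross-section region
beyond a chord at depth d, oriented at a chosen angle. Closed-form
volumes: segment area A = R²(α − sin α)/2 with α = 2·arccos((R−d)/R),
times the axial span for straight tubes; for arc centerlines the Pappus
rule is used (A times the path length of the segment centroid). The
lumen volume is πR²L with L the centerline arc length. Ground truth
masks are the rasterized **pre-blur** geometry, so recovery errors
honestly include partial-volume effects.

The tube center sits deliberately off the voxel lattice (fractional
offsets) and the default radii are non-round: real vessels never align
with the reconstruction grid, and lattice-aligned interfaces alias the
rasterized volumes by several percent. With the off-lattice defaults
the rasterized masks agree with the closed-form volumes to better than
2% at the fixture orientations; chord boundaries at lattice-resonant
orientations (e.g. 45°) can still alias by up to ~7% at this
resolution — an inherent property of crisp voxel-center rasterization,
which is why the recovery checks use the documented fixture geometry.

Fixture levels (fixed specs, default grid 120×64×64 at 10 µm, tube
length ~1.04 mm, lumen radius 14.3 voxels, wall 4.1 voxels — sized so a
full pipeline run takes ~1.5 s and a phantom sweep stays within a
desktop time budget):

* `clean` — one plaque (depth 8.3 voxels, span 0.5 mm), no blur/noise.
* `blurred` — + σ = 0.8 voxel blur.
* `noisy` — + noise sd = 5% of the wall attenuation (0.4 cm⁻¹).
* `branch` — arc centerline (radius 2 mm) with a 60° wall gap, blur and
  noise as `noisy`.
* `confounded` — the plaque's interior (eroded 2 voxels from all plaque
  boundaries) is set to 6.5 cm⁻¹, above the wall threshold: the core
  thresholds like wall and punches a void into the lumen draft, which
  the 5-voxel closing must absorb. This emulates heavily stained plaque
  cores with less-stained shoulders; a core in full contact with the
  wall would instead merge with the wall draft and is a documented
  failure mode requiring manual correction, as in real specimens.

What passing these tests shows: the chain of morphological operations
is implemented exactly (voxel-exact against brute-force references),
and the estimators recover known geometry within stated bands under
blur and noise. What it does not show: performance on real PTA scans
with beam hardening, reconstruction artifacts, collapsed or touching
vessel segments, staining gradients, or plaque attenuation overlapping
the wall over its whole extent — those require scanner data and manual
intervention.

Measured recovery on the fixtures (recomputed by
`scripts/acceptance.py`): clean lumen and plaque volumes within 5% of
the closed forms; with blur and noise within 10% (the lumen grows
~+7% because partial volume shifts the ≥ 6.0 cm⁻¹ boundary into the
wall; the plaque stays within 1%); a sweep of plaque depths gives a
measured-vs-analytic regression slope within [0.9, 1.1] with
r² ≥ 0.95. The systematic plaque deficit of a few percent is the
1-voxel opening, which also strips the bright partial-volume shell
along the wall — the same wall/plaque confound and slight
underestimation expected of the workflow on real data.

## Agreement statistics

`agreement(a, b)` fits OLS of the method under test (b) on the
reference (a) — reference on the x-axis, a documented choice — and
reports bias (mean difference), limits of agreement bias ±
multiplier·sd with the classic 1.96 multiplier (configurable), and the
count of pairs outside the limits. `paired_pipeline_validation` averages
repeated manual readings per section (triplicate design) before
comparison. A one-way ANOVA utility is provided for group comparisons
of specimen reports; animal-study analyses themselves are out of scope.

## Interfaces

The library is the primary interface; the `aortamorph` CLI wraps it
with subcommands `roi`, `segment-wall`, `segment-plaque`, `quantify`,
`phantom`, `validate`, `run`. All CLI defaults equal the workflow
parameters (6.0, 2, 5, 0.8, 1, 2.0, 1, 0.02, 3). The pipeline writes a
run manifest (all parameters + SHA-256 of inputs) for reproducibility.

## Known limitations

* No automatic branch-ostium detection beyond the ROI-shell closure; no
  deformable or learned segmentation.
* Lesion length in 2-D is a band approximation (above).
* Local thickness reads even-width structures one voxel thin.
* Surface estimates of one-voxel sheets fall back to the raw binary
  triangulation and carry its staircase overestimate.
* The phantom is not an X-ray simulation: no beam hardening, cone-beam
  artifacts, or projection/reconstruction noise correlation.
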