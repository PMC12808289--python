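# Methods

## The measurement model

The pipeline reproduces, as deterministic operators, a semi-automatic
workflow for quantifying medial-clavicle maturation from CT:

1. **Load / crop / resample.** Input volumes (DICOM series, NIfTI, NRRD)
   are interpreted in LPS physical coordinates; voxel `(i,j,k)` is centered
   at `origin + direction @ (spacing · index)` with 0-based indices and
   half-open crop boxes. The region of interest is cropped without
   resampling, then resampled once to an isotropic lattice (default: the
   minimum input spacing, linear for HU, nearest-neighbour for labels).
   DICOM series are validated for even slice spacing (relative tolerance
   1e-3) and rescaled to HU via slope/intercept.
2. **Threshold.** Bone mask at ≥ 300 HU, boundary inclusive. 300 HU
   separates mineralized bone from soft tissue on clinical CT.
3. **Grow from seeds.** Painted seeds (one or more per structure:
   metaphysis, each ossification center, fusion area) are grown through
   the mask; each mask voxel takes the label of the geodesically nearest
   seed (chessboard metric, 26-connectivity, paths confined to the mask),
   ties to the smaller label id. With disjoint structures this is an exact
   per-component flood fill; across fusion bridges the boundary falls
   midway between the seed sets, so seeds should be painted densely (the
   phantom's `suggest_seeds` paints the eroded structure interior on every
   other voxel). Seeds that fall outside the mask — e.g. a painted voxel
   pushed under threshold by noise — are dropped by default; a structure
   losing all its seeds is an error.
4. **Solidify.** Internal cavities (background 6-connected components with
   no path to the grid border) whose 26-neighbourhood touches exactly one
   label are filled with that label. Complementary connectivities (6 for
   background, 26 for foreground) avoid topological paradoxes.
5. **Component labeling.** Voxels with the ossification-center role are
   split into 26-connected components; the component count is the reported
   number of ossification centers (norm-variant detection).
6. **En-face alignment.** The viewing axis is the unit vector from the
   distal centerline endpoint (inside the metaphysis) to the proximal one
   (anterior to the epiphysis). The in-plane basis takes the grid axis
   least parallel to the view axis, orthogonalized against it
   (Gram–Schmidt), with the second vector completing a right-handed triad
   — deterministic and free of gimbal degeneracy; for an axis-aligned
   centerline it reproduces the remaining grid axes. The alignment check
   accepts a view when the two endpoints project within one pixel of each
   other (the "line collapses to a point" criterion); a frame built from
   the centerline passes by construction.
7. **Silhouettes and area ratio.** Labeled voxel centers are projected
   orthographically onto the image plane and binned into a pixel lattice
   (default pixel = voxel size) whose phase is anchored to the projected
   voxel lattice. Binning centers — rather than intersecting rays with
   voxel cubes — keeps the area estimate free of an orientation-dependent
   half-voxel dilation (a cube-intersection silhouette is ~3% large for
   oblique views). Epiphysis (centers + fusion area) and metaphysis are
   projected independently from the same frame, so occlusion cannot bias
   either area; the ratio uses raw pixel counts and is therefore
   resolution-free by construction.
8. **Cross-section profile.** Axial positions start at the proximal
   surface of the metaphysis (outermost voxel center plus half a voxel —
   voxels are cells, so the material boundary lies half a cell beyond the
   outermost center) and increase distally in steps of 0.5 mm. Each
   position owns the slab of metaphysis voxel centers within half a step
   of it: area = count · voxel volume / slab width, diameter = greatest
   in-plane caliper (max Feret, convex-hull accelerated) across the slab's
   projected centers plus one voxel footprint.
9. **Distal cut and volumes.** The metaphysis ends one third of a radius
   distal to its greatest diameter: `cut = s* + d_max/6`. Ties resolve to
   the most proximal position (the conservative, smallest-metaphysis
   choice); since measured Feret diameters are quantized at the
   voxel-footprint scale, diameters within one footprint of the maximum
   are treated as tied. Voxels whose centers lie distal to the cut plane
   are clipped; the combined volume (metaphysis + centers + fusion), the
   metaphysis-only volume after erasing the epiphyseal structures, and the
   epiphysis volume by subtraction are all voxel counts times voxel
   volume, so `V_meta + V_epi = V_combined` holds exactly and a negative
   subtraction raises an error rather than being clamped.

A fully fused clavicle (no voxels with an epiphyseal role) yields
`assessable = False` with both ratios as explicit non-values; an empty
epiphysis silhouette with epiphyseal labels present yields an area ratio
of 0 (the pre-ossification analogue).

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_hu` | 300 HU | bone threshold, inclusive |
| `target_spacing_mm` | min input spacing | isotropic working resolution |
| `pixel_size` | working spacing | silhouette pixel size (cancels in the ratio) |
| `profile_step_mm` | 0.5 mm | axial sampling of the cross-section profile |
| `en_face_tol_pixels` | 1 px | endpoint-separation tolerance of the alignment check |
| `drop_seeds_outside_mask` | on | discard painted seeds not in the threshold mask |

## The phantom generator

The phantom emulates the features the measurement must cope with, with
closed-form constructive-solid-geometry ground truth independent of the
rasterization:

- a 40 mm shaft tapering linearly from 5.5 to 5 mm radius, with a
  metaphyseal flare `(1 − (s/6 mm)²)²` raising the end-plate radius to
  10 mm (a 20 mm greatest diameter). The flare has zero slope at the face:
  a rounded rim, like real end-plates — a knife-edged rim would make the
  analytic greatest diameter a measure-zero plane that no finite
  resolution could measure;
- 1..k ellipsoidal ossification centers proximal of the face (default: one
  lens of 4×6×6 mm semi-axes with a 1 mm unfused gap); optional
  cylindrical fusion bridges (radius = `fusion_fraction ·` smallest
  in-plane semi-axis) whose volume is exactly `π r² · gap` on a flat face
  (the ellipsoid never protrudes past its pole plane) and a quadrature
  term where a concavity is present;
- an optional paraboloid "bowl" concavity (void volume `π·depth·r²/2`),
  the fish-mouth norm variant;
- an optional circular bend of the shaft axis (shaft volume via arc-length
  integration, exact by Pappus; the planar-cut truths are then approximate,
  so quantitative validation uses straight shafts);
- HU rendering at bone 700 / center 500 / soft tissue −50, Gaussian
  partial-volume blur (default σ 0.5 mm), additive white Gaussian noise
  (default SD 50 HU) from an explicit integer seed — same spec and seed
  give bit-identical volumes. The truth label grid carries no blur or
  noise.

HU levels are chosen so the 300-HU threshold separates bone from soft
tissue but blur can push thin partial-volume shells under threshold — the
realistic failure mode (see limitations). `scaled(f)` scales all lengths
*including* voxel spacing (the dimensionless-markers claim), while HU,
blur and noise stay fixed as scanner properties. `stage_series` produces
a developmental sequence (growing centers, increasing fusion) whose
analytic volume ratios are strictly increasing.

What the phantom does **not** emulate: cortical/trabecular internal
structure, beam hardening and metal artifacts, anisotropic clinical voxels
(the pipeline resamples, but the phantom is rendered isotropic), soft
tissue other than a uniform background, and population shape variability.
Passing tests therefore demonstrate correctness of the measurement chain
under controlled geometry, not clinical accuracy.

## Numerical conventions

- Axial profile coordinate: 0 at the proximal surface of the profiled
  structure, increasing distally; the cut plane is anchored through this
  coordinate, so the absolute plane position is independent of the anchor
  up to the profile's sampling quantization.
- Tie-breaks: equal geodesic distances → smaller label id; (near-)equal
  greatest diameters → most proximal plane.
- Silhouette pixel lattice anchored to the projected voxel lattice to
  avoid systematic rounding ties at half-voxel phase offsets.
- Degenerate inputs raise typed errors (config 2, alignment 3,
  consistency/labels/seeds 4, I/O 5 as CLI exit codes) rather than
  producing numbers.

## Validation summary

The test suite checks every operator against an independent oracle
(exhaustive threshold scan, multi-source BFS growth, border-flood cavity
detection, analytic sphere/cylinder/rectangle measures), and the full
pipeline against phantom ground truth. At 0.4 mm voxels the noise- and
blur-free reference phantom is recovered within ~1% (area ratio) and ~4%
(volume ratio); both ratios shift ≤2% under isotropic rescaling ×0.8/×1.25
and ≤3% under a 3-axis rigid rotation of the whole scene; three-center and
concavity variants segment with the correct component counts; measured
volume ratios increase strictly along the developmental series.

## Known limitations

- **Partial-volume bias on thin ossification centers.** With clinical-like
  blur (σ = 0.5 mm), thresholding a 500-HU center against −50-HU
  background at 300 HU erodes the segmented surface by
  `σ·Φ⁻¹(350/550) ≈ 0.17 mm` plus a curvature-dependent term. For a lens
  a few mm thick this depresses the measured epiphysis volume by ~10–13%
  and the volume ratio by ~15% relative to the blur-free geometry; blur
  also shifts the apparent greatest-diameter plane slightly distally. The
  area ratio is far less affected because numerator and denominator erode
  together. This is a property of threshold segmentation at these contrast
  levels, not of the implementation; clinical volume ratios should be
  interpreted as systematically conservative for small centers.
- The grow-from-seeds boundary across a fusion bridge is the geodesic
  midline between seed sets, not an intensity-derived interface; dense
  painting near the interface bounds the misassignment.
- The distal-cut position is quantized by the 0.5 mm profile step and the
  voxel-footprint tie band (≈ ±2–4% metaphyseal volume at 0.4 mm voxels).
- Centerline placement is operator input; only the single-point en-face
  criterion is checked numerically, not the endpoints' centrality.
- Correlating the ratios with chronological age (reference intervals,
  staging) is out of scope; the package produces the markers, not age
  estimates.
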