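# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `exmorph`, in the spirit of a software methods section.

## Segmentation post-processing

A probability volume (values in [0, 1], axis order (z, y, x), voxel spacing
in µm supplied explicitly) is binarized at a **strict** threshold: a voxel is
foreground iff `p > t`, default `t = 0.7`. Connected components with
**fewer than** `min_voxels` voxels (default 256) are then removed; a
component of exactly 256 voxels is kept. Both inequalities are deliberate
and tested, since off-by-one differences here change every downstream
metric. Connectivity defaults to 26 (thin curvilinear axons traverse
diagonal voxel steps; 6-connectivity would fragment them); 6 and 18 are
available. Components touching the volume border are retained — densities
are reported per image with no border correction.

Integer TIFF inputs are rescaled by the *dtype* maximum, never the per-image
maximum, so a threshold of 0.7 means the same intensity fraction for every
image. Voxel spacing comes from the caller, not from TIFF tags, whose
dialects are unreliable.

## Morphometry

* **Volume fraction** is a voxel-count ratio; spacing cancels.
* **Skeletonization** uses deterministic 3D medial-axis thinning (Lee-style,
  via scikit-image), with no branch pruning. The skeleton voxels are
  organized into a **minimum spanning forest** of their 26-adjacency graph,
  edges weighted by the physical center-to-center distance. A spanning
  forest reduces to the consecutive-step sum on simple digital paths while
  avoiding the double counting that a raw adjacency sum produces wherever
  three skeleton voxels form a clique.
* **Length measurement.** Summing raw voxel-step weights systematically
  overestimates the length of oblique or curved structures — a digital
  staircase is longer than the line it approximates, by up to ~16% in our
  cylinder experiments. Each maximal degree-two chain of the forest is
  therefore measured as a polygonal line through every 4th voxel (junctions
  and endpoints always included). Axis-aligned paths are measured exactly;
  the residual bias on oblique straight tubes is below ~1%, and a gentle
  4-voxel chord cuts curves too slightly to matter at the tortuosity of
  axonal fibers. The uncorrected sum remains available
  (`SkeletonGraph.raw_length_um`) for auditability.
* **Mean radius** is the Euclidean distance transform of the mask (physical
  distance to the nearest background voxel, anisotropy-aware via the scipy
  EDT `sampling` argument), read out at every skeleton voxel and averaged
  with equal weight across all components pooled. No half-voxel correction
  is applied; the value is reported exactly as the EDT-at-skeleton mean.
* **Tissue units.** For linear expansion factor `f`: lengths divide by `f`,
  so the radius maps as `r̄/f` and length density as `ρ_L·f²` (skeleton
  length shrinks by `f`, the reference volume by `f³`); the volume fraction
  is dimensionless and unchanged. Both image- and tissue-space values are
  always reported so the convention is auditable. Default spacing is
  isotropic 1 µm/voxel; anisotropic spacing (e.g. a coarser light-sheet
  z-step) is honored in the EDT, the edge weights and the volume term, and a
  spacing-blind variant is available through the CLI `--assume-isotropic`
  flag.

### Numerical caveats

* Medial-axis thinning processes the six face directions in a fixed order,
  so it is deterministic but **not exactly equivariant under axis
  permutation**: transposing a volume changes the skeleton metrics at the
  ~1% level (volume fraction is exactly invariant). Tests bound this at 2%.
* The scikit-image 3D thinning can annihilate perfectly symmetric
  even-width objects (a 2×2×L bar thins to nothing). Structures at
  continuous random positions — phantoms, and real probability maps — do not
  hit this configuration; regression tests use odd cross-sections through
  voxel centers.
* An empty mask yields an all-zero result with an explicit `empty` flag
  rather than NaNs.

## Expansion-factor estimation

Scale-invariant (SIFT) keypoints are detected on both images (after
min/max normalization), descriptors matched with a Lowe ratio test
(threshold 0.75, cross-checked), and a similarity transform fitted with
RANSAC (reprojection threshold 3 px, ≥10 inliers, seeded sampler, default
seed 0, final least-squares refit on the consensus set). The scale is
extracted as `√det` of the 2×2 linear block — exact for a similarity and
robust to tiny numerical shear; a negative determinant (reflection) is
treated as failure. All failure modes (blank image, too few keypoints /
matches / inliers, degenerate fit) raise an error carrying the diagnostic
counts; the estimator never returns a silent number. The knob values are
conventional defaults, configurable via `MatchingParams`. Across synthetic
pairs with scales 2–4.5 and rotations to 30°, recovery is within ~0.2% and
forward/reverse estimates are reciprocal within well under 1%.

The mean ± SEM summary over image pairs reports SEM = 0 with `n = 1`
(flagged by the returned count) rather than NaN, keeping tabular outputs
numeric.

## Patch/matrix analysis

ROIs are consumed as integer-labeled mask images: label *k* in the patch
file pairs with label *k* in the matrix file (the matrix ROI is the patch
ROI moved into matrix territory). Each pair contributes the **ratio of mean
intensities** (not the mean of pixel ratios); pairs with a zero matrix mean
are excluded with a warning and counted. Patch area fraction is the union
area of patch masks over the reference region area. Per-pair ratios are
always reported so downstream aggregation (per section, per animal) stays in
the user's hands.

## Optical fractionator

`N̂ = ΣQ⁻ · interval · (grid_x·grid_y / frame_area) · (thickness / dissector)`.
Defaults mirror a standard midbrain design: every 6th section, 60×60 µm²
frame on a 150 µm grid, 10 µm dissector, 2 µm guard zone. The guard zone is
recorded as metadata only — the estimator algebra uses just dissector height
and the *measured mounted* section thickness, which is a required user input
(cut thickness is not a substitute; tissue shrinks on mounting). No
Gundersen coefficient-of-error estimation is provided.

## Synthetic data: what it emulates, and what it does not

**Axon phantoms.** Centerlines are persistent random walks (unit step half a
voxel; direction re-drawn each step from the previous direction plus a
Gaussian kick of s.d. `0.25·tortuosity`, von-Mises-like; `tortuosity = 0`
gives straight lines). Walks are confined to an inner box one radius plus
one voxel inside every face, so the rendered tube — all voxels whose center
lies within the radius of the densely resampled polyline, i.e. a capsule —
sits fully inside the field of view and the polyline length is exact ground
truth. Tubes shorter than half the smallest volume extent are rejected:
the phantom emulates axons traversing an imaging crop, not terminating
inside it. Axons are placed by rejection sampling with a clearance test
(distance from the candidate centerline to previously placed tubes must
exceed radius + 1 voxel), which keeps tube voxel supports disjoint and
non-touching so ground truth stays additive and thinning never fuses two
armatures; after 3000 failed attempts per axon the generator raises rather
than silently under-filling. Feasible density falls with radius: ~30 tubes
at radius 2 voxels fit a 64³ volume, only ~5–6 at radius 5–6.

The probability map is 0.95 on tube voxels and 0.2 background (a confident
CNN-like output cleanly split by the 0.7 threshold), plus optional Gaussian
noise (default s.d. 0.02) and clipping to [0, 1]. Randomness flows through
per-axon substreams of the master seed, so adding axon *n+1* does not
perturb axons 1..*n*, and identical spec + seed is bit-identical.

Defaults (64³ voxels, isotropic unit spacing, 10 axons of radius 3, ~4–5%
volume fraction) match the scale of inference crops used with 3D axon
segmentation networks. Not modeled: optical PSF, light-sheet striping,
anisotropic gel distortion, axon branching, boutons and caliber variation
along fibers. Passing the recovery tests therefore demonstrates the
correctness of the measurement chain on clean tubular geometry, not
performance on degraded real microscopy data.

**Expansion pairs.** A multi-scale filtered-noise texture with added
Gaussian blobs (feature-rich at several scales, as SIFT needs) is resampled
under an exactly known similarity transform (cubic interpolation); the true
transform is returned for comparison. Real pre/post pairs additionally
differ by non-uniform gel distortion, illumination changes and
repositioning; none of that is simulated, so estimator validation here
addresses the geometric fitting, not robustness to acquisition differences.

**Compartment images.** Non-overlapping ellipses at `patch_intensity` on a
uniform `matrix_intensity` background, paired with displaced congruent
matrix ROIs kept 3 px clear of every patch; the noiseless measured ratio
equals the constructed intensity ratio exactly.

## Problem sizes

Validation runs use 20 phantoms at 64³ spanning radii 2–6 voxels and 5–30
tubes per volume, straight digital cylinders of length 240 voxels for the
closed-form radius/length checks, and ~160² pre-expansion textures (scaled
up to ~720² post images) for the registration checks — sizes chosen so the
full suite and the acceptance script each run in about a minute on one CPU
while still exercising every code path at realistic geometry.
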