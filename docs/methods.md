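# Methods

This note documents the models, conventions and numerical choices behind
`orthofusion`, in the order the pipeline uses them.

## Geometry model

A `VoxelGrid` is defined by shape, per-axis spacing (mm), world origin and
a 3×3 orthonormal direction matrix whose columns are the world directions
of the grid axes. The origin is the world position of the **center** of
voxel (0,0,0), matching the NIfTI/MetaImage header convention, and the
sampleable domain is the voxel-center hull (continuous indices in
[0, shape−1]). Everything downstream treats axial, coronal and sagittal
acquisitions as differently-oriented grids in one right-handed mm world
frame; registration between them is pure resampling — header geometry is
trusted verbatim, which is appropriate for volumes reconstructed from one
scan session and is the package's stated scope (no registration
estimation).

Sampling is trilinear. Continuous indices within 1e-9 of an integer are
snapped to it, so sampling exactly at a voxel center returns the stored
value bit-for-bit and identity resampling is exact. Out-of-hull samples
are never extrapolated; they are flagged in a validity mask, because the
fusion step must know true coverage per voxel. Large-grid resampling runs
through `scipy.ndimage.affine_transform` (order 1, no prefilter), which is
mathematically the same trilinear interpolation with the coordinate
generation done in C.

Intensities are carried as float regardless of on-disk dtype; quantization
happens only on write when an integer dtype is requested.

## Phantom

The phantom emulates the relevant anatomy at the level the metrics need:
ellipsoidal "vertebral bodies" with a bright cortical shell (default
1200 HU), dimmer trabecular core (300 HU) and soft-tissue background
(0 HU). Two coaxial bodies separated by a 1.2 mm gap stand in for a facet
joint: the gap is narrower than the 3 mm clinical slice thickness, so it
is exactly the structure thick-slice volumes lose and fusion should
recover. The default grid is 128³ at 0.6 mm isotropic, mirroring a
high-resolution clinical reconstruction.

The cortical shell is the region between the body ellipsoid and an inner
ellipsoid whose semi-axes are shrunk by the cortical thickness (1.5 mm).
This is an approximation to a constant-thickness shell — the exact
Euclidean distance to an ellipsoid has no closed form — and is accurate
where the semi-axes are large relative to the thickness, which holds for
the default geometry.

Partial volume is modelled by 3×3×3 subvoxel supersampling of the analytic
shape before noise; without it, down-sampling artefacts are unrealistically
benign. `supersample=1` yields a pure three-level phantom, used where a
test needs exact intensity levels. Noise is i.i.d. Gaussian per voxel
(default σ = 25 HU, a realistic soft-reconstruction noise level), seeded:
generation is a pure function of (spec, seed). No CT physics (beam
hardening, streaks, dose) is simulated — the phantom exercises the
pipeline and metrics, it does not validate performance on real scanner
artefacts, and conclusions from phantom runs transfer to real data only in
direction, not magnitude.

Ground-truth masks mark voxels whose subsampled inside-fraction is ≥ 0.5.
Evaluation masks are Euclidean-ball dilations (exact distance transform,
anisotropic spacing honoured) of the union mask, default margin 1.2 mm, so
the masked metrics see the bone surface and its immediate neighbourhood.

## Clinical degradation

A thick-slice acquisition is simulated along one axis by convolving with a
Gaussian slice-sensitivity profile and sampling slice centers spaced by
the target thickness (default 3 mm), the first output center coinciding
with the first source center (deterministic geometry; output slice count
is floor(span/thickness)+1). The blur magnitude is a free parameter: the
FWHM defaults to the slice thickness (σ = thickness/2.355), the standard
slice-profile approximation, and is exposed as `blur_fwhm` so users can
match their scanner. Weights are normalized per output slice, so constants
are preserved exactly and no value leaves the source range. A thickness
equal to the source spacing with zero blur degenerates to the identity,
which is the pipeline's no-degradation limit.

The resliced comparison case uses 1-D Lanczos interpolation (kernel
sinc(x)·sinc(x/a), support a = 3 — the common imaging default) along the
through-plane axis only, with weights renormalized to unit sum near the
boundaries. The kernel's negative lobes may overshoot near edges; this is
intentional and documented, not clamped, since reslicing artefacts are part
of what the benchmark measures.

## Fusion

Inputs are resampled onto one axis-aligned isotropic grid (default 0.2 mm;
the benchmark fuses at 0.3 mm to keep the study light) spanning the
intersection of the inputs' hulls, anchored at the lower corner of the
common region. Each output voxel is the unweighted arithmetic mean of the
inputs covering it — deliberately the simplest possible fusion; weighting
hooks (e.g. by in-plane resolution) are a known extension but the default
does none. Under the "union" domain policy, voxels covered by only some
inputs average what is available and the per-voxel contributor count is
recorded.

Per-voxel sums are taken over value-sorted contributors, making the result
bit-identical under any permutation of the inputs. One numerical caveat:
fusing k identical copies reproduces plain resampling exactly for k = 2
(the sum of two equal floats halves exactly), but for k = 3 the value
(v+v+v)/3 can differ from v by one ulp; the invariant is therefore tested
exact for pairs and to 1e-12 relative for triples.

## Image metrics

The SSIM map uses Gaussian-windowed local moments (separable window, side
11, σ = 1.5 voxels) with the standard stabilizers k1 = 0.01, k2 = 0.03 —
the reference SSIM parameterization, pinned because the metric is
meaningless across studies without pinned constants. The dynamic range L
defaults to max−min of the reference volume and is shared across all cases
of one comparison; a per-case L would make cases incomparable. Masked
statistics (mean and sample std, ddof = 1) are taken by masking the
full-volume SSIM map rather than zeroing the volumes before SSIM: zeroing
would manufacture artificial edges inside every window crossing the mask
boundary. PSNR is 10·log10(L²/MSE) with an infinity sentinel at MSE = 0.
NCC is the global zero-mean, unit-variance correlation (the windowed
variant used by some registration tools is out of scope).

Because SSIM needs a common lattice, the benchmark resamples every case
onto the HR grid (trilinear) before comparison; metric values therefore
include that final interpolation, identically for all cases.

## Morphology metrics

Surfaces come from marching cubes at a fixed threshold, default midway
between background and trabecular HU (150 HU) — a deterministic stand-in
for interactive segmentation, which means case meshes inherit exactly the
blur of their volumes. Binary masks are pre-smoothed with a 1-voxel
Gaussian before surfacing: raw 0/1 lattices put every marching-cubes
vertex on an edge midpoint, faceting the surface and inflating a sphere's
area by ~8%, while the light blur restores sub-voxel crossings (measured
sphere area error ≈ −0.5%, vertex radii within ±½ voxel).

Distances are case→reference only (one-directional), evaluated either at
all case vertices or at an area-weighted random sample (the benchmark uses
3000 samples per case to decouple the summary from vertex density and keep
runtime modest). The unsigned distance is the exact minimum point-to-
triangle distance: a k-d tree over reference vertices bounds the search
radius per point, and the exact closest point is evaluated on every
candidate triangle within the bound. The sign is positive outside the
reference, negative inside, decided by ray-crossing parity (+z rays, 2-D
binned candidate triangles, query coordinates nudged sub-nanometre off
shared edges); an open reference mesh triggers a warning and falls back to
nearest-face-normal signing, which is less stable at sharp creases.
Summaries are bias (mean signed), precision (sample std, ddof = 1) and MAE
(mean absolute); MAE ≥ |bias| always holds.

## Kinematics metrics

Rotations are scalar-first unit quaternions, normalized on construction;
q and −q are the same rotation, handled by the absolute inner product in
the orientation error 2·arccos(|⟨p,q⟩|), reported in degrees (radians via
flag). The relative pose of a child bone in its parent's frame is
rotation conj(q_p)·q_c, translation the difference t_c − t_p rotated into
the parent frame by conj(q_p). Tracking-quality series are normalized frame
by frame as (NCC_case − NCC_ref)/NCC_ref; the division is the only reading
of "normalized by the reference" consistent with a unitless error. Trial
summaries are across-frame means and sample stds. Anatomic coordinate
frames are consumed as given (CSV pose tracks); landmark digitization is
out of scope.

## Benchmark

Per seed: generate the HR phantom; simulate the three orthogonal clinical
volumes; reslice the designated axial volume (RS); fuse all three (SR);
compute image metrics on the HR grid and surface metrics from per-case
meshes. Reports carry the configuration hash and seed, so identical
config + seed reproduces identical reports. Across seeds the package
reports medians and IQRs per case — the study-level claims are orderings
between cases, and inferential statistics (ANOVA, post-hoc tests) are
deliberately out of scope.

Default problem sizes — 128³ HR at 0.6 mm, fusion at 0.3 mm, five seeds,
3000 surface samples — were chosen so the full study runs in a couple of
minutes on one CPU while the two-body gap (2 voxels at HR, sub-slice at
clinical thickness) still exercises the failure mode fusion addresses.

## Known limitations

* Header geometry is trusted; patient motion between reconstructions would
  need registration estimation, which is out of scope.
* Averaging blurs: the fused volume trades a little in-plane sharpness for
  large through-plane gains (visible as whole-volume SSIM occasionally
  favouring RS, while masked SSIM and all surface metrics favour SR).
* The phantom is geometric, not anatomic; no claim is made about absolute
  metric magnitudes on real cervical CT.
* Fusion assumes HU-calibrated inputs from one session; no intensity
  harmonization is performed.
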