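# Methods

This note documents the models and algorithms implemented in `shapepost`,
the parameter choices that matter, what the phantom generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Problem setting

Automatic multi-label segmentation of elongated muscles from volumetric
images (slice-wise CNNs in particular) leaves two characteristic error
modes: *blank regions* — voxels belonging to a muscle left as background —
and *mis-segmentation* — voxels assigned to the wrong muscle, sometimes far
from the muscle itself.  Both inflate surface-distance error metrics
(Hausdorff distance, average symmetric surface distance) far more than
they reduce overlap (Dice).  Since a given muscle's 3D shape is highly
conserved across subjects, a statistical shape prior can repair exactly
these defects: replace the predicted label by a deformed copy of the
population mean shape, registered onto the prediction.  The deformed mean
is a closed, connected object by construction, so holes and satellite
fragments cannot survive.

## Statistical shape model

### Correspondence optimization

Each shape is represented by m particles constrained to its surface
(zero level set of a signed distance field, SDF).  Writing shape k's
particles as a vector x_k ∈ R^{3m}, correspondence quality is driven by
the energy Q = H(Z) − Σ_k H(x_k), with Z the shape-space ensemble and H
differential entropy.  The implementation:

- **Ensemble term** H(Z): Gaussian model, H = ½ Σ log(λ_i + α) over the
  N−1 data eigenvalues λ_i, computed through the dual (N×N) SVD.  The
  regularizer α = 10⁻³·mean(λ) + 10⁻⁸ keeps the estimate finite at rank
  deficiency.  Its gradient drives corresponding particles toward a
  compact shape-space distribution.
- **Sampling term** H(x_k): Parzen window with a **single global
  bandwidth** per shape, the median distance to the ~6th nearest
  neighbour.  A per-particle adaptive bandwidth was tried first and
  rejected: it makes clustering a stable fixed point (a cluster shrinks
  its own interaction range, and exactly coincident particles feel zero
  repulsion forever).  The ascent direction is a Gaussian-windowed sum of
  *unit* vectors away from neighbours, so the force on a nearly
  coincident pair stays finite; an explicit tangential "kick" separates
  pairs closer than 0.25 voxel.
- **Surface constraint**: after every move, particles are projected back
  to the zero level set by Newton iteration along the interpolated SDF
  gradient; moves are first projected onto the local tangent plane.
- **Initialization**: particles are seeded from one surface point and
  repeatedly split (tangential offsets) with repulsive relaxation between
  splits, up to a power-of-two target (default 256; the studies use 64,
  which resolves the desk-scale phantoms).  The same initial set is
  projected onto every ensemble member so particle indices start in
  rough correspondence.
- **Optimization**: alternating sampling-ascent and ensemble-descent
  steps; a step that fails to decrease Q is reverted, shrinking the
  sampling step first (uniform-spread moves are the usual culprit once
  the ensemble term dominates).  Iteration cap 200 by default with a
  relative-energy stopping tolerance of 10⁻⁵.
- **Order invariance**: the Procrustes reference frame, the seeding
  shape, and the per-shape random streams are all anchored to a
  canonical shape ordering (by volume, then centroid), so permuting the
  input list leaves the mean and eigenvalues unchanged.

### Alignment

Generalized Procrustes over mask centroids and principal axes, rigid
only — scaling is deliberately excluded because muscle size is a real
biological signal the model should retain.  Eigenvector sign ambiguity
is resolved against the canonical first shape's axes.  Note that
rotation about an axis of a shape with degenerate second moments (e.g. a
circular-cross-section tube) is unidentifiable by construction; the
ensemble alignment only relies on the well-separated long axis for such
shapes.

### Mean mask reconstruction

PCA of the correspondence vectors gives the mean and at most N−1 modes.
The mean *mask* is voxelized by warping the ensemble member nearest the
mean in shape space: a thin-plate-spline interpolant maps the mean
correspondences to that member's correspondences, the member's aligned
SDF is resampled through this map, and the result is thresholded at
zero — a filled, closed mask by construction.  Averaging aligned SDFs and
thresholding at zero is available as a simpler fallback
(`mean_mask_from_sdf_average`).

## Registration

### Rigid (ICP)

Standard ICP (nearest-neighbour matching + SVD rigid fit) started from
coarse centroid/principal-axes poses: all four proper axis-sign
combinations plus the translation-only pose are each refined to
convergence and the lowest final RMS wins.  Without the coarse stage,
plain ICP stalls in local minima beyond roughly 10° of initial
misalignment; with it, rotations up to 30° and translations up to 10 mm
of exact phantom clouds are recovered to machine precision.

### Deformable (nodal grid)

Displacements live on an isotropic hexahedral node grid with nodal
spacing NS (default 5 voxels — the published optimum for muscle masks at
1 mm isotropic resolution) covering the volume plus a one-NS margin, and
are densified by trilinear interpolation (clamped outside the node box).
Both masks are Gaussian-smoothed (σ = 1 voxel) before the
sum-of-squared-differences cost is evaluated, since binary images have
zero gradient almost everywhere.  The cost

  Σ_x (F̃(x) − M̃(x+u(x)))² + λ Σ_nodes ‖L u‖²,  L = node-graph Laplacian

is minimized by Gauss–Newton: each outer iteration linearizes the warped
moving image and solves the normal equations matrix-free by conjugate
gradients (the interpolation operator is a precomputed sparse matrix), with
a backtracking line search on the true cost.  Plain preconditioned
gradient descent was implemented first and abandoned: it stalled at
DSC ≈ 0.91 on a 3-voxel-shift recovery where Gauss–Newton reaches 0.99
in a quarter of the runtime.  Convergence: relative cost change < 10⁻⁴
or 30 outer iterations.  The Jacobian determinant of x+u(x) is evaluated
on a central-difference stencil; min J ≤ 0 flags folding.

**Smoothing coefficient λ.**  `auto_lambda` implements the documented
selection rule "smallest candidate whose dense map is fold-free" over a
log-spaced grid.  For *post-processing* this rule is deliberately **not**
the default: a weakly regularized warp follows the corruption it is
supposed to repair (blank regions pull the mean into holes).  The
mean-shape pipeline therefore defaults to λ = 10, at which the warped
mean absorbs genuine shape differences but resists local defects
(at λ ≤ 1 the fraction of phantom cases whose surface metrics improve
drops to near zero); `lam="auto"` remains available.

### Warping masks

`apply_displacement` backward-maps the binary mask itself with trilinear
interpolation and re-thresholds at 0.5, making the zero field an exact
identity and integer-voxel fields exact shifts; the pre-threshold
interpolated image is the "soft" score used to resolve overlaps during
multi-label recomposition (highest soft value wins, ties to the lowest
label id).

### Mean-shape pipeline robustness

Three measures keep the per-muscle pipeline robust on badly corrupted
predictions, each added after analysing concrete failure cases:

- **Rough cleanup = opening + closing.**  The opening (radius-1 box)
  removes thin noise; a subsequent closing (radius-3 Euclidean ball)
  with hole filling bridges blank-region invaginations so the SSD target
  is not dominated by them.  Components much smaller than the main body
  can optionally be dropped, but this is off by default: large blank
  regions can sever a genuine muscle into comparable fragments that the
  registration needs.
- **Pose by overlap, not RMS.**  ICP is run from every coarse candidate,
  but the pose actually used is the candidate (refined or unrefined)
  whose rigidly-moved mean has the largest volumetric overlap with the
  cleaned prediction.  On corrupted surface clouds, the RMS-optimal pose
  is sometimes an axial slide or an end-to-end flip of the near-symmetric
  fusiform shape.
- **Speck removal.**  Thresholding the warped soft image can pinch off
  sub-voxel specks at thin tips; since the output is a deformation of one
  connected shape, components below 1% of the body are dropped.

## Comparator post-processors

**2D morphological pipeline** (per label, per axial slice): erosion with
a discrete Euclidean disk (r = 3), 8-connected labelling, retention of
the single largest component, dilation with the same disk, hole filling,
then convolution with a uniform 5×5 kernel and thresholding at 0.5.
These defaults follow the published parameterization of the comparator.
Two documented consequences: muscles legitimately split into several
regions on a slice lose all but the largest; and at desk-scale radii the
disk opening plus smoothing costs a few percent DSC even on a perfect
input (a radius-9 disk survives at DSC 0.976) — the chain presumes
muscle-scale cross-sections.

**Fully connected CRF** (per axial slice): Gibbs energy with unary
potentials −log P and Potts-compatible pairwise potentials under a
two-part Gaussian kernel — appearance (weight W1, spatial bandwidth θα,
intensity bandwidth θβ) plus smoothness (W2, θγ); defaults
W1 = θα = θβ = 10 and W2 = θγ = 1, five parallel mean-field iterations.
Inference is exact O(N²) message passing, capped at 4096 pixels per
slice: at desk scale, correctness is preferred over the lattice
approximations used for megapixel images.  The intensity feature is
scalar (grayscale MRI).

## Evaluation metrics

DSC, signed relative volume error, Hausdorff distance and average
symmetric surface distance between surface-voxel centres (a foreground
voxel is surface if any 6-neighbour is background; array borders count),
honouring anisotropic spacing in mm.  dsc(∅,∅) is defined as 1.0 and
flagged.  Pooled (all-labels-union) reporting omits HD by default: on
the union of many muscles the worst-case distance no longer reflects
per-muscle local error.  The Wilcoxon signed-rank test drops zero
differences, midranks ties, enumerates all 2ⁿ sign assignments exactly
for n ≤ 12 and otherwise uses the normal approximation with tie and
continuity corrections; default significance level 0.05.

## Phantom generator

Muscles are emulated as fusiform tubes along the axial (third) axis: a
rounded taper (√sin profile) with per-subject radius perturbations drawn
from a fixed cosine basis of at most 4 harmonics (so variability is
low-dimensional and recoverable by PCA) and a smooth centreline bend.
Multi-label phantoms pack parallel tubes with a configurable gap.  The
default grid is 64×64×96 voxels at 1 mm (studies use 48×48×64); base
radius 7–8 voxels.  An early flat-capped taper was replaced by the
rounded one because the sharp cap rim funnelled Newton-projected
particles into coincident clusters.

Corrupted "predictions" reproduce the observed error taxonomy: spherical
blank regions inside the muscle (default 3 of radius 5), spurious
same-label blobs 2–5 voxels outside it (2 of radius 3), mild boundary
jitter (±0.5 voxel band, 30% flip rate) and reassignment of 5% of
contact-zone voxels to the adjacent label.  These defaults were fixed
once so the raw predictions mirror the error regime reported for
slice-wise CNN muscle segmentation — overlap still high (DSC ≈ 0.8) but
surface metrics dominated by large local defects.

**What the phantoms do not emulate**: MRI texture, bias fields, fat
infiltration, partial-volume effects, anatomically realistic
cross-sections, or inter-muscle shape correlation.  Passing the phantom
studies shows the algorithms are implemented correctly and that the
mean-shape mechanism repairs the modelled error modes; it does not
certify clinical accuracy on real MRI.

## Problem sizes and determinism

All studies run on one core in seconds to a few minutes: 100 16³ mask
pairs for the metric audit, 20 rigid-recovery trials, single 48×48×64
registrations, a 10-member family with 64 particles for parameter
recovery, and 50 paired corruption cases for the mean-shape study.
Every random draw flows from an explicit integer seed; generators are
pure functions of (spec, seed), and the experiment driver records seeds,
parameters and content hashes in a manifest.

## Known limitations

- Procrustes alignment uses moments only; rotations about
  moment-degenerate axes are unidentifiable (harmless for the elongated
  shapes targeted here).
- The deformable model is not guaranteed diffeomorphic; folding is
  *detected* (Jacobian audit), not prevented.
- The CRF is 2D per slice with a dense-matrix kernel; slices beyond 4096
  pixels require tiling.
- A muscle entirely absent from a prediction is skipped (ICP has no
  target), not instantiated from the prior at a guessed pose.
- The mean-shape output inherits the prior's topology; genuinely
  multi-part muscles would need per-part models.
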