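# shapepost

Shape-based post-processing for multi-label 3D segmentations of
muscle-like structures.

Slice-wise neural segmenters of lower-limb muscle MRI produce label maps
with two characteristic defects: *blank regions* (voxels of a muscle left
unassigned) and *mis-segmentation* (voxels assigned to the wrong muscle).
Because the same muscle has a very similar 3D shape across subjects, a
statistical shape model (SSM) built from reference segmentations provides
a strong prior: this package builds such a model per muscle, and replaces
each predicted label with its **mean shape** rigidly aligned (iterative
closest point) and then deformably registered (nodal-grid, sum-of-squared-
differences) onto the prediction.  The warped mean — not the prediction —
is kept, so holes and stray fragments cannot survive.  The package also
implements the two standard comparator post-processors (a slice-wise 2D
morphological pipeline and a fully connected CRF with mean-field
inference), the usual evaluation metrics, and a seeded phantom simulator
so the whole pipeline can be exercised end to end without clinical data.

## The model in brief

**Correspondences.** Each of N aligned shapes is sampled by m surface
particles, giving vectors x_k ∈ R^{3m}.  Particle positions minimize

    Q = H(Z) − Σ_k H(x_k)

where Z = {x_1…x_N} and H is differential entropy: the first term
compacts the shape-space distribution (good correspondence), the second
spreads particles uniformly over each surface (good sampling).  PCA of
the x_k yields the mean shape and at most N−1 variance-carrying modes.

**Registration.** The mean mask is aligned to the prediction by ICP, then
warped by displacements estimated on a hexahedral node grid with nodal
spacing NS (default 5 voxels, the published optimum for muscle masks at
1 mm resolution), densified by trilinear interpolation, minimizing

    Σ_x (F(x) − M(x+u(x)))² + λ Σ_nodes ‖L u‖²

with L the node-graph Laplacian and λ the smoothing coefficient.

**Metrics.** Dice similarity coefficient (DSC), relative volume error
(RVE), Hausdorff distance (HD) and average symmetric surface distance
(ASSD), per label and pooled, plus a Wilcoxon signed-rank test (exact for
small n) for paired method comparison.

## Worked example

```python
from dataclasses import replace
import numpy as np
from shapepost import (PhantomSpec, CorruptionSpec, generate_shape_family,
                       corrupt_prediction, optimize_correspondences,
                       build_shape_model, reconstruct_mean_mask,
                       ms_postprocess_label, extract_label_mask,
                       LabelVolume, dsc, hausdorff, assd)

spec = PhantomSpec(n_subjects=6, volume_shape=(48, 48, 64), base_radius=7,
                   variability=1.2, bend_amplitude=1.0, seed=500)
train = generate_shape_family(spec)                      # reference shapes
ps, _ = optimize_correspondences(train, m=64, iterations=60, seed=0)
model = build_shape_model(ps)
mean_mask = reconstruct_mean_mask(model, ps, train)      # the shape prior

gt = generate_shape_family(replace(spec, n_subjects=1, seed=1001))[0]
pred = corrupt_prediction(LabelVolume(gt.grid.astype(np.int16)),
                          CorruptionSpec(seed=1))        # blank regions etc.
pm = extract_label_mask(pred, 1)
out = ms_postprocess_label(pm, mean_mask)

print(f"raw : DSC={dsc(gt, pm):.3f}  HD={hausdorff(gt, pm):.1f} mm  "
      f"ASSD={assd(gt, pm):.2f} mm")
print(f"MS  : DSC={dsc(gt, out):.3f}  HD={hausdorff(gt, out):.1f} mm  "
      f"ASSD={assd(gt, out):.2f} mm")
```

Output:

```
raw : DSC=0.727  HD=10.3 mm  ASSD=0.99 mm
MS  : DSC=0.861  HD=2.2 mm  ASSD=0.80 mm
```

The corrupted prediction's worst-case surface error (HD) collapses from
10.3 mm to 2.2 mm because the warped mean has no holes or satellites;
mean surface error (ASSD) and overlap (DSC) improve as well.  This is the
method's signature: large local errors are eliminated while overlap stays
on par.

A command-line interface mirrors the library:

```bash
shapepost simulate --out data/ --labels 2 --subjects 4 --seed 0
shapepost build-ssm --masks data/s0_gt.nii.gz --masks data/s1_gt.nii.gz \
    --masks data/s2_gt.nii.gz --out bank/
shapepost postprocess ms --pred data/s3_pred.nii.gz --bank bank/ --out post.nii.gz
shapepost evaluate --ref data/s3_gt.nii.gz --pred post.nii.gz
shapepost run-experiment --out results/ --seed 0
```

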