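# cctstrain

Regional left-ventricular (LV) strain analysis from retrospective-gated
cardiac CT (CCT) image sequences.

A gated CCT study reconstructs 10–20 3D volumes across one cardiac cycle.
`cctstrain` tracks the motion of the LV endocardium across those frames with
two intensity-based deformable registration engines, deforms a single
end-diastolic endocardial mesh through the cycle, and computes regional
circumferential strain, longitudinal strain and local endocardial area
change, together with systolic dyssynchrony indices. Only one semi-automated
segmentation (of the end-diastolic reference frame) is required.

The package is aimed at researchers quantifying regional cardiac mechanics
from CT — for example in dyssynchronous heart-failure patients being
evaluated for cardiac resynchronisation therapy — and ships a fully analytic
deforming-ventricle phantom so that every stage of the workflow is testable
without clinical data.

## Method

**Motion tracking.** Every frame is registered directly to the end-diastolic
reference (frame 0):

- **TSFFD** — temporal sparse free-form deformation: a four-level cubic
  B-spline transform (control spacing halving per level) minimising the mean
  sum of squared intensity differences with a bending-energy penalty
  (weight Θ₀ = 5·10⁻⁶), an L1 sparsity penalty over the control
  displacements of all levels (weight Θ₁ = 0.43) and a cyclic temporal
  coupling between neighbouring frames. The objective is minimised per
  level by a monotone line-search descent whose direction solves the damped
  Gauss–Newton normal equations with matrix-free conjugate gradients.
- **DDS** — dense displacement sampling: a discrete MRF formulation where
  control points on lattices of spacing 8, 7, 6, 5, 4 voxels choose
  displacement labels from a quantised search region; the data term is the
  patch-mean Hamming distance between binarised self-similarity-context
  (SSC) descriptors, smoothness is Θ‖f_p − f_q‖² (Θ = 0.5) on a minimum
  spanning tree of the control lattice, and the labelling is solved exactly
  by min-sum message passing.

**Mesh deformation.** The displacement field is rasterised onto the voxel
lattice and each reference-mesh vertex m moves to m + Π(m, u), where Π is
trilinear interpolation.

**Strain.** Each reference triangle carries a fixed orthonormal triad
(e_r, e_θ, e_z): surface normal, circumferential, and the in-plane
projection of the apex→mitral-centroid long axis. The element deformation
gradient **F** maps reference edges to deformed edges and unit normal to
unit normal; the Green–Lagrange tensor **E** = ½(FᵀF − I) is rotated into
the element frame, E_e = Q E Qᵀ, whose radial row/column then vanish
identically. Reported values are E_θθ (circumferential), E_zz
(longitudinal) and the triangle area ratio (its square root is the SQUEEZ
index). Regional curves are unweighted means over the triangles of each
AHA segment (16 segments: basal 6, mid 6, apical 4).

**Dyssynchrony.** From each regional curve: T2P (time to peak as cycle
fraction), TOS (first crossing of 50 % amplitude from onset), MAG
(peak-to-peak amplitude). The systolic dyssynchrony index (SDI) is the
standard deviation of a per-segment measurement across the 16 segments;
healthy and CRT groups are compared with Welch t-tests on per-subject SDIs.

## Worked example

```python
import numpy as np
from cctstrain import phantom, imaging, motion, reg_ffd, strain

spec = phantom.PhantomSpec()            # 64^3 voxels, 10 frames, 20 HU noise
frames, truth = phantom.generate_phantom_sequence(spec)

mask = imaging.region_grow(frames[0], phantom.default_seeds(spec), margin=30.0)
mesh = imaging.smooth_mesh(imaging.extract_surface(mask), iterations=10)

stacks = reg_ffd.register_tsffd(frames)   # Theta0=5e-6, Theta1=0.43
ref = frames[0]
fields = [motion.DisplacementField.from_ffd_stack(s, ref.shape, ref.origin,
                                                  ref.spacing) for s in stacks]
meshes = [mesh] + [motion.deform_mesh(mesh, f) for f in fields[1:]]

lm = truth.landmarks0
apex = lm["apex"]
base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
curves = strain.regional_curves(meshes, strain.aha_label(mesh, lm),
                                strain.element_bases(mesh, apex, base))
print(round(curves.e_cc[5].mean(), 4))   # -0.1963
print(truth.strain(5)[0])                # -0.18
```

The phantom contracts with circumferential stretch 0.8 at end-systole, i.e.
a true peak circumferential strain of −18 %; the tracked value above
recovers it to within two strain points. The same `StrainCurveSet` feeds
the dyssynchrony statistics (`cctstrain.dyssynchrony`) and CSV/bullseye
exports.

A command-line entry point wraps the same pipeline:

```
cctstrain pipeline --method tsffd --seed 1 --out results/
cctstrain register --method dds --theta 0.5 --spacings 8,7,6,5,4 \
    --frames f0.nii.gz --frames f1.nii.gz --out fields/
cctstrain optimise --method tsffd --grid bending=0:1:0.1,sparsity=0:1:0.1 \
    --out surface.csv
```

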