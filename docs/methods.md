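# Methods

This note documents the models, parameters and numerical choices behind
`cctstrain`, and what the synthetic phantom does and does not establish.

## The analytic phantom

The phantom emulates a contrast-enhanced LV blood pool: a prolate-spheroid
cavity (default semi-axes 16/16/24 mm, long axis on the third image axis)
at 400 HU, a 4 mm myocardial shell at 50 HU, and −1000 HU background on a
64³ grid of 1 mm isotropic voxels, with additive i.i.d. Gaussian noise of
20 HU drawn from a generator seeded per sequence (generation is
bit-reproducible). Edges are rendered with a half-voxel linear intensity
transition, comparable to the point-spread function of a modern CT scanner
at this voxel size. Motion is the cyclic axis-aligned stretch

    phi_t(x) = c + diag(lam_c(t), lam_c(t), lam_l(t)) (x − c),
    lam(t)   = 1 + (lam_peak − 1) sin²(π t / n_frames),

with default end-systolic stretches lam_c* = 0.8 and lam_l* = 0.88 over 10
frames. These produce a peak circumferential strain of −18 % and a peak
longitudinal strain of −11.3 %, in the range reported for healthy subjects
by CT, MRI and echo techniques. The deformation was chosen to be affine
precisely because it has exact closed-form Green–Lagrange strains
everywhere: E_cc = (lam_c² − 1)/2, E_zz = (lam_l² − 1)/2, and an area ratio
lam_c·lam_l for wall elements aligned with the stretch axes.

Two analytic meshes accompany the images. A prismatic cylinder shell about
the long axis has exactly vertical facets, so every element triad aligns
with the stretch axes and the closed forms are realised to machine
precision — this is the verification fixture for the strain module. An
icosphere-based ellipsoid triangulation of the cavity surface serves for
tests where realistic element orientations matter; on it only E_cc is
exact for every element (the circumferential direction is always
horizontal and in-plane), which is why the end-to-end pipeline criterion
is stated for circumferential strain.

What the phantom does *not* model: papillary muscles and trabeculae
(the clinical workflow includes papillary muscles in the blood pool),
through-plane anisotropy, gating artefacts, beam hardening, regional wall
thickening, or any electromechanical physiology. Passing the phantom tests
therefore demonstrates the correctness of the numerics and the ability of
the registration engines to track clean, smooth, cyclic motion at CT-like
contrast and noise — not clinical accuracy on pathological anatomy.

## Imaging

Voxel indices are 0-based; world coordinates are `origin + index·spacing`
(mm); direction cosines beyond axis flips are not modelled. Blood-pool
segmentation is grey-value region growing: 6-connected flood fill within
`[min(seed HU) − 30, max(seed HU) + 30]`, with several seeds spread
through the cavity as an operator would click them. Sparse 2D annotations
are completed to 3D by linear interpolation of per-slice signed distance
maps (annotated slices reproduce exactly). Surfaces come from marching
cubes on the mask softened by a 1-voxel Gaussian (a smooth surface rather
than a voxel staircase), are consistently oriented outward, and are
smoothed by the Taubin lambda/mu scheme (0.5/−0.53) followed by a
centroid rescale that restores enclosed volume exactly, comfortably inside
the 0.5 % volume-preservation contract. Surface-to-mask distance is the
mean absolute value of the voxel signed-distance field (shifted half a
voxel so the zero level sits at the voxel interface) sampled at the
vertices.

## TSFFD registration

The transform is an additive stack of cubic B-spline levels; the coarsest
control spacing is a quarter of the domain extent, halving per level
(four levels by default). Levels are optimised coarse to fine on an image
pyramid whose downsampling factor is matched to the control spacing
(capped at 4×). All frames are registered directly to frame 0; within a
level, frames are processed in temporal order with warm-started controls,
and a second sweep couples each frame to its cyclic neighbours through a
first-difference penalty.

The objective per level combines

- mean SSD over in-bounds voxels (HU²) with trilinear target sampling;
- Θ₀ × bending energy: the sum of squared second finite differences of the
  control displacements, divided by the squared control spacing and scaled
  by the squared calibrated HU span (4095²). Under this scaling Θ₀ values
  of 10⁻⁶–10⁻⁵ balance data fit against stiffness while Θ₀ = 1 freezes
  curved motion entirely;
- Θ₁ × the per-component mean of the ε-smoothed L1 norm (ε = 10⁻² mm) of
  the control displacements. Under this scaling the sparsity weight is a
  gentle shrinkage whose main effect is to keep featureless background at
  zero displacement; accuracy is insensitive to Θ₁ across [0, 1];
- in temporal mode, Θ₀ times a per-control-point mean squared cyclic
  first difference between the frame's and its neighbours' controls,
  sharing the bending scale.

Defaults Θ₀ = 5·10⁻⁶ and Θ₁ = 0.43 are the hyperparameter-search optima
for gated cardiac CT.

The optimiser is a monotone line-search descent: each outer step
linearises the residual and solves the damped Gauss–Newton normal
equations approximately with matrix-free conjugate gradients (≤30 CG
iterations, Tikhonov damping 10⁻³ of the mean data-term curvature), then
backtracks on the true objective, accepting only decreases. First-order
descent variants were found to stall with systematic sub-voxel residuals
because the B-spline normal matrix couples neighbouring controls strongly.
Two image gradients exist side by side: the optimiser's search direction
uses central differences of the Gaussian-regularised target (the exact
derivative of the trilinear interpolant is one-sided at lattice-aligned
displacements and useless as a search direction there), while
`objective_and_gradient(exact=True)` exposes the exact analytic gradient,
which matches central finite differences to ~10⁻⁸ and is what the
gradient-verification tests exercise.

## DDS registration

Five labelling passes run over the full-resolution image at control
spacings 8, 7, 6, 5, 4 voxels with displacement quantisation steps
4, 4, 2, 2, 1 voxels and search radius equal to the spacing — a nested
halving schedule that ends at single-voxel precision so every integer
displacement is reachable (each pass's residual is at most the next pass's
step). Each pass composes its incremental field with the running estimate;
during the pyramid the image is warped with the *rounded* field and
nearest-neighbour gathers, because trilinear resampling blurs the warped
image wherever the field is fractional and corrupts the self-similarity
descriptors. Control labels are interpolated linearly to the voxel
lattice; cubic interpolation of discrete labels rings around isolated
label changes and the ringing accumulates across composed passes.

SSC descriptors: Gaussian-weighted (σ = 0.8 voxel) patch SSDs between the
12 non-opposite pairs of 6-neighbourhood offsets, converted to
self-similarities exp(−D/mean D) and binarised against the per-voxel mean
channel (ties → 0). A noise gate zeroes the descriptor wherever the mean
channel distance falls below 8× its volume median: in contrast CT the
median is dominated by featureless voxels (air, homogeneous blood pool),
whose bits would otherwise be noise-random and poison the patch-mean
Hamming data term. The gate, like the descriptor, is invariant to positive
affine intensity rescaling; it assumes featureless regions dominate the
volume and should be disabled (`noise_gate=0`) for fully textured data.

Unary costs are patch-mean Hamming distances (patch halfwidth = spacing/2)
with border replication; a label costs +inf only when its displaced patch
loses all overlap with the image. At passes with step > 1 a small bias
(0.2 per unit label norm) favours the zero label, preventing dithering
between bracketing labels when the true residual is below the quantisation
step. Smoothness is Θ‖f_p − f_q‖² (Θ = 0.5) on a minimum spanning tree
built with Prim's algorithm (deterministic tie-breaking) over edge weights
equal to the absolute patch-mean intensity difference in the reference, so
the tree avoids crossing tissue boundaries; the labelling is the exact
tree MAP by leaf-to-root min-sum message passing.

## Motion and strain

Displacement fields are rasterised to the voxel lattice and applied to
mesh vertices and landmarks by component-wise trilinear interpolation;
points outside the field domain raise rather than extrapolate, because
silent extrapolation corrupts strain. A deformation collapsing a triangle
below 10⁻¹² mm² is flagged, not dropped.

The element triads are computed once on the reference mesh and reused for
all frames. **F** maps reference unit normal to deformed unit normal (no
through-wall stretch): this choice makes the radial row and column of the
rotated strain tensor vanish identically (|E_ri| < 10⁻¹⁰ in the tests);
the alternative area-preserving normal scaling was rejected because it
contaminates E_rr. Regional means are unweighted over member elements
(an area-weighted option exists); empty segments are NaN, never zero.
AHA labelling: the long axis runs apex → mitral-landmark centroid,
longitudinal thirds split apical/mid/basal, and sector boundaries are
anchored at the mean septal direction, counted counter-clockwise viewed
from the base; the apex-cap segment 17 is not used.

## Validation and dyssynchrony

The tracking cost is the mean squared *relative* difference between
estimated and observed anatomical measurements over measurement kinds and
frames (the companion report is the mean absolute relative error in
percent); cells with zero or undefined observations are excluded and
counted. The mitral-annulus area projects the annulus ring onto its
least-squares plane and applies the shoelace formula; midpoint-based
distances use the ring centroid. Grid search enumerates every axis
permutation deterministically and records failed evaluations as missing.
Agreement statistics use Pearson r, the R² of a simple regression, and
Welch (unequal-variance) t-tests with a Welch-Satterthwaite 95 % CI.

Curve measurements define the peak as the sample of largest absolute
deviation from the frame-0 value, so negative-going strain curves and
positive-going area curves are handled uniformly; TOS interpolates the
first 50 %-amplitude crossing linearly; onset is frame 0 (the R-wave
reference). SDI uses the n−1 standard deviation across exactly 16
segments. Group comparisons compute, per subject, the SDI of each of the
nine strain/measurement combinations and Welch-test them between groups.
The frame-rate experiment recomputes the measurements on stride-2
subsampled curves; on smooth phantom curves MAG changes by < 2 % while TOS
is the most sensitive measurement on steep-onset curves.

## Problem sizes and determinism

The phantom used throughout is 64³ voxels × 10 frames (registration
benchmarks use a 48³ static variant); these sizes keep a full pipeline run
in the minutes range on one CPU while leaving the cavity ≥ 24 voxels
across. All randomness flows through explicit integer seeds; identical
configuration and seed reproduce outputs bit-for-bit, which the pipeline
manifest checksums assert.

## Known limitations

- Longitudinal strain is recovered less accurately than circumferential
  strain (the wall is nearly parallel to the long axis, so tangential
  motion is weakly constrained — an aperture problem); the phantom
  pipeline overestimates |E_ll| while recovering E_cc within ±0.02.
- The B-spline fill-in between the walls smooths the radial displacement
  profile, which slightly overestimates |E_cc| for mid-ventricular
  segments (≈ +0.03 at worst on the default phantom).
- The DDS engine quantises displacements to one voxel at its finest pass;
  sub-voxel motion is represented only through the interpolation of
  integer labels.
- The SSC noise gate assumes featureless regions dominate the volume
  (true for contrast CT), and the registration engines have been
  validated on phantom motion only; no claim is made about pathology,
  arrhythmia-corrupted gating, or device artefacts.
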