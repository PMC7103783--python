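# Methods

`fetalrecon` reconstructs a single isotropic high-resolution 3D volume from
several motion-corrupted stacks of thick 2D MR slices, the situation of
fetal brain MRI acquired with single-shot fast spin echo (SSFSE) sequences.
This note documents the models implemented, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic validation does and does not show.

## Slice acquisition model

Each acquired slice is modelled as

    y_k = A_k x + e_k

where `x` is the unknown high-resolution volume and `A_k` encodes the
k-th slice's rigid pose, blurring by the point spread function (PSF), and
down-sampling to the acquired pixel lattice. The PSF is a slice-aligned
anisotropic Gaussian: in-plane FWHM = 1.2 x the in-plane pixel spacing on
both in-plane axes, through-plane FWHM = the slice thickness, converted to
standard deviations by sigma = FWHM / (2 sqrt(2 ln 2)). Both constants are
configurable (`make_psf`); the in-plane factor follows the standard SSFSE
slice-profile approximation.

Discretization: the rotated PSF covariance is expressed in volume index
coordinates and augmented by the voxel's own second moment (1/12 per index
axis) — high-resolution voxels are treated as box basis functions rather
than point masses. This both reflects the finite voxel extent and keeps the
narrow in-plane kernel well resolved on the grid; without it, voxel-center
quadrature of a kernel with sigma below one voxel produces
position-dependent normalization wobble that measurably biases
slice-to-volume registration. The kernel is truncated at a Mahalanobis
radius of 3 standard deviations and the per-pixel weights are renormalized
to sum to one over the truncated in-extent support, so constants are mapped
to constants away from boundaries and the forward/adjoint pair is exact
(dot-product agreement to ~1e-16 in the tests). The operator is matrix-free:
per-slice sparse weights are generated on demand and never assembled
globally; the solver caches them per slice for the duration of one solve.

## Scattered data approximation (SDA)

The initial volume and all high-resolution brain-mask volumes are built by
discrete Nadaraya-Watson kernel regression: nearest-neighbor splatting of
intensity and of unit weights onto the target grid (ties at .5 round toward
the lower index), Gaussian blurring of both accumulators, and their ratio
where the blurred weight exceeds 1e-8 of its maximum. The smoothing standard
deviation defaults to 1 target-grid voxel; the paper-stated "standard
deviation of 1" carries no units, and voxels are the only reading that keeps
the kernel narrow on a sub-millimetre grid (a mm interpretation is available
via `sigma_in_mm`). Mask volumes threshold the soft SDA at 0.5.

## Outlier-robust super-resolution reconstruction

The volume estimate solves

    x = argmin_{x >= 0}  sum_{k in K_beta} 1/2 ||y_k - A_k x||^2
                         + alpha/2 ||grad x||^2

with `K_beta` the inlier set: slices whose normalized cross-correlation
(NCC) with their simulated counterpart `A_k x_prev`, evaluated only on the
pixels where the current high-resolution brain mask projects, reaches the
threshold `beta`. Evaluating on the slice-projected mask (rather than the
slice's own mask) matters: a corrupted slice cannot escape evaluation by
drifting to a pose where its own masked region happens to match. Slices
with degenerate similarity (constant region, too few pixels, no overlap)
are treated as outliers. Rejection is complete — excluded slices contribute
nothing to the solve, so adding a rejected slice leaves the reconstruction
bit-identical.

In the first cycle the reference is the SDA initialization, which contains
every slice's own contribution; scoring a slice against an average that
includes itself is biased upward, and a strongly corrupted slice can
"self-vote" past the first (lenient) threshold, enter the first solve, and
then keep confirming itself in later cycles. The first-cycle selection
therefore scores each slice against the leave-one-out SDA of all *other*
slices — a jackknife, computed exactly and cheaply by subtracting the
slice's splat from the accumulators before blurring. Later cycles score
against solved volumes that no longer contain rejected slices and use the
plain rule. This made the outlier-rejection recall and the
reconstruction-quality ordering stable across simulation seeds rather than
holding only at particular draws.

For fixed `K_beta` the problem is linear least squares; the stacked system
`[A_k ; sqrt(alpha) grad]` is solved matrix-free with SciPy's LSMR
(default cap 100 iterations, tolerance 1e-6), and positivity is enforced by
clipping negative values once after convergence. `grad` is the
spacing-scaled forward-difference operator (zero at the far boundary), so
`alpha` is resolution-independent; its exact adjoint (negative divergence)
is used in the normal equations. Defaults: alpha = 0.01; per-cycle
thresholds beta = (0.5, 0.65, 0.8), increasingly strict as the
reconstruction sharpens; reconstruction resolution 0.8 mm isotropic
(matching the template space; the phantom experiments use 1.2 mm, 0.8 x the
phantom spacing, to stay at desk scale).

An empty inlier set raises `NoInliersError`; the documented recovery is to
retry with `beta` reduced by 0.15.

## Motion correction pipeline

`reconstruct_subject_space` runs, in fixed order: (1) target-stack
selection — the stack whose estimated brain volume (sum of slice-mask
pixels x pixel volume) is closest to 70% of the median across stacks, ties
toward the lower index; (2) rigid volume-to-volume alignment of every other
stack to the target, masked-NCC metric; (3) per-stack linear intensity
correction `a I + b` regressed against masked target voxels paired with
trilinearly interpolated moving-stack values; (4) SDA initialization of
volume and mask on an isotropic grid oriented by the target stack and
covering the union of aligned stack masks plus a 10 mm margin; (5) three
cycles of {per-slice slice-to-volume registration against the previous
iterate; inlier selection at beta_i; robust SRR solve; mask SDA from the
inlier slice masks}. The cycle count is fixed (no adaptive stopping). An
optional `n4_hook` lets callers run external bias-field correction first;
the package itself does not model bias fields.

### Registration engine

The paper delegates registration to external engines (symmetric
block-matching for volumes, ITK NCC for slices); this package ships a
self-contained stand-in: bounded Powell search over the six rigid
parameters (intrinsic Z-Y-X Euler angles in degrees, translations in mm)
maximizing masked NCC. Engineering choices that proved load-bearing:

* rotations are parameterized about the fixed masked centroid (volumes) or
  the slice's masked center (slices), so rotation and translation do not
  couple through a long lever arm to the world origin;
* the search is bounded (capture range 30 deg / 30 mm for volumes,
  12 deg / 8 mm for slices) — the unbounded Powell line search otherwise
  jumps into distant spurious NCC basins;
* slice registration runs translation-only first (the NCC valley is far
  sharper in translation than rotation), then full 6-DOF with the
  translation directions searched first, then a coordinate-wise parabolic
  polish — the rotational NCC valley is so shallow (~2e-3 NCC per degree)
  that Powell's convergence test otherwise stops essentially at the
  initialization;
* the first pipeline cycle registers translation only: against the blurry
  SDA initialization, slice rotations are not identifiable, and estimating
  them there injects errors that later cycles cannot fully undo;
* volume registration uses a 3-level pyramid (Gaussian smoothing sigma
  2/1/0 voxels with sampling strides 4/2/1) and offers an optional trimmed
  slab-blockwise NCC for corrupted stacks.

A note on evaluation: the subject-space frame inherits the target stack's
average motion and is therefore arbitrary with respect to any simulated
ground truth. Recovered slice poses are scored after a global Kabsch gauge
alignment; rotation error is reported both per rotation parameter (the
convention motion is usually summarized in) and as the geodesic angle.

## Template-space alignment

The template is chosen from an atlas by nearest brain volume. Principal
brain axes (PBA) of the subject and template masks (PCA of the binary voxel
clouds, soft masks thresholded at 0.5) give four initial transforms — the
sign combinations of the two leading subject eigenvectors that keep the
basis right-handed, the third axis being their cross product. Near-isotropic
eigenvalue spectra trigger a warning. Each candidate is refined by masked
rigid registration, and the winner is the refined transform with maximal
normalized mutual information (32-bin joint histogram) between the warped
reconstruction and the template. The final template-space volume is
produced by one more robust SRR on the template grid with the slice poses
composed through the template transform — the subject-space volume is never
resampled, avoiding a second interpolation.

The packaged synthetic atlas helper (`save_atlas` / `load_atlas`) stores
one NIfTI volume + mask per entry and a JSON manifest; a real spatiotemporal
atlas can be dropped in with the same layout.

## Localization and segmentation machinery

* `dice_loss`: soft Dice, `1 - 2<y,g> / (||y||^2 + ||g||^2)`, stabilized by
  eps = 1e-8.
* `downscale` / `multiscale_loss`: recursive 2x2 average pooling with
  stride 2 (odd borders averaged over the available block); the multi-scale
  loss averages the Dice loss over S = 4 scales by default, penalizing
  disagreement at non-local scales as well as per-pixel error.
* `PNetSpec` / `build_pnet`: the dilated-convolution dense-prediction
  architecture (five feature blocks with 2/2/3/3/3 conv layers, dilations
  1/2/4/8/16, 64 channels, concatenated into a 1x1-conv softmax classifier)
  is represented as a validated declarative description with receptive-field
  bookkeeping. The deep network itself is not trained here; externally
  trained predictions enter as probability maps.
* `train_segmenter`: a deliberately small trainable model — per-pixel
  logistic classifier on standardized multi-scale image features (intensity,
  Gaussian smoothings at sigma 1/2/4/8, gradient magnitudes at sigma 1/2),
  warm-started by a ridge fit and fine-tuned with Adam (learning rate 1e-3,
  batch size 10, weight decay 1e-7) directly on the multi-scale Dice loss,
  whose gradient is backpropagated through the average-pooling chain in
  closed form. It exists to exercise the loss end-to-end on synthetic
  shapes; it is not a stand-in for a CNN on clinical data.
* `coarse_to_bbox`: binarize at 0.5, 3D morphological closing then opening
  with a 3x3x3 cube, largest 26-connected component, tight voxel box,
  back-mapping to the original grid via recorded per-axis scale factors,
  5 mm world-space margin per face, clipped to the image extent. Threshold,
  structuring element and connectivity are configurable; the defaults are
  the natural choices where no value is prescribed.
* `prepare_locnet_input`: in-plane resize of each slice to 96x96 (aspect not
  preserved; the exact per-axis scale factors are returned for box
  back-mapping) and per-stack normalization by mean and standard deviation.

## Synthetic data generator

The simulator provides the ground truth the validation rests on.

* Phantom: a 64^3, 1.5 mm grid carrying nested smooth ellipsoids (bright
  shell, interior gradient, off-center blobs) inside an elongated ellipsoid
  "brain" mask with half-axis fractions (0.62, 0.48, 0.36) of the half
  field of view — pairwise eigenvalue ratios >= 1.2 so principal-axis
  estimation is well posed — plus band-limited Gaussian texture (correlation
  length ~1.5 voxels, amplitude 0.25). The texture matters: real parenchyma
  is textured, and a texture-free phantom leaves through-plane slice
  alignment under-constrained in a way real data is not.
* Acquisition: three orthogonal stacks of 44x44 slices at
  1.5 x 1.5 x 3.0 mm, slice count covering the masked anatomy plus 10 mm.
  Slices are generated with the same oriented-Gaussian forward operator the
  reconstruction uses (an "inverse crime" accepted deliberately: the
  validation targets the estimation machinery, not model misspecification).
* Motion: per-slice 6-parameter trajectories; within each of M = 2
  interleaved sub-stacks a clipped uniform random walk (steps 0.5 deg /
  0.3 mm), between sub-stacks an independent jump (bounds 3 deg / 2 mm),
  everything clipped to the global bounds (5 deg / 3 mm by default, honoured
  exactly). Motion rotations act about the anatomy center. No physiological
  model is claimed.
* Artifacts: a per-slice Bernoulli draw (default 10%) corrupts slices with
  one of: sinusoidal intensity banding (amplitude 1.2-2 x the range),
  directional motion smear plus a displaced ghost copy, or signal dropout
  (60-90% of the masked rows attenuated to near zero). Magnitudes are
  calibrated — and asserted in the tests — so corrupted slices fall below
  NCC 0.8 against their clean counterparts, making the final rejection
  threshold meaningful. Bands and dropouts are centred on the masked rows so
  corruption hits anatomy rather than background.
* Noise: additive Gaussian, standard deviation 1% of the phantom intensity
  range (Rician noise deliberately omitted). Each stack is finally distorted
  by a linear intensity scaling a in [0.8, 1.2], b within +-5% of the range.

Everything is deterministic given the seeds; distinct seeds decorrelate.

## What the validation shows — and does not

The phantom experiments (in `fetalrecon.experiments`, also driven by
`scripts/acceptance.py`) demonstrate, at desk scale on one CPU: exactness
of the operators; agreement of the matrix-free solve with a dense oracle;
complete outlier rejection with recall 1.0 on calibrated corruptions;
median pose-recovery errors of ~0.5 deg per rotation parameter (~1.2 deg
geodesic) and ~0.35 mm after three cycles under 5 deg / 3 mm motion; a
reconstruction that beats the best single input stack by several dB of
masked PSNR and degrades when rejection is disabled; and 20/20 successful
template alignments under offsets up to 30 deg / 20 mm. They do not show
robustness to bias fields, spin-history effects, non-rigid motion,
model-mismatched slice profiles, or real anatomy — the simulator generates
none of these — and the trainable segmenter's ellipse benchmark says
nothing about clinical segmentation accuracy.

## Known limitations

* The registration engine is a local, derivative-free stand-in for mature
  block-matching/ITK engines; its capture ranges are documented config, not
  claims about the original tools. Very large inter-stack motion should be
  handled by the template-style PBA initialization, not by the v2v step.
* Single-orientation inputs leave the through-plane problem underdetermined;
  at least three roughly orthogonal stacks are needed for isotropic detail.
* Intensity correction uses simple regression of interpolated pairs and
  inherits regression dilution when the overlap is noisy.
* Stacks are read with the slice-select axis assumed to be the axis of
  largest spacing when headers are ambiguous.
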