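# Methods

## Synthetic phantom

The phantom emulates the *result* of a 3D TOF-MRA acquisition, not the MR
physics: flowing blood appears bright, static parenchyma dimmer, background
near zero. It is an ellipsoidal "brain" envelope (semi-axes 0.42 of each
dimension) filled at the parenchyma level, with `n_vessels` tubes painted at
the artery level. Each tube is a smooth 3D random walk (persistent direction
with Gaussian perturbation, step 0.6 voxel) whose radius tapers linearly
from a trunk value near the maximum of `vessel_radius_range` to the minimum
at the tip, so a single phantom contains both large trunks and small
peripheral vessels — the structures that drive perceptual quality
differences. Masks are exact by construction: `arterial` is the set of
painted voxels (clipped to the envelope), `parenchymal = brain AND NOT
arterial`.

Defaults, chosen once as a plausible normalized TOF-MRA contrast: intensity
levels artery 1.0 / parenchyma 0.3 / background 0.0 (arbitrary units),
noise SD 0.02 (complex Gaussian added in quadrature before the magnitude is
taken, giving Rician magnitude statistics; SNR ~ 50 in arteries, ~ 15 in
parenchyma), 6 vessels with radii 1–3 mm at 1 mm isotropic voxels, default
shape 96x96x48. The acquisition-geometry shape 256x256x110 is available by
configuration; the method itself is scale-free, and the smaller default
keeps a full sweep at desk scale. Axis 0 is the readout
(antero-posterior) direction; axes 1–2 are the phase encodes (transverse,
craniocaudal). What the phantom does *not* emulate: flow-related
enhancement, inhomogeneous tissue texture, skull/extracranial structures,
motion, or segmentation error in the masks — so passing tests demonstrate
correctness of the pipeline's computations, not clinical performance on
real scans.

Coil maps are broad Gaussian magnitude profiles centered on an ellipse
around the phase-encode plane with gentle linear phase ramps, normalized by
the pointwise root-sum-of-squares so that RSS = 1 everywhere. This makes
the sum-of-squares (SoS) combination of fully sampled noiseless data
reproduce the source volume exactly, which pins down the reference standard
without a separate sensitivity-estimation step.

## Undersampling

Variable-density Poisson-disk sampling on the two phase-encode dimensions
(the readout is fully sampled and the 2D mask broadcasts along it). The
exclusion radius grows with normalized distance d from the k-space center
as `r(d) = r0 (1 + 3 d^2)` (edge radius 4x the center radius); a candidate
is rejected if it is closer to an accepted point than the radius evaluated
at the pair's midpoint; the DC point is always kept. `r0` is calibrated by
bisection (at most 40 iterations, fresh identical dart order per
evaluation) until the achieved rate is within 0.005 absolute of the target;
if the grid is so small that its rate granularity exceeds that tolerance, a
`CalibrationError` reports the bracketing rates instead of silently
accepting a miss. An optional fully sampled center disc (5% of the grid
diagonal) is off by default. Distances are plain Euclidean on the finite
grid (no torus wrap).

## Reconstruction

FCSA with FISTA momentum, fixed 15 outer iterations (no early stopping),
initialized at the zero-filled adjoint `x0 = A* y`. Each iteration:
gradient step on the data term at the momentum point; TV subproblem
(isotropic 3D TV, forward differences, Neumann boundary; Chambolle-type
projected-gradient dual iteration, 10 inner iterations, dual step
1/(4*ndim*w)); wavelet subproblem (Daubechies-4, 3 levels, periodization
boundary — an orthonormal perfect-reconstruction transform, so
soft-thresholding all coefficients is the *exact* prox); average the two
solutions; FISTA momentum update. Under the centered unitary FFT convention
and RSS-normalized coils, ||A|| <= 1, so the fixed step size 1.0 needs no
line search. Images stay complex throughout; magnitude is taken only at the
metrics boundary. The objective is recorded at `x0` and after every outer
iteration.

Two coil-handling paths exist: reconstruction with known sensitivities
(default; the phantom's own maps) and per-coil reconstruction with a unit
coil followed by SoS combination, for data whose sensitivities are unknown.
SVD coil compression to `n` virtual coils is provided for multi-coil data
reduction.

**Data scale.** Regularization weights are only meaningful relative to the
data scale, so the pipeline (and the CLI) normalizes the measured k-space
to unit L2 norm before reconstruction; the reference volume is divided by
the same factor, and the output can be rescaled back. This is the
convention that makes a fixed weight grid — here ten log-spaced values
3.2e-3 down to 1.0e-7 per axis, a 10x10 = 100-cell sweep — span the full
transition from under- to over-regularization. Every metric used here is
invariant to this common rescale.

## Metrics

All 2D metrics operate on craniocaudal maximum intensity projections.
Masked variants apply the 3D brain mask to the *volume* before projection
(removing out-of-mask structure along the ray), and each comparison
normalizes both images by the maximum of the relevant reference MIP, so the
PSNR peak value and the SSIM dynamic range are 1. A consequence used as a
test invariant: voxels outside the brain mask cannot change a masked metric
at all.

* NMSE = MSE(ref, rec) / MSE(ref, 0); PSNR = 10 log10(MAX^2 / MSE), with an
  infinite sentinel for identical images.
* SSIM: uniform (unweighted) 8x8 windows, stride 1, valid windows only,
  population statistics; c1 = (0.01 L)^2, c2 = (0.03 L)^2 with L the
  dynamic range. The canonical denominator form
  (mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2) is used.
* Forced-keypoint SIFT: DoG keypoints (3 scales/octave, sigma0 = 1.6,
  contrast threshold 0.03 on ~[0,1] images, edge ratio 10, dominant
  orientation only, at most the 500 strongest) are detected on the
  reference MIP only; 4x4x8 gradient-histogram descriptors are then
  computed on *both* images at identical (position, scale, orientation)
  tuples — never re-detected on the reconstruction — and the score is the
  mean Euclidean distance over pairs (0 for identical images; exactly
  invariant to a constant intensity offset because descriptors are built
  from gradients). Keypoint counts are data-dependent; on the default
  phantom's masked MIP they are of order tens, not the hundreds a real
  angiogram yields.
* CNR: computed on full 3D volumes, (mean over arterial mask − mean over
  parenchymal mask) / population SD of (reference − reconstruction) over
  the parenchymal mask; infinite sentinel (with a warning) if the
  difference vanishes.
* Slice NMSE: per-craniocaudal-slice NMSE averaged over slices with nonzero
  reference.

## Sweep and rankings

One reconstruction plus one full metric evaluation per grid cell, iterated
in a fixed order (alphas outer, betas inner); reference keypoints are
detected once and reused. `top_k` sorts by value with ties broken by
(alpha, beta) descending, so rankings are reproducible. Observer scores
(1–5 per cell) are optional external input — the package never fabricates
them — and are compared to metrics by Spearman rank correlation after
orienting each metric so higher is better. Reports: per-metric 10x10 (or
5x5) color maps with alpha increasing downward and beta rightward, a full
CSV that round-trips losslessly, and top-10 tables per metric.

## Desk-scale experiment sizes

The end-to-end concordance experiment uses a 96x96x48 phantom, 2 simulated
coils, 21% sampling, a 5x5 grid (every other value of the ten-value grid,
containing both the heaviest pair 3.2e-3 and the mid-grid 3.2e-5), seeds
1–5, and single-precision (complex64) solver arithmetic — the working
precision of clinical MR reconstruction. Exact-recovery and adjointness
tests run in double precision. Numerical tolerances follow from the
representation: 1e-10/1e-8 for float64 identities, 1e-6 for iterative
recovery, 1e-3 for the 10-iteration-budget TV prox against the exact 1D
solution.

## Known limitations

* The phantom's vessel geometry is synthetic; nothing here validates
  metric–radiologist concordance on real data.
* The TV prox is approximate (fixed 10 dual iterations), and the splitting
  averages the two subproblem solutions rather than computing the exact
  prox of the combined penalty. The averaged map's fixed point is therefore
  not a minimizer of the composite objective, and in the strongly
  TV-dominated corner of the weight grid (beta >> alpha, where the wavelet
  subproblem is nearly the identity) the recorded objective can *rise* from
  the zero-filled start over the fixed 15 iterations. This is a property of
  the averaging scheme itself — it persists without momentum, with doubled
  subproblem weights and with a well-converged TV prox — and matters only
  for weight pairs the sweep ranks as poor anyway.
* SIFT detection uses discrete (non-interpolated) extrema; keypoint
  positions are integer grid locations per octave. For forced-pair
  comparison this is immaterial since both images use the same tuples.
* Masks of real scans (brain extraction, vessel segmentation) are out of
  scope; user-supplied masks are accepted as NIfTI files.
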