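# Methods

## Problem and model

`ctdirnet` performs unsupervised deformable image registration (DIR) of
thoracic CT pairs for adaptive radiotherapy: given an initial (planning) CT
`iCT` and a later verification CT `vCT` on the same grid, a convolutional
encoder–decoder predicts a dense displacement field `g` (one 3-vector per
voxel, in voxel units).  A spatial transformer then forms the synthetic CT by
backward warping,

    sCT(p) = vCT(p + g(p)),

with trilinear interpolation and border clamping.  Training needs no
ground-truth correspondences: the network is optimized so that `sCT`
resembles `iCT` under the combined objective

    L = L_wMAE + alpha * L_smooth            ("wMAE" variant)
    L = L_wMAE + alpha * L_smooth + beta * L_struct   ("M+S" variant)

* **HU-weighted MAE.**  `L_wMAE = mean_p w_p |iCT(p) - sCT(p)|` with
  `w_p = clamp(iCT_norm(p), w_min, 1)` on normalized intensities.  Weighting
  by the reference intensity makes dense tissue (bone, ~0.57 after
  normalization) count an order of magnitude more than lung (~0.07), which
  suppresses high-HU artifacts.  Raw HU would give negative weights in air,
  so the normalized intensity is clamped below at `w_min = 0.05`; air still
  contributes, and the "higher HU, larger weight" ordering is preserved.
* **Smoothness.**  `L_smooth` is the mean (over 3 components x 3 axes x N
  voxels) of squared forward-difference gradients of `g`, zero on last-index
  faces.  The 1/(3N) normalization makes `alpha` transfer across grid sizes;
  with an unnormalized sum the effective regularization would grow with N.
* **Structure similarity.**  For the M+S variant each contour of interest
  (CTV and five organs at risk) is a binary bitmap; the moving bitmaps are
  warped by the same field (kept as floats inside the loss so it stays
  differentiable) and compared with the reference bitmaps by the global
  structural similarity index

      SSIM(x, y) = (2 mu_x mu_y + C1)(2 cov_xy + C2)
                   / ((mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2)),

  `C1 = (0.01 R)^2`, `C2 = (0.03 R)^2`, dynamic range `R = 1` for bitmaps and
  normalized volumes.  Since SSIM = 1 means perfect agreement, the *loss* is
  `1 - mean SSIM over structures`, so minimization improves agreement.
  Statistics are whole-volume (no sliding window), matching the single-formula
  definition used for per-structure scoring.
* **Random-mask augmentation.**  Each training sample has one randomly
  placed `m^3` cube (default m = 5) set to 0 at the same location in both
  `iCT` and `vCT` (0 in normalized units = -1000 HU = air).  The cube corner
  is uniform over all in-bounds positions.  Masking injects noise, acts
  against overfitting, and pushes the network to refine different
  sub-regions on different batches.  Masks are never applied at inference.

Default hyperparameters: `alpha = 0.01`, `beta = 0.1`, mask size `m = 5`,
Adam with learning rate 1e-4, beta1 = 0.9, beta2 = 0.999, batch size 4.

## Network

A UNet-style architecture on 2-channel input (iCT, vCT concatenated): every
convolution is 3-D, kernel 3, stride 1, followed by LeakyReLU(0.2); 2x max
pooling between encoder levels; nearest-neighbour 2x up-sampling and skip
concatenation in the decoder; a final 3-channel convolution with weights
initialized from N(0, 1e-5) and zero bias, so a fresh network starts at
(essentially) the identity transform.  Default channels follow the published
VoxelMorph configuration (encoder [16, 32, 32, 32], decoder
[32, 32, 32, 16, 16]); both lists are configurable, and the desk-scale test
fixtures use a lighter [8, 16, 16, 16]/[16, 16, 16, 8, 8] network.  If a skip
concatenation would yield an odd channel count, the first feature map is
duplicated (a seeded-random choice is available); input shapes must be
divisible by 2^levels.

The network, spatial transformer, losses and Adam optimizer are implemented
in NumPy on a small reverse-mode automatic-differentiation engine
(`ctdirnet.autodiff`) written for exactly the operator set this model needs.
Convolutions are evaluated as stacked-column matrix products (one GEMM per
layer); gradients of every operator are verified against central differences
in the test suite (relative error < 1e-5 in float64).  Training runs in
float32; weight files are NumPy `.npz` archives carrying the architecture
configuration for load-time validation.

## Preprocessing

CT volumes use the (z, y, x) axis convention, spacing in mm.  The
standardization chain is: 6-DOF rigid registration to a reference CT
(SimpleITK: mean-squares metric, 3-level multi-resolution, full sampling —
deterministic), resampling to 2 x 1.26 x 1.26 mm, center-crop to
136 x 384 x 384 (odd size differences keep the extra voxel on the high-index
side), and intensity normalization `v = (HU + 1000)/3000` (air -> 0,
~2000 HU -> 1, no clipping).  All constants are configurable.  Out-of-field
and pad-back voxels are filled with -1000 HU (air).  `postprocess` inverts
normalization and cropping to return synthetic CTs to the pre-crop grid; the
rigid alignment is deliberately not inverted, since the synthetic CT lives on
the reference-aligned grid of its initial CT.  Vendor-specific metal-artifact
reduction is out of scope; the preprocessing chain exposes a hook position
(apply any volume->volume callable before normalization).

## Synthetic data

No patient data ships with the package; every experiment runs on generated
phantoms.

* **Thorax phantom** — ellipsoidal soft-tissue body (40 HU), two lung
  ellipsoids (-800 HU), spherical tumor (CTV, soft tissue, default radius
  8 mm) inside the right lung, vertebral column (700 HU) with spinal cord,
  esophageal tube, cardiac ellipsoid; additive Gaussian noise (default
  sigma 5 HU).  Structure bitmaps come from the final tissue label map and
  are therefore pairwise disjoint.  Geometry is relative to the grid, so the
  same anatomy renders at any resolution; organ radii are chosen so that all
  six structures stay non-empty down to 16^3 grids (the spinal-cord radius,
  ~6 mm at default scale, is at the upper end of anatomical for that reason).
* **Deformations** — sums of low-frequency cosine modes under a separable
  sine envelope that vanishes on a 2-voxel boundary shell, rescaled so the
  peak displacement norm equals `max_displacement`.  The generator verifies
  fold-freeness (positive finite-difference Jacobian determinant everywhere)
  and refuses amplitudes that would fold.  The verification image of a pair
  is the phantom warped by such a field, so the true correspondence is known.
* **Dose grids** — sums of anisotropic Gaussian beam kernels (peak dose =
  beam weight; optional rescale to a prescription maximum; optional seeded
  noise).  These stand in for treatment-planning dose recalculations in the
  DVH/gamma evaluation stack.

What the phantoms do *not* emulate: partial-volume blur at tissue interfaces
(labels switch within one voxel), sliding motion at the pleura, topology
changes (tumor growth/shrinkage between fractions), scanner-specific noise
texture and artifacts.  Passing recovery tests therefore demonstrates the
correctness of the optimization machinery, not clinical-grade accuracy on
patient CTs.  The sharp edges make warping-based intensity recovery *harder*
than on real CT: even an exact inverse deformation leaves ~65% of the
pre-registration MAE at 64^3 (double-interpolation blur concentrated in the
~9% of voxels on tissue boundaries; the median voxel error is at the noise
level).

## Evaluation stack

* **MAE** (HU), optionally within a mask.
* **CDVH** — fraction of voxels with |dHU| strictly greater than each
  threshold; `cdvh_quantile` inverts the curve (linear interpolation), e.g.
  the |dHU| level exceeded by only 5% of voxels.
* **DSC** and per-structure **SSIM** with a tabular report (aggregate row =
  arithmetic means).  DSC of two empty masks is defined as 1.0 with a
  warning, so batch reports avoid NaN.
* **DVH** — cumulative, fraction of structure volume receiving >= d;
  indices D95/D5 by linear inversion of the curve (default bin 0.05 Gy),
  Dmean/Dmax directly, V5 as a percentage.
* **3-D gamma** — global normalization to max(ref); voxels below the
  threshold percentage of max(ref) are excluded from both map and passing
  rate; the search minimizes over evaluated-dose positions within 3x the DTA
  (beyond that the spatial term alone exceeds 1), on a subvoxel-refined
  offset grid (default factor 3, trilinear interpolation).  At refinement
  factor 1 the search is exactly the integer-offset exhaustive search, which
  the test suite cross-checks against an independent brute-force oracle.
* **Paired Student's t-test** (two-sided, df = n-1) with explicit
  degenerate-input errors (n < 2, zero-variance differences).

## Desk-scale experiment sizes

All shipped experiments are sized for a single CPU.  The registration
recovery study uses 16^3 phantoms (4 mm spacing), peak deformation 1.5
voxels, the light network, batch size 1, 300 iterations per seed, 20 seeds;
the training-progress property uses 100-iteration runs at learning rate 1e-3
on smooth 16^3 pairs, where progress is measurable above the random-mask
noise within that budget.  The acceptance script runs the same 16^3 recovery
(both variants) plus a 32^3 dose-pair gamma/DVH comparison in a few minutes.
At these scales and the published learning rate (1e-4), 300 Adam iterations
move the network only slightly; the registration machinery demonstrably
reduces MAE and improves tumor DSC, but full convergence of instance
optimization requires orders of magnitude more iterations (the original
training regime was tens of thousands of steps on a GPU cluster).  The
M+S variant reaches markedly higher propagated-structure SSIM than the wMAE
variant on the same seeds, while the wMAE variant gives the better intensity
MAE — the same qualitative trade-off the two objectives are designed around.

## Known limitations

* Instance optimization at the published learning rate needs large iteration
  budgets; for desk-scale demonstrations the structure-driven M+S variant
  converges much faster on contours than intensities.
* The gamma search radius cap (3x DTA) is exact for reporting passing rates
  (gamma values above ~3 are truncated at the cap, but all of those fail
  anyway); gamma *values* far above 1 are lower bounds.
* Rigid registration assumes a reasonable initial overlap (centered
  initialization); it is a standardization step, not a general-purpose
  registration tool.
* Structure warping uses nearest-threshold (0.5) re-binarization; very thin
  structures (1 voxel) can locally break under large deformations.
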