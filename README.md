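# ctdirnet

Unsupervised deformable image registration (DIR) for thoracic CT in adaptive
radiotherapy.  A UNet-style network maps an initial (planning) CT and a later
verification CT to a dense displacement vector field (DVF); a spatial
transformer warps the verification CT onto the planning anatomy to produce a
synthetic CT (sCT), and the same field propagates contours.  Training is
unsupervised, driven by

* an HU-weighted mean absolute error, `L_wMAE = mean_p w_p |iCT(p) − sCT(p)|`
  with `w_p ∝ clamp(iCT_norm(p), w_min, 1)`, so bone counts more than lung;
* a displacement smoothness penalty `L_smooth = mean ‖∇g‖²` (forward
  differences);
* optionally a structure term `1 − mean_j SSIM(s_iCT_j, s_sCT_j)` over CTV and
  organ-at-risk bitmaps ("M+S" variant, weight β);
* a random-mask augmentation: one m³ cube (m = 5) zeroed at the same location
  in both inputs of every training sample.

The combined objective is `L = L_wMAE + α·L_smooth (+ β·L_SSIM)` with
α = 0.01, β = 0.1, optimized with Adam (lr 1e-4, β₁ = 0.9, β₂ = 0.999).
Because no patient data ships with the package, a phantom module generates
thorax CTs (body/lung/bone/tumor compartments at realistic HU), smooth
fold-free deformations with known ground truth, structure bitmaps, and
synthetic dose grids, so the whole pipeline — preprocessing, training,
registration, contour propagation, MAE/CDVH/SSIM/DSC/DVH/3-D-gamma
evaluation — runs end-to-end on any machine.

The deep-learning stack (network, autodiff, Adam, spatial transformer) is
self-contained NumPy; rigid preprocessing is SimpleITK; I/O is NIfTI via
nibabel.

## Worked example

```python
import numpy as np
from ctdirnet import (DeformationSpec, NetworkConfig, PhantomSpec, TrainConfig,
                      dsc, instance_optimize, make_pair, make_smooth_dvf,
                      make_thorax_phantom, mae_hu, normalize)

ct, structs = make_thorax_phantom(PhantomSpec(shape=(16,)*3, spacing=(4.0,)*3, seed=1))
dvf_true = make_smooth_dvf(ct.shape, DeformationSpec(max_displacement=1.5, seed=2))
ict, vct, vstructs = make_pair(ct, structs, dvf_true)     # inter-fraction pair

cfg = TrainConfig(iterations=300, batch_size=1, seed=1, variant="M+S",
                  network=NetworkConfig(encoder_channels=[8, 16, 16, 16],
                                        decoder_channels=[16, 16, 16, 8, 8]))
dvf, sct, history, sstructs = instance_optimize(
    normalize(ict), normalize(vct), structures=(structs, vstructs), config=cfg)

print(f"MAE before {mae_hu(ict.values, vct.values):.1f} HU, "
      f"after {mae_hu(ict.values, sct.values * 3000 - 1000):.1f} HU")
print(f"tumor DSC before {dsc(vstructs['CTV'], structs['CTV']):.3f}, "
      f"after {dsc(sstructs['CTV'], structs['CTV']):.3f}")
```

```
MAE before 23.8 HU, after 26.0 HU
tumor DSC before 0.836, after 1.000
```

The M+S objective drives the propagated contours to agreement within 300
iterations (tumor DSC 0.836 → 1.000; mean structure SSIM ≈ 0.996), while the
intensity MAE moves little at the published learning rate in so few
iterations — the wMAE variant on the same pair reaches MAE 21.7 HU with mean
structure SSIM ≈ 0.89.  This is the same trade-off the two objectives are
designed around: structure fidelity (M+S) versus intensity fidelity (wMAE).
Full instance-optimization convergence needs far larger iteration budgets
(see `docs/methods.md`).

A command-line interface mirrors the library:

```sh
ctdirnet phantom --shape 32 --spacing 2 --max-disp 2 --seed 0 --out data/
ctdirnet train --data data/ --out run/
ctdirnet register --weights run/weights.npz --ict data/ict.nii.gz \
    --vct data/vct.nii.gz --structs data/ --out out/
ctdirnet evaluate --ict data/ict.nii.gz --sct out/sct.nii.gz --out report.json
ctdirnet gamma --ref dose_a.nii.gz --eval dose_b.nii.gz --criteria 3,3,10 --out g.json
```

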