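"""Shared fixtures.

The registration recovery study (20 seeds of single-pair instance
optimization on a small deformed phantom) is expensive, so it runs once per
session and is shared by the training-property and acceptance tests.  Its
conditions are fixed: 16^3 grid at 4 mm isotropic spacing, 5 HU noise, peak
ground-truth displacement 1.5 voxels, and the published training
hyperparameters (Adam 1e-4, alpha = 0.01, mask size 5) for 300 iterations.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctdirnet import (
    DeformationSpec,
    NetworkConfig,
    PhantomSpec,
    TrainConfig,
    dsc,
    instance_optimize,
    make_pair,
    make_smooth_dvf,
    make_thorax_phantom,
    mae_hu,
    normalize,
    ssim,
)

RECOVERY_SHAPE = (16, 16, 16)
RECOVERY_SPACING = (4.0, 4.0, 4.0)
RECOVERY_MAX_DISP = 1.5          # voxels
RECOVERY_ITERATIONS = 300
RECOVERY_SEEDS = tuple(range(20))
MS_SEEDS = tuple(range(5))       # subset that also runs the M+S variant

SMALL_NET = NetworkConfig(encoder_channels=[8, 16, 16, 16],
                          decoder_channels=[16, 16, 16, 8, 8])


def make_recovery_pair(seed: int):
    """One deformed phantom pair with known truth, normalized for training."""
    ct, structs = make_thorax_phantom(
        PhantomSpec(shape=RECOVERY_SHAPE, spacing=RECOVERY_SPACING, seed=seed)
    )
    dvf_true = make_smooth_dvf(
        RECOVERY_SHAPE,
        DeformationSpec(max_displacement=RECOVERY_MAX_DISP, seed=1000 + seed),
    )
    ict, vct, vstructs = make_pair(ct, structs, dvf_true)
    return ict, vct, structs, vstructs, dvf_true


def _mean_structure_ssim(truth, prop) -> float:
    return float(np.mean([
        ssim(truth[n].astype(float), prop[n].astype(float)) for n in truth.names
    ]))


def run_recovery(seed: int, variant: str = "wMAE") -> dict:
    """Instance-optimize one pair and summarize registration quality."""
    ict, vct, structs, vstructs, _ = make_recovery_pair(seed)
    a, b = normalize(ict), normalize(vct)
    cfg = TrainConfig(iterations=RECOVERY_ITERATIONS, batch_size=1, seed=seed,
                      variant=variant, network=SMALL_NET)
    out = instance_optimize(a, b, structures=(structs, vstructs), config=cfg)
    dvf, sct, history, sstructs = out
    pre_mae = mae_hu(ict.values, vct.values)
    post_mae = mae_hu(ict.values, sct.values * 3000.0 - 1000.0)
    return {
        "seed": seed,
        "variant": variant,
        "pre_mae": pre_mae,
        "post_mae": post_mae,
        "mae_ratio": post_mae / pre_mae,
        "dsc_pre": dsc(vstructs["CTV"], structs["CTV"]),
        "dsc_post": dsc(sstructs["CTV"], structs["CTV"]),
        "structure_ssim": _mean_structure_ssim(structs, sstructs),
        "loss_first": history.total[0],
        "loss_last": history.total[-1],
        "n_iterations": len(history),
    }


@pytest.fixture(scope="session")
def recovery_study():
    """20 wMAE recovery runs plus a 5-seed M+S arm for the variant comparison."""
    wmae_runs = [run_recovery(s, "wMAE") for s in RECOVERY_SEEDS]
    ms_runs = [run_recovery(s, "M+S") for s in MS_SEEDS]
    return {"wMAE": wmae_runs, "M+S": ms_runs}


@pytest.fixture(scope="session")
def small_phantom():
    """A 32^3 phantom with structures, shared by read-only tests."""
    return make_thorax_phantom(
        PhantomSpec(shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0), seed=7)
    )
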