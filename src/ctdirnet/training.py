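"""Unsupervised training loop, inference, and single-pair instance optimization.

Each training iteration samples a batch of (iCT, vCT) pairs, zeroes one
randomly placed m^3 cube at the same location in both members of every pair,
predicts the displacement field from the masked pair, warps the masked vCT,
and takes an Adam step on the combined objective against the masked iCT.
Masking forces the network to keep improving different sub-regions across
batches and acts as noise-injection regularization; it is never applied at
inference time.

``register`` is the inference path: no masking, field prediction, warping of
the verification image and (optionally) its structure bitmaps.
``instance_optimize`` specializes the loop to a single pair — train on the
singleton dataset, then register the same pair.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .errors import ConsistencyError, ParameterError
from .grids import NormVolume, StructureSet
from .model import NetworkConfig, RegistrationNetwork, build_network, predict_dvf
from .transform_losses import (
    LossWeights,
    MaskRecord,
    SSIMParams,
    apply_random_mask,
    training_objective,
    warp,
    warp_structures,
)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the published protocol: Adam with learning rate 1e-4,
    beta1 = 0.9, beta2 = 0.999, batch size 4, random-mask size 5.
    """

    lr: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 4
    mask_size: int = 5
    loss: LossWeights = field(default_factory=LossWeights)
    ssim_params: SSIMParams = field(default_factory=SSIMParams)
    variant: str = "wMAE"
    iterations: int = 300
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ParameterError("lr must be positive")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if self.mask_size < 0:
            raise ParameterError("mask_size must be >= 0")
        if self.variant not in ("wMAE", "M+S"):
            raise ParameterError(f"unknown variant {self.variant!r}")


@dataclass
class TrainHistory:
    """Per-iteration record of the loss terms, mask placements and wall time."""

    total: list[float] = field(default_factory=list)
    terms: list[dict[str, float]] = field(default_factory=list)
    mask_records: list[list[MaskRecord]] = field(default_factory=list)
    seconds: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.total)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[ad.Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _as_array(vol) -> np.ndarray:
    arr = vol.values if isinstance(vol, NormVolume) else np.asarray(vol)
    return arr.astype(np.float32, copy=False)


def _mask_dict(structs) -> dict[str, np.ndarray] | None:
    if structs is None:
        return None
    if isinstance(structs, StructureSet):
        return {n: structs[n] for n in structs.names}
    return dict(structs)


def _split_structs(structs):
    """A pair's structures: None, one set for both sides, or (iCT set, vCT set)."""
    if structs is None:
        return None, None
    if isinstance(structs, tuple):
        si, sv = structs
        return _mask_dict(si), _mask_dict(sv)
    d = _mask_dict(structs)
    return d, d


def _normalize_pairs(pairs, config: TrainConfig):
    out = []
    shape = None
    for pair in pairs:
        if len(pair) == 2:
            (ict, vct), structs = pair, None
        else:
            ict, vct, structs = pair
        a, b = _as_array(ict), _as_array(vct)
        if a.shape != b.shape:
            raise ConsistencyError(f"pair shape mismatch {a.shape} vs {b.shape}")
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise ConsistencyError("all training pairs must share one grid shape")
        si, sv = _split_structs(structs)
        if config.variant == "M+S" and si is None:
            raise ParameterError("the M+S variant requires structures for every pair")
        out.append((a, b, si, sv))
    if not out:
        raise ParameterError("at least one training pair is required")
    return out, shape


def train(pairs, config: TrainConfig = TrainConfig(),
          net: RegistrationNetwork | None = None) -> tuple[RegistrationNetwork, TrainHistory]:
    """Run the iterative masked-training loop; returns the network and history.

    ``pairs`` is a list of ``(ict, vct)`` or ``(ict, vct, structures)`` where
    ``structures`` is a StructureSet / name->bitmap dict shared by both sides,
    or an ``(ict_structs, vct_structs)`` tuple.  Fully reproducible for a
    fixed ``config.seed``: network initialization, batch sampling and mask
    placement all derive from it.
    """
    data, shape = _normalize_pairs(pairs, config)
    if net is None:
        net = build_network(config.network, seed=config.seed)
    net._check_shape(shape)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(net.parameters(), config.lr, config.adam_beta1,
               config.adam_beta2, config.adam_eps)
    history = TrainHistory()
    use_structs = config.variant == "M+S"

    for _ in range(config.iterations):
        t0 = time.perf_counter()
        idx = rng.integers(0, len(data), size=config.batch_size)
        opt.zero_grad()
        batch_terms: dict[str, float] = {}
        batch_masks: list[MaskRecord] = []
        total = 0.0
        for i in idx:
            ict, vct, si, sv = data[i]
            ict_m, vct_m, rec = apply_random_mask(ict, vct, config.mask_size, rng)
            batch_masks.append(rec)
            dvf = net.forward(ad.Tensor(np.stack([ict_m, vct_m])))
            loss, terms = training_objective(
                ict_m, vct_m, dvf,
                struct_masks_i=si if use_structs else None,
                struct_masks_v=sv if use_structs else None,
                weights=config.loss, variant=config.variant,
                ssim_params=config.ssim_params,
            )
            loss.backward(np.asarray(1.0 / config.batch_size, dtype=np.float32))
            total += terms["total"] / config.batch_size
            for key, value in terms.items():
                batch_terms[key] = batch_terms.get(key, 0.0) + value / config.batch_size
        opt.step()
        history.total.append(total)
        history.terms.append(batch_terms)
        history.mask_records.append(batch_masks)
        history.seconds.append(time.perf_counter() - t0)
    return net, history


def register(net: RegistrationNetwork, ict, vct, vstructs: StructureSet | None = None):
    """Inference: predict the field, warp vCT -> sCT, propagate structures.

    No masking is applied.  Returns ``(dvf, sct)`` or ``(dvf, sct, sstructs)``
    when structures are given; bitmaps are warped with the same field and
    thresholded at 0.5.  ``sct`` has the same type as ``vct``.
    """
    dvf = predict_dvf(net, ict, vct)
    sct = warp(vct, dvf)
    if vstructs is None:
        return dvf, sct
    return dvf, sct, warp_structures(vstructs, dvf)


def instance_optimize(ict, vct, structures=None, config: TrainConfig = TrainConfig()):
    """Optimize the network on one pair, then register that same pair.

    ``structures`` follows the per-pair convention of :func:`train`.  Returns
    ``(dvf, sct, history)``, plus the propagated vCT structures as a fourth
    element when structures were supplied.
    """
    pair = (ict, vct) if structures is None else (ict, vct, structures)
    net, history = train([pair], config)
    _, sv = _split_structs(structures)
    if sv is not None:
        dvf, sct, sstructs = register(net, ict, vct, StructureSet(sv))
        return dvf, sct, history, sstructs
    dvf, sct = register(net, ict, vct)
    return dvf, sct, history
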