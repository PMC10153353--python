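"""UNet-style registration network: (iCT, vCT) pair -> dense displacement field.

The encoder stacks 3-D convolutions (kernel 3, stride 1, LeakyReLU 0.2) with 2x
max-pooling between levels; the decoder mirrors it with nearest-neighbour
up-sampling and skip concatenation from the matching encoder level.  The final
3-channel head is initialized near zero so an untrained network starts at
(almost) the identity transform.  When a concatenation would produce an odd
channel count, the first feature map is duplicated (deterministically by
default) to keep counts even.

Implemented on the package's NumPy autodiff engine; weights are float32.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .errors import ConsistencyError, ParameterError, WeightsFormatError
from .grids import DisplacementField, NormVolume


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``encoder_channels`` has one entry per encoder level (the number of
    down-samplings is ``len(encoder_channels) - 1``); ``decoder_channels``
    lists the decoder convolutions — the first ``levels`` of them each precede
    an up-sample + skip concatenation, the rest run at full resolution.
    """

    encoder_channels: list[int] = field(default_factory=lambda: [16, 32, 32, 32])
    decoder_channels: list[int] = field(default_factory=lambda: [32, 32, 32, 16, 16])
    kernel_size: int = 3
    leaky_slope: float = 0.2
    duplicate: str = "first"      # odd-channel fix: "first" or "random"

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ParameterError("kernel_size must be odd")
        if self.leaky_slope <= 0:
            raise ParameterError("leaky_slope must be positive")
        if any(c <= 0 for c in self.encoder_channels + self.decoder_channels):
            raise ParameterError("all channel counts must be positive")
        if len(self.decoder_channels) < self.levels:
            raise ParameterError("need at least one decoder conv per up-sampling level")
        if self.duplicate not in ("first", "random"):
            raise ParameterError("duplicate must be 'first' or 'random'")

    @property
    def levels(self) -> int:
        """Number of 2x down-sampling steps."""
        return len(self.encoder_channels) - 1

    def to_dict(self) -> dict:
        return {
            "encoder_channels": list(self.encoder_channels),
            "decoder_channels": list(self.decoder_channels),
            "kernel_size": self.kernel_size,
            "leaky_slope": self.leaky_slope,
            "duplicate": self.duplicate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


def _conv_plan(config: NetworkConfig) -> list[tuple[int, int]]:
    """(in_channels, out_channels) for every convolution, in forward order."""
    plan: list[tuple[int, int]] = []
    levels = config.levels
    in_ch = 2
    skips: list[int] = []
    for i, ch in enumerate(config.encoder_channels):
        plan.append((in_ch, ch))
        in_ch = ch
        if i < levels:
            skips.append(ch)
    for j, ch in enumerate(config.decoder_channels):
        plan.append((in_ch, ch))
        in_ch = ch
        if j < levels:
            in_ch = in_ch + skips[levels - 1 - j]
            if in_ch % 2:
                in_ch += 1          # duplicated feature map
    plan.append((in_ch, 3))          # displacement head
    return plan


class RegistrationNetwork:
    """A built network: configuration plus learnable convolution weights."""

    def __init__(self, config: NetworkConfig, params: list[tuple[ad.Tensor, ad.Tensor]],
                 seed: int = 0):
        self.config = config
        self.params = params          # [(weight, bias), ...] in forward order
        self._dup_rng = np.random.default_rng(seed)

    def parameters(self) -> list[ad.Tensor]:
        out: list[ad.Tensor] = []
        for w, b in self.params:
            out.extend((w, b))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _check_shape(self, shape) -> None:
        div = 2 ** self.config.levels
        if any(s % div for s in shape):
            raise ParameterError(
                f"input shape {tuple(shape)} not divisible by 2^levels = {div}"
            )

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        """Map a (2, nz, ny, nx) input tensor to a (3, nz, ny, nx) field tensor."""
        cfg = self.config
        if x.data.ndim != 4 or x.data.shape[0] != 2:
            raise ConsistencyError(f"network input must be (2, nz, ny, nx), got {x.data.shape}")
        self._check_shape(x.data.shape[1:])
        levels = cfg.levels
        it = iter(self.params)
        skips: list[ad.Tensor] = []
        for i in range(len(cfg.encoder_channels)):
            w, b = next(it)
            x = ad.leaky_relu(ad.conv3d(x, w, b), cfg.leaky_slope)
            if i < levels:
                skips.append(x)
                x = ad.maxpool2(x)
        for j in range(len(cfg.decoder_channels)):
            w, b = next(it)
            x = ad.leaky_relu(ad.conv3d(x, w, b), cfg.leaky_slope)
            if j < levels:
                x = ad.upsample2(x)
                x = ad.concat([x, skips[levels - 1 - j]])
                if x.data.shape[0] % 2:
                    if cfg.duplicate == "first":
                        idx = 0
                    else:
                        idx = int(self._dup_rng.integers(0, x.data.shape[0]))
                    x = ad.concat([x, ad.narrow_channels(x, idx, idx + 1)])
        w, b = next(it)
        return ad.conv3d(x, w, b)


def build_network(config: NetworkConfig = NetworkConfig(), seed: int = 0) -> RegistrationNetwork:
    """Initialize a network: He-style conv init, near-zero displacement head.

    Deterministic for a fixed seed; the head weights are drawn from
    N(0, 1e-5) with zero bias so a fresh network predicts |DVF| << 1 voxel.
    """
    rng = np.random.default_rng(seed)
    k = config.kernel_size
    params: list[tuple[ad.Tensor, ad.Tensor]] = []
    plan = _conv_plan(config)
    for i, (cin, cout) in enumerate(plan):
        is_head = i == len(plan) - 1
        if is_head:
            w = rng.normal(0.0, 1e-5, size=(cout, cin, k, k, k))
        else:
            std = np.sqrt(2.0 / (cin * k ** 3))
            w = rng.normal(0.0, std, size=(cout, cin, k, k, k))
        params.append((ad.parameter(w.astype(np.float32)),
                       ad.parameter(np.zeros(cout, dtype=np.float32))))
    return RegistrationNetwork(config, params, seed=seed)


def _pair_input(ict, vct) -> np.ndarray:
    a = ict.values if isinstance(ict, NormVolume) else np.asarray(ict)
    b = vct.values if isinstance(vct, NormVolume) else np.asarray(vct)
    if a.shape != b.shape:
        raise ConsistencyError(f"iCT shape {a.shape} != vCT shape {b.shape}")
    return np.stack([a, b]).astype(np.float32)


def predict_dvf(net: RegistrationNetwork, ict, vct) -> DisplacementField:
    """Predict the displacement field registering vCT onto iCT (voxel units)."""
    x = ad.Tensor(_pair_input(ict, vct))
    out = net.forward(x)
    spacing = ict.spacing if isinstance(ict, NormVolume) else (1.0, 1.0, 1.0)
    return DisplacementField(out.data.astype(np.float64), spacing=spacing)


def save_weights(net: RegistrationNetwork, path) -> None:
    """Serialize configuration and weights to a .npz archive."""
    arrays = {}
    for i, (w, b) in enumerate(net.params):
        arrays[f"w{i}"] = w.data
        arrays[f"b{i}"] = b.data
    arrays["config_json"] = np.frombuffer(
        json.dumps(net.config.to_dict()).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_weights(path, config: NetworkConfig | None = None) -> RegistrationNetwork:
    """Load a network saved by :func:`save_weights`.

    If ``config`` is given it must match the stored configuration exactly,
    otherwise a :class:`WeightsFormatError` is raised.
    """
    try:
        with np.load(path) as data:
            stored = NetworkConfig.from_dict(
                json.loads(bytes(data["config_json"]).decode())
            )
            n_convs = len(_conv_plan(stored))
            params = []
            for i in range(n_convs):
                params.append((ad.parameter(data[f"w{i}"]), ad.parameter(data[f"b{i}"])))
    except (KeyError, ValueError, OSError, json.JSONDecodeError) as exc:
        raise WeightsFormatError(f"cannot read weights file {path}: {exc}") from exc
    if config is not None and config.to_dict() != stored.to_dict():
        raise WeightsFormatError(
            f"stored config {stored.to_dict()} does not match requested {config.to_dict()}"
        )
    return RegistrationNetwork(stored, params)
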