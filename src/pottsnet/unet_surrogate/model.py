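"""The periodic U-Net surrogate: architecture, prediction, recursive rollout.

A classic encoder-decoder with skip connections reconstructed at configurable
depth and width (the published schematic fixes neither): two 3x3
circular-padded convolutions with PReLU per level, 2x2 max-pool downsampling,
nearest-neighbor upsampling with a channel-halving convolution, and two 1x1
heads — mask logits (sigmoid applied at prediction time) and a linear field
head (clipped at zero at prediction time, keeping concentrations physical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List

import numpy as np

from ..dataset_builder import TwoChannelFrame
from ._nn import Adam, Conv2d, MaxPool2, Param, PReLU, Sequential, Upsample2

__all__ = [
    "SurrogateConfig",
    "UNet",
    "build_surrogate",
    "predict",
    "rollout",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class SurrogateConfig:
    """Architecture and training settings for the surrogate.

    ``depth`` encoder/decoder levels with ``base_channels`` filters at the top,
    doubling per level; every convolution is circularly padded; activations
    are PReLU.  The loss weights reproduce the published balance: binary
    cross-entropy on the mask channel plus 10x mean-squared error on the
    field channel.
    """

    depth: int = 4
    base_channels: int = 32
    kernel_size: int = 3
    in_channels: int = 2
    loss_mask_weight: float = 1.0
    loss_field_weight: float = 10.0
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    horizon: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateConfig":
        return cls(**d)


def _block(c_in: int, c_out: int, k: int, rng) -> Sequential:
    return Sequential(
        Conv2d(c_in, c_out, k, rng), PReLU(c_out),
        Conv2d(c_out, c_out, k, rng), PReLU(c_out),
    )


class UNet:
    """Hand-wired U-Net over the layer engine in ``_nn``.

    ``forward`` returns (mask_logits, field) with the input's spatial shape;
    ``backward`` consumes the two head gradients.  Calling the model on a
    :class:`TwoChannelFrame` runs :func:`predict`.
    """

    def __init__(self, config: SurrogateConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        B, d, k = config.base_channels, config.depth, config.kernel_size
        widths = [B * 2 ** i for i in range(d + 1)]

        self.enc = []
        c_in = config.in_channels
        for i in range(d):
            self.enc.append(_block(c_in, widths[i], k, rng))
            c_in = widths[i]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _block(widths[d - 1], widths[d], k, rng)
        self.ups = []
        self.up_convs = []
        self.dec = []
        for i in reversed(range(d)):
            self.ups.append(Upsample2())
            self.up_convs.append(Sequential(Conv2d(widths[i + 1], widths[i], k, rng),
                                            PReLU(widths[i])))
            self.dec.append(_block(widths[i] * 2, widths[i], k, rng))
        self.mask_head = Conv2d(widths[0], 1, 1, rng)
        self.field_head = Conv2d(widths[0], 1, 1, rng)
        self._skip_channels = None

    # -- plumbing ----------------------------------------------------------
    def modules(self) -> List:
        mods = list(self.enc) + self.pools + [self.bottleneck]
        mods += self.ups + self.up_convs + list(self.dec)
        mods += [self.mask_head, self.field_head]
        return mods

    def params(self) -> List[Param]:
        out = []
        for m in self.modules():
            out.extend(m.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _check_shape(self, x: np.ndarray) -> None:
        h, w = x.shape[2], x.shape[3]
        f = 2 ** self.config.depth
        if h % f or w % f:
            raise ValueError(
                f"lattice size {h}x{w} not divisible by the downsampling factor {f}"
            )

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple:
        """x (N, 2, H, W) float32 -> (mask_logits (N,1,H,W), field (N,1,H,W))."""
        self._check_shape(x)
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, up_conv, dec, skip in zip(self.ups, self.up_convs, self.dec, reversed(skips)):
            h = up_conv.forward(up.forward(h))
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h)
        return self.mask_head.forward(h), self.field_head.forward(h)

    def backward(self, d_mask_logits: np.ndarray, d_field: np.ndarray) -> None:
        dh = self.mask_head.backward(d_mask_logits) + self.field_head.backward(d_field)
        d_skips = []
        for up, up_conv, dec, c_skip in zip(
            reversed(self.ups), reversed(self.up_convs), reversed(self.dec),
            self._skip_channels,
        ):
            dh = dec.backward(dh)
            d_skips.append(dh[:, :c_skip])
            dh = up.backward(up_conv.backward(dh[:, c_skip:]))
        # d_skips was collected shallowest-first; the encoder walks deepest-first
        dh = self.bottleneck.backward(dh)
        for enc, pool, d_skip in zip(
            reversed(self.enc), reversed(self.pools), reversed(d_skips)
        ):
            dh = pool.backward(dh)
            dh = enc.backward(dh + d_skip)

    def make_optimizer(self) -> Adam:
        return Adam(self.params(), lr=self.config.learning_rate)

    # -- convenience -------------------------------------------------------
    def __call__(self, frame: TwoChannelFrame) -> TwoChannelFrame:
        return predict(self, frame)

    def state_arrays(self) -> List[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: List[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.value = a.astype(np.float32)


def build_surrogate(config: SurrogateConfig) -> UNet:
    """Construct the (untrained) periodic U-Net; weights seeded by config.seed."""
    return UNet(config)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def predict(model: UNet, frame: TwoChannelFrame) -> TwoChannelFrame:
    """One-step prediction: the frame ``horizon`` MCS ahead (nominally).

    The mask channel holds sigmoid probabilities in (0, 1); the field channel
    is clipped at 0 to keep concentrations physical.
    """
    x = frame.to_array()[None]
    logits, fld = model.forward(x)
    return TwoChannelFrame(
        mask=_sigmoid(logits[0, 0]).astype(np.float32),
        field=np.maximum(fld[0, 0], 0.0).astype(np.float32),
        mcs=frame.mcs + model.config.horizon,
        sim_id=frame.sim_id,
    )


def rollout(
    model: UNet, frame: TwoChannelFrame, n_iterations: int, binarize: bool = False
) -> List[TwoChannelFrame]:
    """Recursive prediction: feed each output back as the next input.

    Continuous mask probabilities are re-fed by default (the smoothing they
    carry is part of the surrogate's documented failure mode); ``binarize``
    thresholds at 0.5 between steps instead.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    frames = []
    current = frame
    for _ in range(n_iterations):
        current = predict(model, current)
        frames.append(current)
        if binarize:
            current = TwoChannelFrame(
                mask=(current.mask > 0.5).astype(np.float32),
                field=current.field,
                mcs=current.mcs,
                sim_id=current.sim_id,
            )
    return frames


def save_checkpoint(model: UNet, path: str) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(model.config.to_dict()), **arrays)


def load_checkpoint(path: str) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        config = SurrogateConfig.from_dict(json.loads(str(data["config"])))
        model = UNet(config)
        arrays = [data[f"p{i}"] for i in range(len(model.params()))]
    model.load_state_arrays(arrays)
    return model
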