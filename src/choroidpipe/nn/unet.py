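"""Depth-7 multi-head U-Net for joint region/vessel/fovea prediction.

Encoder blocks are two 3x3 convolutions each followed by batch
normalisation and ReLU; the first three blocks raise the channel width
from 8 to 64, after which it stays constant to bound the parameter
count. Downsampling is 2x2 max pooling. Up-blocks use a 1x1 convolution
to reduce the channel dimension followed by bilinear interpolation
(cheaper than transposed convolutions), concatenate the encoder skip,
and apply another two-convolution block. A final 1x1 convolution
produces three logit channels (region, vessel, fovea); sigmoids are
applied at prediction time. The network is fully convolutional: any
input whose sides are divisible by 2**(depth-1) = 64 is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm2d, BilinearUp2d, Conv2d, Layer, MaxPool2d, ReLU

__all__ = ["UNetConfig", "UNet", "build_unet"]


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 7
    encoder_channels: tuple[int, ...] = (8, 32, 64, 64, 64, 64, 64)
    out_channels: int = 3
    in_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.encoder_channels) != self.depth:
            raise ValueError("encoder_channels must have one entry per level")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")

    @property
    def divisor(self) -> int:
        return 2 ** (self.depth - 1)


class _ConvBlock:
    """Two Conv3x3 -> BatchNorm -> ReLU stages."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        self.layers: list[Layer] = [
            Conv2d(in_ch, out_ch, 3, rng), BatchNorm2d(out_ch), ReLU(),
            Conv2d(out_ch, out_ch, 3, rng), BatchNorm2d(out_ch), ReLU(),
        ]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet:
    """Fully convolutional multi-head U-Net (see module docstring)."""

    def __init__(self, config: UNetConfig | None = None, seed: int = 0) -> None:
        self.config = config or UNetConfig()
        rng = np.random.default_rng(seed)
        ch = self.config.encoder_channels
        d = self.config.depth

        self.enc_blocks = [_ConvBlock(self.config.in_channels, ch[0], rng)]
        self.enc_blocks += [_ConvBlock(ch[i - 1], ch[i], rng) for i in range(1, d)]
        self.pools = [MaxPool2d() for _ in range(d - 1)]

        # decoder from the bottleneck up: reduce channels to the skip
        # level's width, upsample, concatenate, convolve
        self.up_reduce = [Conv2d(ch[i + 1], ch[i], 1, rng) for i in range(d - 2, -1, -1)]
        self.ups = [BilinearUp2d() for _ in range(d - 1)]
        self.dec_blocks = [
            _ConvBlock(2 * ch[i], ch[i], rng) for i in range(d - 2, -1, -1)
        ]
        self.head = Conv2d(ch[0], self.config.out_channels, 1, rng)

    # -- plumbing -----------------------------------------------------------
    def _all_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        for blk in self.enc_blocks + self.dec_blocks:
            layers.extend(blk.layers)
        layers.extend(self.up_reduce)
        layers.append(self.head)
        return layers

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, name) for l in self._all_layers() for name in l.params]

    def zero_grad(self) -> None:
        for layer in self._all_layers():
            layer.zero_grad()

    def grad_norm(self) -> float:
        total = 0.0
        for layer, name in self.parameters():
            g = layer.grads[name]
            total += float(np.sum(g.astype(np.float64) ** 2))
        return float(np.sqrt(total))

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._all_layers()):
            for name, val in layer.params.items():
                out[f"{i}.{name}"] = val.copy()
            if isinstance(layer, BatchNorm2d):
                out[f"{i}.running_mean"] = layer.running_mean.copy()
                out[f"{i}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._all_layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Input (N, 1, H, W) -> logits (N, out_channels, H, W)."""
        n, c, h, w = x.shape
        div = self.config.divisor
        if h % div or w % div:
            raise ValueError(f"input sides must be divisible by {div}, got {h}x{w}")
        x = x.astype(np.float32)
        skips = []
        for i, blk in enumerate(self.enc_blocks):
            x = blk.forward(x, training)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for reduce, up, blk, skip in zip(
            self.up_reduce, self.ups, self.dec_blocks, reversed(skips)
        ):
            x = reduce.forward(x, training)
            x = up.forward(x, training)
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for a batch (input grad discarded)."""
        d = self.config.depth
        dy = self.head.backward(dlogits.astype(np.float32))
        # decoder: dec_blocks[j] consumed concat(skip_{d-2-j}, upsampled)
        dskips: dict[int, np.ndarray] = {}
        for j in range(d - 2, -1, -1):
            dcat = self.dec_blocks[j].backward(dy)
            skip_level = d - 2 - j
            ch = self._skip_channels[skip_level]
            dskips[skip_level] = dcat[:, :ch]
            dy = self.up_reduce[j].backward(self.ups[j].backward(dcat[:, ch:]))
        # encoder: dy is now the gradient at the bottleneck block's output
        for i in range(d - 1, -1, -1):
            dy = self.enc_blocks[i].backward(dy)
            if i > 0:
                dy = self.pools[i - 1].backward(dy) + dskips[i - 1]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x, training=False)
        return 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    return UNet(config, seed)
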