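"""Network architectures: per-pixel 1D estimator and residual U-Net.

Two estimators mirror the two ways of consuming a multi-echo series:

``nn1d``
    A fully-connected network applied one pixel at a time: N_eta inputs,
    6 hidden layers of 64 ReLU units, 2 outputs interpreted as (S0, T).
    It can only learn the decay-curve-to-parameter inverse mapping — no
    spatial context.

``cnn``
    A 2D residual U-Net over whole image series: N_eta input channels,
    4 encoder/decoder levels with increasing widths, 3x3 convolutions,
    batch normalization and PReLU activations, residual units in the
    first two downsampling levels, and a 2-channel (S0, T) output head.
    Convolutions let it exploit spatial correlation between neighbouring
    pixels, which is exactly the prior the naturalistic training corpus
    carries and the pixel-random corpus lacks.

The output head bias is initialised at (S0, T) = (0.5, 1.0) so the decay
forward model used by self-supervised training starts in a well-posed
region (T near zero has vanishing gradients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Linear,
    Module,
    PReLU,
    ReLU,
    Sequential,
    Upsample2x,
)

__all__ = [
    "NetworkConfig",
    "desk_config",
    "paper_config",
    "MLP1D",
    "ResidualUNet",
    "build_network",
]

_HEAD_BIAS = (0.5, 1.0)  # (S0, T) output-head bias init


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters (parameter count is a pure function
    of this config)."""

    arch: str  # "nn1d" | "cnn"
    n_inputs: int = 10
    n_outputs: int = 2
    # nn1d
    n_hidden_layers: int = 6
    hidden_width: int = 64
    # cnn
    encoder_widths: tuple[int, ...] = (128, 128, 256, 512)
    kernel: int = 3
    n_residual_levels: int = 2

    def __post_init__(self) -> None:
        if self.arch not in ("nn1d", "cnn"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.n_outputs != 2:
            raise ValueError("networks output exactly (S0, T)")
        if min(self.n_inputs, self.n_hidden_layers, self.hidden_width) < 1:
            raise ValueError("sizes must be positive")
        if any(w < 1 for w in self.encoder_widths):
            raise ValueError("encoder widths must be positive")


def paper_config(arch: str, n_inputs: int = 10) -> NetworkConfig:
    """Full-scale configuration (GPU-scale training; not used in tests)."""
    return NetworkConfig(arch=arch, n_inputs=n_inputs)


def desk_config(arch: str, n_inputs: int = 10) -> NetworkConfig:
    """Reduced configuration for CPU-scale experiments (widths [16,16,32,64])."""
    return NetworkConfig(arch=arch, n_inputs=n_inputs, encoder_widths=(16, 16, 32, 64))


class MLP1D(Module):
    """Fully-connected per-pixel estimator: decay curve -> (S0, T)."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        if config.arch != "nn1d":
            raise ValueError("MLP1D requires an nn1d config")
        self.config = config
        self.grid_eta: np.ndarray | None = None
        layers: list[Module] = [Linear(config.n_inputs, config.hidden_width, rng), ReLU()]
        for _ in range(config.n_hidden_layers - 1):
            layers += [Linear(config.hidden_width, config.hidden_width, rng), ReLU()]
        head = Linear(config.hidden_width, config.n_outputs, rng)
        head.bias.value[...] = _HEAD_BIAS
        layers.append(head)
        self.net = Sequential(*layers)

    def forward(self, x):
        if x.shape[-1] != self.config.n_inputs:
            raise ValueError(
                f"expected {self.config.n_inputs} inputs, got {x.shape[-1]}"
            )
        return self.net(x)

    def backward(self, grad):
        return self.net.backward(grad)


class _ConvBlock(Module):
    """conv -> batch norm -> PReLU."""

    def __init__(self, c_in, c_out, rng, stride=1, kernel=3):
        self.conv = Conv2d(c_in, c_out, kernel, rng, stride=stride)
        self.bn = BatchNorm2d(c_out)
        self.act = PReLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))

    def backward(self, grad):
        return self.conv.backward(self.bn.backward(self.act.backward(grad)))


class _ResUnit(Module):
    """Two-conv residual unit with a projection shortcut when needed."""

    def __init__(self, c_in, c_out, rng, stride=1, kernel=3):
        self.block1 = _ConvBlock(c_in, c_out, rng, stride=stride, kernel=kernel)
        self.conv2 = Conv2d(c_out, c_out, kernel, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.proj = (
            Conv2d(c_in, c_out, 1, rng, stride=stride)
            if (c_in != c_out or stride != 1)
            else None
        )
        self.act = PReLU()

    def forward(self, x):
        h = self.bn2(self.conv2(self.block1(x)))
        s = self.proj(x) if self.proj is not None else x
        return self.act(h + s)

    def backward(self, grad):
        g = self.act.backward(grad)
        gh = self.block1.backward(self.conv2.backward(self.bn2.backward(g)))
        gs = self.proj.backward(g) if self.proj is not None else g
        return gh + gs


class ResidualUNet(Module):
    """Residual U-Net mapping (B, N_eta, H, W) -> (B, 2, H, W).

    Encoder: one full-resolution residual unit, then three stride-2
    downsampling stages (the first a residual unit, the rest plain conv
    blocks).  Decoder: nearest-neighbour upsampling + conv, skip
    concatenation, and a conv block per level; 1x1 output head.
    H and W must be divisible by 8.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        if config.arch != "cnn":
            raise ValueError("ResidualUNet requires a cnn config")
        self.config = config
        self.grid_eta: np.ndarray | None = None
        c0, c1, c2, c3 = config.encoder_widths
        k = config.kernel
        self.enc0 = _ResUnit(config.n_inputs, c0, rng, stride=1, kernel=k)
        self.enc1 = _ResUnit(c0, c1, rng, stride=2, kernel=k)
        self.enc2 = _ConvBlock(c1, c2, rng, stride=2, kernel=k)
        self.bottleneck = _ConvBlock(c2, c3, rng, stride=2, kernel=k)
        self.up2 = Sequential(Upsample2x(), _ConvBlock(c3, c2, rng, kernel=k))
        self.dec2 = _ConvBlock(2 * c2, c2, rng, kernel=k)
        self.up1 = Sequential(Upsample2x(), _ConvBlock(c2, c1, rng, kernel=k))
        self.dec1 = _ConvBlock(2 * c1, c1, rng, kernel=k)
        self.up0 = Sequential(Upsample2x(), _ConvBlock(c1, c0, rng, kernel=k))
        self.dec0 = _ConvBlock(2 * c0, c0, rng, kernel=k)
        self.head = Conv2d(c0, config.n_outputs, 1, rng)
        head_bias = np.array(_HEAD_BIAS)
        self.head.bias.value[...] = head_bias

    def forward(self, x):
        if x.ndim != 4 or x.shape[1] != self.config.n_inputs:
            raise ValueError(
                f"expected (B, {self.config.n_inputs}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("H and W must be divisible by 8")
        x0 = self.enc0(x)
        x1 = self.enc1(x0)
        x2 = self.enc2(x1)
        xb = self.bottleneck(x2)
        d2 = self.dec2(np.concatenate([self.up2(xb), x2], axis=1))
        d1 = self.dec1(np.concatenate([self.up1(d2), x1], axis=1))
        d0 = self.dec0(np.concatenate([self.up0(d1), x0], axis=1))
        return self.head(d0)

    def backward(self, grad):
        c0, c1, c2, _ = self.config.encoder_widths
        g = self.head.backward(grad)
        g = self.dec0.backward(g)
        gu0, gx0 = g[:, :c0], g[:, c0:]
        g = self.up0.backward(gu0)
        g = self.dec1.backward(g)
        gu1, gx1 = g[:, :c1], g[:, c1:]
        g = self.up1.backward(gu1)
        g = self.dec2.backward(g)
        gu2, gx2 = g[:, :c2], g[:, c2:]
        g = self.bottleneck.backward(self.up2.backward(gu2))
        g = self.enc2.backward(g + gx2)
        g = self.enc1.backward(g + gx1)
        return self.enc0.backward(g + gx0)


def build_network(config: NetworkConfig, seed: int = 0) -> Module:
    """Instantiate a model with seed-deterministic initial weights."""
    rng = np.random.default_rng(seed)
    if config.arch == "nn1d":
        return MLP1D(config, rng)
    return ResidualUNet(config, rng)
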