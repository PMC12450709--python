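"""Network building blocks: convolutions, group normalization, attention.

All parameters are initialized from an explicit numpy Generator so model
construction is fully reproducible from a single integer seed.
"""
from __future__ import annotations

import math
from typing import Iterable, Iterator, Optional

import numpy as np

from .autodiff import Tensor, concat, conv3d, conv_transpose3d

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "SeparableConv3d",
    "GroupNorm",
    "SelfAttention3d",
    "ResidualBlock",
]


class Module:
    """Lightweight container with recursive parameter discovery."""

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            yield from _params_of(value, seen)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        seen: set[int] = set()
        yield from _named_params_of(self, prefix, seen)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _params_of(value, seen: set[int]) -> Iterator[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        if id(value) not in seen:
            seen.add(id(value))
            yield value
    elif isinstance(value, Module):
        for v in value.__dict__.values():
            yield from _params_of(v, seen)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _params_of(v, seen)


def _named_params_of(obj, prefix: str, seen: set[int]) -> Iterator[tuple[str, Tensor]]:
    if isinstance(obj, Module):
        for name, v in obj.__dict__.items():
            yield from _named_params_of(v, f"{prefix}{name}." if prefix or name else name, seen)
    elif isinstance(obj, Tensor) and obj.requires_grad:
        if id(obj) not in seen:
            seen.add(id(obj))
            yield prefix.rstrip("."), obj
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            yield from _named_params_of(v, f"{prefix}{i}.", seen)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
    ):
        k = kernel_size
        fan_in = (in_channels // groups) * k**3
        self.weight = Tensor(
            _kaiming(rng, (out_channels, in_channels // groups, k, k, k), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 2,
        padding: int = 1,
        bias: bool = True,
    ):
        k = kernel_size
        fan_in = in_channels * k**3
        self.weight = Tensor(
            _kaiming(rng, (in_channels, out_channels, k, k, k), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, self.stride, self.padding)


class SeparableConv3d(Module):
    """Depthwise 3-D convolution followed by a pointwise 1x1x1 convolution."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: int = 1,
    ):
        self.depthwise = Conv3d(
            in_channels, in_channels, kernel_size, rng, padding=padding, groups=in_channels
        )
        self.pointwise = Conv3d(in_channels, out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class GroupNorm(Module):
    """Group normalization over (channels/groups, spatial) with affine scale."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError(f"channels {num_channels} not divisible by groups {num_groups}")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.gamma = Tensor(np.ones(num_channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        N, C = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        g = self.num_groups
        xg = x.reshape(N, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2.0).mean(axis=2, keepdims=True)
        normed = (xg - mu) * ((var + self.eps) ** -0.5)
        out = normed.reshape(N, C, *spatial)
        shape = (1, C) + (1,) * len(spatial)
        return out * self.gamma.reshape(shape) + self.beta.reshape(shape)


class SelfAttention3d(Module):
    """Multi-head self-attention over the flattened voxel grid, with residual."""

    def __init__(self, channels: int, rng: np.random.Generator, heads: int = 1):
        if channels % heads:
            raise ValueError("channels must be divisible by heads")
        self.channels = channels
        self.heads = heads
        c = channels
        self.wq = Tensor(_kaiming(rng, (c, c), c), requires_grad=True)
        self.wk = Tensor(_kaiming(rng, (c, c), c), requires_grad=True)
        self.wv = Tensor(_kaiming(rng, (c, c), c), requires_grad=True)
        self.wo = Tensor(_kaiming(rng, (c, c), c), requires_grad=True)
        self.bq = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.bk = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.bv = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.bo = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        N, C = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        T = int(np.prod(spatial))
        h = self.heads
        dh = C // h
        tokens = x.reshape(N, C, T).transpose((0, 2, 1))  # (N, T, C)
        q = tokens @ self.wq + self.bq
        k = tokens @ self.wk + self.bk
        v = tokens @ self.wv + self.bv

        def split(t: Tensor) -> Tensor:
            return t.reshape(N, T, h, dh).transpose((0, 2, 1, 3))  # (N, h, T, dh)

        q, k, v = split(q), split(k), split(v)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (N, h, T, dh)
        ctx = ctx.transpose((0, 2, 1, 3)).reshape(N, T, C)
        out = ctx @ self.wo + self.bo
        out = out.transpose((0, 2, 1)).reshape(N, C, *spatial)
        return x + out


class ResidualBlock(Module):
    """Pre-activation residual block: (GroupNorm -> Swish -> conv) x 2 + skip.

    Convolutions are depthwise-separable by default; a 1x1x1 projection is
    added on the identity path only when input and output channels differ.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        norm_groups: int = 8,
        use_separable: bool = True,
    ):
        def make_conv(cin: int, cout: int):
            if use_separable:
                return SeparableConv3d(cin, cout, 3, rng, padding=1)
            return Conv3d(cin, cout, 3, rng, padding=1)

        self.norm1 = GroupNorm(min(norm_groups, in_channels), in_channels)
        self.conv1 = make_conv(in_channels, out_channels)
        self.norm2 = GroupNorm(min(norm_groups, out_channels), out_channels)
        self.conv2 = make_conv(out_channels, out_channels)
        self.proj = Conv3d(in_channels, out_channels, 1, rng) if in_channels != out_channels else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).swish())
        h = self.conv2(self.norm2(h).swish())
        skip = self.proj(x) if self.proj is not None else x
        return h + skip
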