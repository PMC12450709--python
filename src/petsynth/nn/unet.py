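"""Lightweight residual 3-D U-Net for MRI -> PET modality conversion.

Architecture: an initial 3x3x3 projection convolution, four resolution levels
of pre-activation residual blocks with depthwise-separable convolutions and
group normalization, strided-convolution downsampling between levels,
self-attention at the deepest encoder level, a bottleneck of
residual -> attention -> residual, a mirrored decoder with skip concatenation
and transposed-convolution upsampling (attention again at the deepest decoder
level), and a final GroupNorm -> Swish -> conv -> Sigmoid head constraining
the output to [0, 1]. Swish activations throughout.

Channel width is constant (32) by default; per-level multipliers expose a
multiplicative schedule. The default configuration stays under one million
trainable parameters.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ..volumes import Modality, Volume
from .autodiff import Tensor, concat, no_grad
from .layers import Conv3d, ConvTranspose3d, GroupNorm, Module, ResidualBlock, SelfAttention3d

__all__ = ["ModelConfig", "UNet3D", "build_model", "count_parameters", "predict",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Network specification.

    ``attention_levels`` are encoder/decoder level indices (0-based; the
    deepest level is ``n_levels - 1``) that receive a self-attention block, in
    addition to the bottleneck attention which is always present.
    """

    in_channels: int = 1
    out_channels: int = 1
    base_channels: int = 32
    n_levels: int = 4
    residual_blocks_per_level: int = 2
    channel_multipliers: tuple[int, ...] = ()
    use_separable: bool = True
    norm_groups: int = 8
    attention_levels: tuple[int, ...] = ()
    attention_heads: int = 1
    head_kernel: int = 3  # final reconstruction convolution kernel size
    input_shape: tuple[int, int, int] = (96, 96, 96)

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        mult = self.channel_multipliers or tuple([1] * self.n_levels)
        if len(mult) != self.n_levels or any(m < 1 for m in mult):
            raise ValueError("channel_multipliers must be n_levels positive integers")
        object.__setattr__(self, "channel_multipliers", tuple(int(m) for m in mult))
        attn = self.attention_levels or (self.n_levels - 1,)
        if any(a < 0 or a >= self.n_levels for a in attn):
            raise ValueError("attention_levels out of range")
        object.__setattr__(self, "attention_levels", tuple(sorted(set(int(a) for a in attn))))
        if self.base_channels % self.norm_groups:
            raise ValueError("base_channels must be divisible by norm_groups")
        shape = tuple(int(s) for s in self.input_shape)
        div = 2 ** (self.n_levels - 1)
        if any(s % div for s in shape):
            raise ValueError(
                f"input_shape {shape} must be divisible by 2^(n_levels-1) = {div}"
            )
        object.__setattr__(self, "input_shape", shape)

    @property
    def level_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * m for m in self.channel_multipliers)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(s: str) -> "ModelConfig":
        d = json.loads(s)
        for key in ("channel_multipliers", "attention_levels", "input_shape"):
            d[key] = tuple(d[key])
        return ModelConfig(**d)


class UNet3D(Module):
    """Instantiated network; see the module docstring for the layer stack."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        cfg = config
        chans = cfg.level_channels
        ng = cfg.norm_groups

        self.proj = Conv3d(cfg.in_channels, chans[0], 3, rng, padding=1)

        # encoder: per level, residual blocks (+ attention at flagged levels),
        # then a strided-conv downsample except after the deepest level
        self.enc_blocks: list[list[Module]] = []
        self.enc_attn: list[Optional[SelfAttention3d]] = []
        self.downs: list[Conv3d] = []
        cur = chans[0]
        for level in range(cfg.n_levels):
            out_ch = chans[level]
            blocks = []
            for bi in range(cfg.residual_blocks_per_level):
                blocks.append(
                    ResidualBlock(cur if bi == 0 else out_ch, out_ch, rng, ng, cfg.use_separable)
                )
            self.enc_blocks.append(blocks)
            self.enc_attn.append(
                SelfAttention3d(out_ch, rng, cfg.attention_heads)
                if level in cfg.attention_levels
                else None
            )
            cur = out_ch
            if level < cfg.n_levels - 1:
                self.downs.append(Conv3d(cur, chans[level + 1], 3, rng, stride=2, padding=1))
                cur = chans[level + 1]

        # bottleneck: residual -> attention -> residual
        self.mid_block1 = ResidualBlock(cur, cur, rng, ng, cfg.use_separable)
        self.mid_attn = SelfAttention3d(cur, rng, cfg.attention_heads)
        self.mid_block2 = ResidualBlock(cur, cur, rng, ng, cfg.use_separable)

        # decoder: mirrored levels from deep to shallow; each consumes the
        # concatenated skip from its encoder level, with transposed-conv
        # upsampling between levels
        self.dec_blocks: list[list[Module]] = []
        self.dec_attn: list[Optional[SelfAttention3d]] = []
        self.ups: list[ConvTranspose3d] = []
        for level in reversed(range(cfg.n_levels)):
            out_ch = chans[level]
            blocks = []
            for bi in range(cfg.residual_blocks_per_level):
                in_ch = (cur + out_ch) if bi == 0 else out_ch  # skip concat on first block
                blocks.append(ResidualBlock(in_ch, out_ch, rng, ng, cfg.use_separable))
            self.dec_blocks.append(blocks)
            self.dec_attn.append(
                SelfAttention3d(out_ch, rng, cfg.attention_heads)
                if level in cfg.attention_levels
                else None
            )
            cur = out_ch
            if level > 0:
                self.ups.append(ConvTranspose3d(cur, chans[level - 1], 4, rng, stride=2, padding=1))
                cur = chans[level - 1]

        self.out_norm = GroupNorm(ng, cur)
        # near-zero head: the network starts from an almost flat 0.5 output
        # and learns deviations, which stabilizes the first optimization steps
        # while keeping the fresh model input-sensitive
        self.out_conv = Conv3d(
            cur, cfg.out_channels, cfg.head_kernel, rng, padding=cfg.head_kernel // 2
        )
        self.out_conv.weight.data *= 1e-3 / float(np.std(self.out_conv.weight.data) + 1e-12)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.shape[2:] != cfg.input_shape:
            raise ValueError(f"expected spatial shape {cfg.input_shape}, got {x.shape[2:]}")
        h = self.proj(x)
        skips: list[Tensor] = []
        for level in range(cfg.n_levels):
            for block in self.enc_blocks[level]:
                h = block(h)
            if self.enc_attn[level] is not None:
                h = self.enc_attn[level](h)
            skips.append(h)
            if level < cfg.n_levels - 1:
                h = self.downs[level](h)

        h = self.mid_block2(self.mid_attn(self.mid_block1(h)))

        for di, level in enumerate(reversed(range(cfg.n_levels))):
            h = concat([h, skips[level]], axis=1)
            for block in self.dec_blocks[di]:
                h = block(h)
            if self.dec_attn[di] is not None:
                h = self.dec_attn[di](h)
            if level > 0:
                h = self.ups[di](h)

        h = self.out_conv(self.out_norm(h).swish())
        return h.sigmoid()


def build_model(config: ModelConfig, seed: int = 0) -> UNet3D:
    """Construct the network with seeded, reproducible initialization."""
    return UNet3D(config, seed)


def count_parameters(model: Module) -> int:
    """Total number of trainable parameter entries."""
    return model.n_parameters()


def predict(model: UNet3D, mri: Volume) -> Volume:
    """One deterministic forward pass: normalized MRI volume -> PET in [0, 1].

    The input must be conformed to the model's configured grid and scaled to
    [0, 1] beforehand.
    """
    if mri.shape != model.config.input_shape:
        raise ValueError(
            f"input shape {mri.shape} does not match model input {model.config.input_shape}; "
            "conform and normalize the volume first"
        )
    with no_grad():
        x = Tensor(mri.data[None, None].astype(np.float32))
        y = model(x)
    return Volume(y.data[0, 0], mri.voxel_size_mm, Modality.PET)


def save_checkpoint(model: UNet3D, path: str | Path) -> Path:
    """Serialize parameter arrays plus the embedded config JSON and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {name: p.data for name, p in model.named_parameters()}
    meta = json.dumps(
        {"version": CHECKPOINT_VERSION, "config": json.loads(model.config.to_json()), "seed": model.seed}
    )
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> UNet3D:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        config = ModelConfig.from_json(json.dumps(meta["config"]))
        model = UNet3D(config, seed=meta["seed"])
        params = dict(model.named_parameters())
        for name, p in params.items():
            p.data = npz[name].astype(np.float32)
    return model
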