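"""Build the 3-D U-Net and inspect its parameter budget and forward contract.

Prints the image-projection layer's parameter count (a fixed consequence of
the 1 -> 32 channel 3x3x3 design: 1*32*27 + 32 = 896), the total trainable
parameter count of the full-size configuration, and the saving from
depthwise-separable convolutions.
"""
import dataclasses

import numpy as np

from petsynth import ModelConfig, Volume, build_model, count_parameters, predict

cfg = ModelConfig()  # 96-cube input, 32 channels, 4 levels
model = build_model(cfg, seed=0)
proj = model.proj.weight.data.size + model.proj.bias.data.size
print(f"image projection parameters: {proj}")
print(f"total trainable parameters (default config): {count_parameters(model):,}")

dense = build_model(dataclasses.replace(cfg, use_separable=False), seed=0)
print(f"same architecture with dense convolutions:   {count_parameters(dense):,}")
print("separable convolutions factor each 3x3x3 convolution into a per-channel")
print("spatial filter plus a 1x1x1 channel mixer, cutting the parameter count.")

small = ModelConfig(base_channels=8, n_levels=3, norm_groups=4, input_shape=(32, 32, 32))
m = build_model(small, seed=0)
vol = Volume(np.random.default_rng(0).random((32, 32, 32)), modality="MRI")
out = predict(m, vol)
print(f"\ndesk-scale model: {count_parameters(m):,} parameters; "
      f"forward pass {vol.shape} -> {out.shape}, output range "
      f"[{out.data.min():.3f}, {out.data.max():.3f}] (sigmoid head keeps it in [0, 1])")
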