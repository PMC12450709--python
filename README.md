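# petsynth

Synthesis of TSPO-PET-like standardized-uptake-value (SUV) volumes from
structural T1-weighted MRI, with the full study machinery around the model:
paired-phantom simulation, intensity normalization, binder-genotype
regression, leakage-free subject-level cross-validation, and an evaluation
and statistics battery.

## Who this is for

Neuroimaging researchers who want to prototype and stress-test
cross-modality image synthesis — in particular MRI → PET translation for
neuroinflammation imaging, where the PET tracer binds the 18-kDa
translocator protein (TSPO) — without access to a paired PET/MRI cohort.
Real cohorts of this kind are small, private, and expensive; every stage of
this package is therefore exercised end-to-end on *phantoms*: synthetic
paired volumes in which the molecular image is a known deterministic
function of structural tissue class, a two-level binder-genotype factor
(high-affinity vs mixed-affinity binders, HAB/MAB), subject-specific focal
high-uptake blobs, and voxel noise. Because the ground truth is known, the
training loop and every metric can be verified against closed forms and
brute-force oracles.

## The model

A lightweight residual 3-D U-Net maps a normalized T1 volume to a PET SUV
map in [0, 1]:

- initial 3×3×3 projection convolution (1 → 32 channels; 896 parameters),
- four resolution levels of pre-activation residual blocks built from
  depthwise-separable convolutions with group normalization and Swish
  activations, strided-convolution downsampling between levels,
- self-attention at the deepest encoder/decoder level and a bottleneck of
  residual → attention → residual,
- mirrored decoder with skip concatenation and transposed-convolution
  upsampling,
- final GroupNorm → Swish → convolution → **sigmoid**, constraining the
  output to [0, 1].

Training minimizes the hybrid loss

    L = α · BCE(y, ŷ) + (1 − α) · MSE(y, ŷ),        α = 0.5

with Adam, where BCE treats the target SUV as a soft label. Cross-validation
is subject-level and stratified by diagnostic group: all repeated sessions
of one subject share a fold, so no subject ever straddles the train/test
boundary.

Evaluation: masked MSE against raw and 4 mm-FWHM-smoothed targets,
normalized difference NormDiff = (recon − true)/(recon + true) ∈ [−1, 1],
percentage difference, contrast-to-noise ratio
CNR = (mean ROI₁ − mean ROI₂)/SD(ROI₁ ∪ ROI₂) summarized as the median over
1,000 random 4×4×3-voxel ROI pairs, region-wise means over an integer-label
atlas, Pearson correlation, Bland–Altman limits of agreement (±1.96 SD),
median-split Mann–Whitney U tests (exact by enumeration at small n), Tukey
outlier fences, and a matched-vs-mismatched subject-specificity analysis.

The network and its training loop run on a small numpy reverse-mode autodiff
core (`petsynth.nn.autodiff`) with hand-derived 3-D convolution primitives —
the whole package needs only numpy/scipy/pandas/nibabel (+ typer for the
CLI).

## Worked example

`examples/03_build_and_inspect_model.py` builds the full-size network and
prints:

```
image projection parameters: 896
total trainable parameters (default config): 383,073
same architecture with dense convolutions:   1,412,193
```

The projection count is a fixed consequence of the design (1·32·27 weights +
32 biases = 896). Replacing depthwise-separable convolutions with dense ones
nearly quadruples the parameter budget — the separable factorization is what
keeps the model lightweight.

`examples/04_train_and_evaluate_fold.py` runs one cross-validation fold at
desk scale (20 subjects / 39 scans, 32³ grid, reduced model, a few minutes
on one CPU) and prints the masked test MSE of the trained model next to the MSE
of the best constant predictor; a ratio well below 1 shows the network
actually reads the MRI. The other examples cover cohort simulation,
preprocessing + fold construction, and the agreement statistics.

There is also a thin CLI over the same pipeline:

```bash
petsynth all --out run0 --seed 1        # simulate → preprocess → train → predict → evaluate
petsynth evaluate --out run0            # re-run a single stage
```

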