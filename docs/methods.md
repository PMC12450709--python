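# Methods

## Problem setting

The package addresses cross-modality synthesis of molecular brain images
from structural ones: given a T1-weighted MRI volume, predict the
corresponding PET standardized-uptake-value (SUV) map for a
neuroinflammation tracer that binds the 18-kDa translocator protein (TSPO).
Both volumes are assumed already coregistered, skull-stripped and conformed
to a common cubic grid — acquisition, reconstruction and spatial
normalization are upstream of this package. All stages operate on a
`PairedScan` (MRI, PET, brain mask, optional integer-label atlas, plus
subject/session/diagnostic-group/genotype metadata) and a `Cohort` of such
scans with subject-level identity.

## The network

`petsynth.nn.unet.UNet3D` is a residual encoder–decoder ("U-Net") for
volumes whose side is divisible by 2^(levels−1) (default 96³, four levels):

- **Image projection**: dense 3×3×3 convolution, 1 → `base_channels` (32).
  With bias this is 1·32·27 + 32 = 896 parameters, a fixed consequence of
  the design used as a worked example in the tests.
- **Encoder**: per level, `residual_blocks_per_level` (2) pre-activation
  residual blocks (GroupNorm → Swish → conv, twice, identity skip with a
  1×1×1 projection only when channel counts change). Convolutions are
  depthwise-separable by default (per-channel 3×3×3 depthwise followed by a
  1×1×1 pointwise channel mixer); a dense mode exists for comparison.
  Downsampling between levels is a stride-2 3×3×3 convolution.
- **Attention**: multi-head self-attention over the flattened voxel grid
  (scaled dot-product, residual add) at the deepest level of both encoder
  and decoder, and in the bottleneck (residual → attention → residual).
- **Decoder**: mirrors the encoder; each level first concatenates the
  encoder skip of the same resolution, then applies its residual blocks;
  upsampling is a stride-2 4×4×4 transposed convolution (the even kernel
  avoids checkerboard misalignment).
- **Head**: GroupNorm → Swish → 3×3×3 convolution to one channel → sigmoid,
  so outputs live in [0, 1] like the min–max-normalized SUV targets.

Channel width is constant across levels by default (`channel_multipliers`
all 1); a multiplicative schedule is available through the config. Group
normalization uses 8 groups by default; attention defaults to a single head
with head dimension equal to the channel count. The default full-size
configuration has 383,073 trainable parameters (logged at build; the
package treats "lightweight" as a hard < 1,000,000 contract). The head
convolution is rescaled at initialization to a weight SD of 1e-3, so a fresh
network outputs ≈ 0.5 everywhere and learns deviations from a flat field;
this materially stabilizes the first optimization steps of the sigmoid+BCE
head while keeping the fresh model input-sensitive. The head kernel size is
configurable (`head_kernel`, default 3): a 1×1×1 head turns the final stage
into a pure channel mixer, which sharpens voxel-scale structure — on
phantoms whose tissue shells are only one or two voxels wide this halves the
held-out reconstruction error, so the desk-scale configuration uses it.

The network, its backward pass and Adam run on `petsynth.nn.autodiff`, a
small reverse-mode automatic-differentiation core over float32 numpy
arrays. The two convolution primitives (grouped/strided convolution,
transposed convolution) iterate over kernel offsets and perform one
channel-mixing contraction per offset on strided views, keeping peak memory
at the scale of the activations; their gradients are hand-derived and
verified against numerical directional derivatives in the test suite.

## Loss and training

The training objective is the hybrid loss L = α·BCE + (1−α)·MSE with
α = 0.5, both terms voxel-mean-reduced; BCE treats the target as a soft
label and clamps predictions to [1e-7, 1 − 1e-7]. Optimization is Adam.
The library default learning rate is 1e-3 with batch size 2 and 50 epochs;
the *pipeline's* desk-scale defaults (32³ grid, reduced model, small phantom
cohorts, 20 epochs) are a base rate of 5e-3, batch size 1, and a cosine
decay of the learning rate to 5% of base over the run. These were chosen
because, in the few-hundred-step regime of a desk-scale run, batch-1 updates
double the number of optimizer steps per epoch and the decay removes the
late-phase oscillation a constant rate shows; both are exposed in the config
and the schedule can be switched back to constant. Gradients are clipped to
a global norm of 1 by default (disable with ``grad_clip_norm=None``), which
tames occasional loss spikes in the batch-1 regime.

Short desk-scale runs are init-sensitive: different seeds can land in
basins of visibly different sharpness. ``train_model`` therefore supports
seeded random restarts (``n_restarts``; the pipeline default is 2), keeping
the restart with the lowest mean training loss over its final epoch — a
selection that uses only training data, never the held-out fold. The
full-size 50-epoch regime is far less init-sensitive and a single run is
the library default.

Within a cross-validation round the validation set (used only for the loss
curve) is a seeded 10% of training *subjects*. `train_model` refuses to run
if any subject appears on both sides — the same subject-level integrity that
`make_folds` enforces: subjects are shuffled by seed, grouped by diagnostic
group, ordered by descending scan count, and dealt greedily to the currently
smallest fold, so folds are stratified by group, balanced in scan count, and
never split a subject's repeated sessions.

## Preprocessing

- MRI: robust scaling to [0, 1] using the 1st/99th percentiles of
  within-mask intensities (linear-interpolation percentile convention),
  then clipping. Constant inputs yield zeros plus a warning.
- PET: per-scan min–max scaling of within-mask intensities to [0, 1];
  out-of-mask voxels are set to 0.
- Genotype: TSPO binder status (HAB reference = 0, MAB = 1) modulates
  tracer uptake; a voxel-wise ordinary-least-squares regression of PET on
  the binary indicator is fitted **on training-fold scans only** and its
  coefficient map subtracted for MAB scans everywhere, keeping the
  HAB-referenced intercept. The default order is genotype adjustment on raw
  SUV before min–max scaling; the reverse order is configurable. Voxel-wise
  regression (rather than a regional summary) and within-mask min/max are
  package choices where the upstream convention is ambiguous; both are
  flagged in the config.
- Smoothing: separable Gaussian at 4 mm FWHM (σ = FWHM / (2√(2 ln 2)) ≈
  1.699 mm), per-axis σ in voxels from the voxel size, nearest-neighbour
  boundary, kernel truncated at 4σ. Used to produce the smoothed comparison
  target, not applied to training inputs.

Grid conformance (`conform`) center-crops/zero-pads to the target shape by
default — lossless for the retained field of view and idempotent — with an
optional trilinear resampling mode.

## The phantom generator

`petsynth.phantom` emulates the structure of a simultaneous PET/MRI cohort
so that the full pipeline is testable without data:

- an ellipsoidal brain mask (semi-axes 0.45/0.40/0.35 of the grid) split
  into `n_regions` equal-volume concentric shells (radial edges at
  (i/n)^(1/3); a seeded Voronoi mode is the alternative geometry);
- MRI = per-region class mean (defaults 1100/850/600/350, a T1-like
  contrast ordering) × a smooth multiplicative bias field (low-resolution
  Gaussian noise upsampled, ±10%) + i.i.d. Gaussian noise (SD 25, ≈ 3% of
  the tissue contrast range);
- PET = per-region uptake (defaults 0.4/1.0/0.7/1.4) × genotype factor
  (0.7 for MAB — mixed-affinity binders carry proportionally less signal)
  + subject-specific focal Gaussian blobs (3 blobs, amplitude 0.8,
  σ = 2.5 voxels) + i.i.d. Gaussian noise (SD 0.05), clipped at 0;
- blob centres are a *subject-level* property re-used across a subject's
  sessions, so repeated scans of one subject are more alike than scans of
  different subjects — this gives the subject-specificity analysis a true
  signal;
- all randomness flows from one integer seed through stable hashes of
  (subject, session), so cohorts are bitwise reproducible regardless of
  generation order.

What the phantom does **not** emulate: anatomy, PET physics (scatter,
attenuation, partial volume), scanner- or site-level variation, and any
genuine biological coupling between structure and inflammation beyond the
shared tissue-class geometry. Passing tests therefore demonstrate that the
machinery is correct and that the network can recover a learnable
cross-modal mapping under noise — not that the approach works on real
cohorts.

## Evaluation and statistics

- `mse`, `normdiff` ((r−t)/(r+t), bounded in [−1,1]; denominators < 1e-8
  excluded from summaries and zeroed in maps), `percent_diff`
  (100·(r−t)/t, t < 1e-8 excluded) — all mask-restricted.
- `cnr` reads "SD(ROI1 + ROI2)" as the population SD of the concatenated
  voxel sets (the voxelwise-sum reading and sample SD are config switches).
  The global estimate is the median CNR over `n_samples` (1,000) random
  4×4×3 ROI pairs; each ROI must have ≥ 80% of its voxels in-mask and the
  two ROIs of a pair must not overlap. ROI coordinates are a deterministic
  function of (mask, seed) and are re-used across the true/reconstructed
  pair of a scan, making the comparison paired.
- `bland_altman` returns the mean difference and mean ± 1.96·sample-SD.
- `pearson` is the product-moment correlation with the two-sided t-based
  p-value (n−2 degrees of freedom).
- `median_split` assigns ties to the Low group. `mann_whitney_u` uses
  midranks; p is exact by dynamic-programming enumeration of the null U
  distribution when the combined sample is ≤ 12 with no ties, otherwise a
  normal approximation with tie and continuity corrections.
- `remove_outliers` drops values outside Tukey fences (1.5×IQR,
  linear-interpolation quartiles); fewer than 4 values pass through
  unchanged.
- No multiple-testing correction is applied by default (region-wise raw
  p-values); Benjamini–Hochberg adjustment is available behind a flag.
- `subject_specificity` compares each reconstruction against its own scan's
  true PET and against one representative scan per other subject (the
  subject's first scan in cohort order, grids conformed, masks
  intersected), and tests matched vs mismatched MSE with a one-sided
  Mann–Whitney.

## Problem sizes

Desk-scale studies — the pipeline defaults, the examples, the acceptance
script — use a 32³ grid, a reduced model (8 base channels, 3 levels, one
residual block per level, per-channel normalization, a 1×1×1 head; the
phantom's cross-modal mapping is nearly voxelwise, so a shallow, sharp
network trains best per CPU-second), cohorts of ~20 subjects / ~39 scans
with the repeat-scan pattern 1/2/3 sessions cycling over subjects, and 20
training epochs. These
sizes keep a full simulate→train→evaluate round in minutes on one CPU while
preserving every structural property of the full-size setting (96³, 32
channels, 4 levels, 50 epochs), which the same code runs by passing the
default `ModelConfig`.

## Known limitations

- The numpy training loop is single-threaded and memory-bound; full-size
  96³ training is out of desk-scale reach (a single 96³ forward pass of the
  full-width model takes on the order of a minute).
- The genotype regression assumes a purely additive, voxel-independent
  genotype effect; interactions with diagnostic group are not modelled.
- Attention cost grows quadratically with voxel count at the level where it
  is applied; it is restricted to the deepest levels for that reason.
- Phantom realism limits are listed above; in particular min–max SUV
  scaling makes the target scale depend on each scan's extreme values, so a
  fraction of the reconstruction error on phantoms reflects per-scan scale
  jitter from blob overlap rather than mapping error.
- The "smoothed target has lower MSE" pattern holds only when the
  reconstruction is at least as smooth as the comparison kernel. The
  desk-scale phantom's tissue shells are thinner than a 4 mm FWHM kernel, so
  a *crisp* trained reconstruction can show the reverse ordering there — the
  property is exercised with an explicitly smooth predictor, and the
  pipeline reports both MSEs rather than asserting an ordering.
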