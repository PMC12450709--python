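"""Normalize a cohort and build leakage-free cross-validation folds.

Shows the preprocessing chain (robust MRI scaling, genotype regression,
per-scan PET min-max scaling) and a subject-level stratified 5-fold split in
which repeated sessions of one subject never straddle folds.
"""
from collections import Counter

from petsynth import PhantomSpec, PreprocessConfig, generate_cohort, make_folds, preprocess_cohort

spec = PhantomSpec(shape=(32, 32, 32), seed=3)
cohort = generate_cohort(
    10, [1, 2, 3, 1, 2, 3, 1, 2, 3, 1],
    {"HC": 0.3, "KOA": 0.4, "CLB": 0.3}, {"HAB": 0.6, "MAB": 0.4}, spec,
)

folds = make_folds(cohort, k=5, seed=0)
print("fold sizes (test scans):", [len(f) for f in folds.test_keys])
for fold, keys in enumerate(folds.test_keys):
    subs = sorted({sid for sid, _ in keys})
    print(f"  fold {fold}: subjects {subs}")
print("every subject appears in exactly one fold; repeated sessions travel together.")

processed, adjustment = preprocess_cohort(
    cohort, PreprocessConfig(), training_keys=folds.train_keys[0]
)
print("\nafter preprocessing (fitted on fold-0 training scans only):")
scan = processed.scans[0]
print(f"  MRI range  [{scan.mri.data.min():.2f}, {scan.mri.data.max():.2f}]  (robust-scaled)")
print(f"  PET range  [{scan.pet.data.min():.2f}, {scan.pet.data.max():.2f}]  (min-max SUV)")
coef = adjustment.per_voxel_genotype_coefficient
print(f"  genotype coefficient: mean {coef.mean():.4f} over the grid -- the "
      "within-mask magnitude reflects the simulated binding difference that was regressed out")
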