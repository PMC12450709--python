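"""Intensity normalization and adjustment chain for paired MRI/PET scans.

The chain mirrors standard simultaneous PET/MRI practice on already-conformed
volumes: structural images are mapped to [0, 1] by robust scaling (1st/99th
percentile), molecular SUV maps by per-scan min-max scaling within the brain
mask, binder-genotype effects on tracer uptake are regressed out voxel-wise
on the training subset only (no leakage into test folds), and Gaussian
smoothing at a given FWHM provides the smoothed comparison target.
"""
from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import Cohort, Genotype, Modality, PairedScan, Volume

__all__ = [
    "PreprocessWarning",
    "SmoothingSpec",
    "PreprocessConfig",
    "GenotypeAdjustment",
    "fwhm_to_sigma",
    "robust_scale_mri",
    "minmax_scale_pet",
    "fit_genotype_adjustment",
    "apply_genotype_adjustment",
    "gaussian_smooth",
    "preprocess_scan",
    "preprocess_cohort",
]

# FWHM = 2 * sqrt(2 * ln 2) * sigma
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class PreprocessWarning(UserWarning):
    """Raised (as a warning) on degenerate inputs, e.g. constant volumes."""


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum (mm)."""
    return float(fwhm_mm) / _FWHM_FACTOR


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing kernel: FWHM in mm, truncation in sigmas."""

    fwhm_mm: float = 4.0
    truncation_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0 or self.truncation_sigmas <= 0:
            raise ValueError("fwhm_mm and truncation_sigmas must be positive")

    @property
    def sigma_mm(self) -> float:
        return fwhm_to_sigma(self.fwhm_mm)


@dataclass(frozen=True)
class PreprocessConfig:
    """Resolved preprocessing options (JSON-serializable)."""

    fwhm_mm: float = 4.0
    truncation_sigmas: float = 4.0
    percentiles: tuple[float, float] = (1.0, 99.0)
    genotype_adjustment: bool = True
    # "adjust_then_scale": genotype regression on raw SUV, then min-max;
    # "scale_then_adjust": the reverse order.
    order: str = "adjust_then_scale"

    def __post_init__(self) -> None:
        if self.order not in ("adjust_then_scale", "scale_then_adjust"):
            raise ValueError(f"unknown preprocessing order {self.order!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(s: str) -> "PreprocessConfig":
        d = json.loads(s)
        d["percentiles"] = tuple(d["percentiles"])
        return PreprocessConfig(**d)

    @property
    def smoothing(self) -> SmoothingSpec:
        return SmoothingSpec(self.fwhm_mm, self.truncation_sigmas)


def _mask_values(volume: Volume, mask: Optional[Volume]) -> np.ndarray:
    if mask is None:
        return volume.data.ravel()
    return volume.data[mask.data.astype(bool)]


def robust_scale_mri(
    volume: Volume,
    mask: Optional[Volume] = None,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> Volume:
    """Robustly scale a structural volume to [0, 1].

    v' = clip((v - p_lo) / (p_hi - p_lo), 0, 1) with percentiles computed over
    within-mask voxels (whole volume if no mask), using linear interpolation
    between order statistics. A constant input yields all zeros plus a
    :class:`PreprocessWarning`.
    """
    vals = _mask_values(volume, mask)
    p_lo, p_hi = np.percentile(vals, percentiles)
    if p_hi == p_lo:
        warnings.warn("constant volume in robust_scale_mri; output all zeros", PreprocessWarning)
        return volume.with_data(np.zeros_like(volume.data, dtype=np.float32))
    scaled = np.clip((volume.data - p_lo) / (p_hi - p_lo), 0.0, 1.0).astype(np.float32)
    if mask is not None:
        scaled = scaled * mask.data.astype(np.float32)
    return volume.with_data(scaled)


def minmax_scale_pet(volume: Volume, mask: Optional[Volume] = None) -> Volume:
    """Min-max scale a PET SUV volume to [0, 1] over within-mask voxels.

    Out-of-mask voxels are set to 0. A constant input yields all zeros plus a
    :class:`PreprocessWarning`.
    """
    vals = _mask_values(volume, mask)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        warnings.warn("constant volume in minmax_scale_pet; output all zeros", PreprocessWarning)
        return volume.with_data(np.zeros_like(volume.data, dtype=np.float32))
    scaled = ((volume.data - lo) / (hi - lo)).astype(np.float32)
    scaled = np.clip(scaled, 0.0, 1.0)
    if mask is not None:
        scaled = scaled * mask.data.astype(np.float32)
    return volume.with_data(scaled)


@dataclass(frozen=True)
class GenotypeAdjustment:
    """Voxel-wise OLS fit of PET intensity on the binary genotype indicator.

    Encoding: HAB -> 0 (reference), MAB -> 1. The adjusted PET keeps the
    HAB-referenced intercept: adjusted = raw - coefficient * indicator.
    """

    per_voxel_intercept: np.ndarray
    per_voxel_genotype_coefficient: np.ndarray

    REFERENCE_ENCODING = {Genotype.HAB: 0.0, Genotype.MAB: 1.0}

    def __post_init__(self) -> None:
        if self.per_voxel_intercept.shape != self.per_voxel_genotype_coefficient.shape:
            raise ValueError("intercept and coefficient grids must share shape")


def _genotype_indicator(scan: PairedScan) -> float:
    return GenotypeAdjustment.REFERENCE_ENCODING[scan.genotype]


def fit_genotype_adjustment(cohort: Cohort | Sequence[PairedScan]) -> GenotypeAdjustment:
    """Fit the voxel-wise genotype regression on a (training) set of scans.

    Per voxel, ordinary least squares of PET value on the binary genotype
    indicator: coefficient = cov(g, y) / var(g), intercept = mean(y) -
    coefficient * mean(g). Requires both genotypes in the subset.
    """
    scans = list(cohort)
    if not scans:
        raise ValueError("empty training subset")
    g = np.array([_genotype_indicator(s) for s in scans], dtype=np.float64)
    if len(np.unique(g)) < 2:
        raise ValueError(
            "genotype coefficient unidentifiable: training subset contains a single genotype"
        )
    shape = scans[0].pet.shape
    for s in scans:
        if s.pet.shape != shape:
            raise ValueError("scans in genotype fit must share grid shape")
    y = np.stack([s.pet.data.astype(np.float64) for s in scans], axis=0)
    gc = g - g.mean()
    denom = float((gc**2).sum())
    coef = np.tensordot(gc, y, axes=(0, 0)) / denom
    ybar = y.mean(axis=0)
    intercept = ybar - coef * g.mean()
    return GenotypeAdjustment(
        per_voxel_intercept=intercept.astype(np.float32),
        per_voxel_genotype_coefficient=coef.astype(np.float32),
    )


def apply_genotype_adjustment(scan: PairedScan, adj: GenotypeAdjustment) -> PairedScan:
    """Remove the fitted genotype effect from one scan's PET volume."""
    if adj.per_voxel_genotype_coefficient.shape != scan.pet.shape:
        raise ValueError(
            f"adjustment grid {adj.per_voxel_genotype_coefficient.shape} does not match "
            f"scan grid {scan.pet.shape}"
        )
    indicator = _genotype_indicator(scan)
    adjusted = scan.pet.data - adj.per_voxel_genotype_coefficient * np.float32(indicator)
    return replace(scan, pet=scan.pet.with_data(adjusted.astype(np.float32)))


def gaussian_smooth(volume: Volume, spec: SmoothingSpec = SmoothingSpec()) -> Volume:
    """Separable Gaussian smoothing at the requested FWHM.

    Per-axis sigma in voxels is sigma_mm / voxel_size_mm[axis]; boundary mode
    is nearest-neighbour replication and the kernel is truncated at
    ``truncation_sigmas``.
    """
    sigma_vox = [spec.sigma_mm / v for v in volume.voxel_size_mm]
    smoothed = gaussian_filter(
        volume.data.astype(np.float32),
        sigma=sigma_vox,
        mode="nearest",
        truncate=spec.truncation_sigmas,
    )
    return volume.with_data(smoothed)


def preprocess_scan(
    scan: PairedScan,
    config: PreprocessConfig = PreprocessConfig(),
    adjustment: Optional[GenotypeAdjustment] = None,
) -> PairedScan:
    """Apply the full normalization chain to one scan.

    MRI: robust [0,1] scaling. PET: genotype adjustment (if enabled and an
    adjustment is provided) then per-scan min-max scaling -- or the reverse
    order if configured. The genotype adjustment must have been fitted on
    training scans only.
    """
    mri = robust_scale_mri(scan.mri, scan.mask, config.percentiles)
    out = replace(scan, mri=mri)
    do_adjust = config.genotype_adjustment and adjustment is not None
    if config.order == "adjust_then_scale":
        if do_adjust:
            out = apply_genotype_adjustment(out, adjustment)
        out = replace(out, pet=minmax_scale_pet(out.pet, out.mask))
    else:
        out = replace(out, pet=minmax_scale_pet(out.pet, out.mask))
        if do_adjust:
            out = apply_genotype_adjustment(out, adjustment)
    return out


def preprocess_cohort(
    cohort: Cohort,
    config: PreprocessConfig = PreprocessConfig(),
    training_keys: Optional[Iterable[tuple[str, int]]] = None,
) -> tuple[Cohort, Optional[GenotypeAdjustment]]:
    """Preprocess every scan of a cohort.

    If genotype adjustment is enabled, the voxel-wise regression is fitted on
    the scans named by ``training_keys`` (all scans if None -- only valid
    outside a cross-validation context) and applied to every scan.
    """
    adj = None
    if config.genotype_adjustment:
        if training_keys is None:
            fit_scans = list(cohort)
        else:
            wanted = set(training_keys)
            fit_scans = [s for s in cohort if s.key in wanted]
        genos = {s.genotype for s in fit_scans}
        if len(genos) < 2:
            warnings.warn(
                "single-genotype training subset; skipping genotype adjustment",
                PreprocessWarning,
            )
        else:
            adj = fit_genotype_adjustment(fit_scans)
    out = [preprocess_scan(s, config, adj) for s in cohort]
    return Cohort(out, cohort.manifest_path), adj
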