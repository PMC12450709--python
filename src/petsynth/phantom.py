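"""Seeded paired MRI/PET brain phantoms with a known cross-modal mapping.

The generator emulates the structure of a simultaneous PET/MRI study cohort:
an ellipsoidal "brain" partitioned into tissue regions, a structural volume
whose intensity is a per-region class mean under a smooth multiplicative bias
field, and a molecular (PET-like) volume whose uptake is a deterministic
function of tissue class, scaled by a two-level binder-genotype factor, plus
subject-specific focal high-uptake blobs and voxel noise. Because the
molecular image is a known function of the structural tissue classes, every
downstream stage (training, evaluation, statistics) can be tested against
ground truth without any real data.

Randomness is fully reproducible: one integer seed plus a stable hash of
(subject_id, session) drives each scan's noise stream, and blob layout is a
subject-level property so repeated sessions of one subject share focal
anatomy (scans of one subject are more alike than scans of two subjects).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import zoom

from .volumes import Cohort, Genotype, Group, Modality, PairedScan, Volume, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "noiseless_spec", "blob_centers"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the paired-phantom generator.

    Defaults give a 96-cube grid at 1 mm isotropic with four concentric tissue
    shells; tests typically shrink ``shape`` to 32-cubes. ``genotype_factor``
    multiplies molecular uptake for mixed-affinity binders (MAB), emulating
    reduced tracer binding relative to high-affinity binders (HAB).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_regions: int = 4
    mri_class_means: tuple[float, ...] = (1100.0, 850.0, 600.0, 350.0)
    pet_class_uptake: tuple[float, ...] = (0.4, 1.0, 0.7, 1.4)
    genotype_factor: float = 0.7
    n_blobs: int = 3
    blob_amplitude: float = 0.8
    blob_sigma_vox: float = 2.5
    bias_amplitude: float = 0.1
    noise_sd_mri: float = 25.0
    noise_sd_pet: float = 0.05
    label_geometry: str = "shells"  # or "voronoi"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if len(self.mri_class_means) != self.n_regions or len(self.pet_class_uptake) != self.n_regions:
            raise ValueError("class mean/uptake lists must have length n_regions")
        if any(m <= 0 for m in self.mri_class_means):
            raise ValueError("mri_class_means must be positive")
        if any(u < 0 for u in self.pet_class_uptake):
            raise ValueError("pet_class_uptake must be non-negative")
        if self.genotype_factor <= 0:
            raise ValueError("genotype_factor must be positive")
        if self.n_blobs < 0 or self.blob_amplitude <= 0:
            raise ValueError("n_blobs must be >= 0 and blob_amplitude > 0")
        if self.noise_sd_mri < 0 or self.noise_sd_pet < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.label_geometry not in ("shells", "voronoi"):
            raise ValueError("label_geometry must be 'shells' or 'voronoi'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(s: str) -> "PhantomSpec":
        d = json.loads(s)
        for k in ("shape", "voxel_size_mm", "mri_class_means", "pet_class_uptake"):
            d[k] = tuple(d[k])
        return PhantomSpec(**d)


def noiseless_spec(spec: PhantomSpec) -> PhantomSpec:
    """The same phantom with both voxel-noise terms and the bias field off."""
    return dataclasses.replace(spec, noise_sd_mri=0.0, noise_sd_pet=0.0, bias_amplitude=0.0)


def _stable_hash(*parts: object) -> int:
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


def _scan_rng(spec: PhantomSpec, subject_id: str, session: int) -> np.random.Generator:
    return np.random.default_rng(_stable_hash("scan", spec.seed, subject_id, session))


def _subject_rng(spec: PhantomSpec, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(_stable_hash("subject", spec.seed, subject_id))


def _ellipsoid_radius(shape: Sequence[int]) -> np.ndarray:
    """Normalized ellipsoidal radius (0 at centre, 1 on the brain boundary)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return np.sqrt(r2)


def _make_labels(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Brain mask and integer region labels 1..n_regions inside it."""
    r = _ellipsoid_radius(spec.shape)
    mask = (r <= 1.0).astype(np.uint8)
    n = spec.n_regions
    labels = np.zeros(spec.shape, dtype=np.int32)
    if spec.label_geometry == "shells":
        # equal-volume concentric shells: for an ellipsoid, volume ~ r^3
        edges = np.array([(i / n) ** (1.0 / 3.0) for i in range(n + 1)])
        for i in range(n):
            sel = (r > edges[i]) & (r <= edges[i + 1]) & (mask == 1)
            labels[sel] = i + 1
        labels[(r == 0) & (mask == 1)] = 1
    else:  # voronoi
        rng = np.random.default_rng(_stable_hash("voronoi", spec.seed))
        coords = np.argwhere(mask == 1)
        if len(coords) < n:
            raise ValueError("n_regions exceeds mask voxel count")
        seeds = coords[rng.choice(len(coords), size=n, replace=False)]
        d2 = np.stack(
            [((coords - s) ** 2).sum(axis=1) for s in seeds], axis=1
        )
        nearest = d2.argmin(axis=1)
        labels[tuple(coords.T)] = nearest + 1
    if int(mask.sum()) < n:
        raise ValueError("n_regions exceeds mask voxel count")
    return mask, labels


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias in [1 - a, 1 + a]: low-res noise upsampled."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.shape, dtype=np.float32)
    coarse = rng.standard_normal((4, 4, 4))
    factors = [s / 4 for s in spec.shape]
    smooth = zoom(coarse, factors, order=3)
    smooth = smooth[tuple(slice(0, s) for s in spec.shape)]
    span = np.abs(smooth).max()
    if span > 0:
        smooth = smooth / span
    return (1.0 + spec.bias_amplitude * smooth).astype(np.float32)


def blob_centers(spec: PhantomSpec, subject_id: str, mask: np.ndarray) -> np.ndarray:
    """Subject-level focal blob centres (shared across a subject's sessions)."""
    rng = _subject_rng(spec, subject_id)
    coords = np.argwhere(mask == 1)
    if spec.n_blobs == 0:
        return np.empty((0, 3), dtype=np.int64)
    idx = rng.choice(len(coords), size=spec.n_blobs, replace=False)
    return coords[idx]


def _blob_field(spec: PhantomSpec, centers: np.ndarray) -> np.ndarray:
    out = np.zeros(spec.shape, dtype=np.float32)
    if len(centers) == 0:
        return out
    grids = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
    s2 = 2.0 * spec.blob_sigma_vox**2
    for c in centers:
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        out += spec.blob_amplitude * np.exp(-d2 / s2)
    return out


def generate_phantom(
    spec: PhantomSpec,
    subject_id: str,
    session: int,
    group: Group | str,
    genotype: Genotype | str,
) -> PairedScan:
    """Generate one paired phantom scan.

    The molecular (PET) image is ``uptake[label] * genotype_factor(genotype)
    + blob field + noise`` clipped at zero; the structural (MRI) image is
    ``class_mean[label] * bias + noise``. Identical arguments give
    bitwise-identical output.
    """
    genotype = Genotype(genotype)
    group = Group(group)
    mask, labels = _make_labels(spec)
    rng = _scan_rng(spec, subject_id, session)

    mri_map = np.zeros(spec.shape, dtype=np.float32)
    pet_map = np.zeros(spec.shape, dtype=np.float32)
    for i in range(spec.n_regions):
        sel = labels == i + 1
        mri_map[sel] = spec.mri_class_means[i]
        pet_map[sel] = spec.pet_class_uptake[i]

    bias = _bias_field(spec, rng)
    mri = mri_map * bias
    if spec.noise_sd_mri > 0:
        mri = mri + rng.normal(0.0, spec.noise_sd_mri, spec.shape).astype(np.float32)
    mri *= mask

    gfac = spec.genotype_factor if genotype is Genotype.MAB else 1.0
    centers = blob_centers(spec, subject_id, mask)
    pet = pet_map * gfac + _blob_field(spec, centers)
    if spec.noise_sd_pet > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd_pet, spec.shape).astype(np.float32)
    pet = np.clip(pet, 0.0, None) * mask

    vs = spec.voxel_size_mm
    return PairedScan(
        subject_id=subject_id,
        session=session,
        group=group,
        genotype=genotype,
        mri=Volume(mri, vs, Modality.MRI),
        pet=Volume(pet, vs, Modality.PET),
        mask=Volume(mask, vs, Modality.MASK),
        labels=Volume(labels, vs, Modality.LABELS),
    )


def _allocate(n: int, mix: dict, rng: np.random.Generator) -> list:
    """Deterministically allocate n items to categories by proportion."""
    cats = list(mix.keys())
    props = np.array([float(mix[c]) for c in cats])
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {props.sum()}")
    counts = np.floor(props * n).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = props * n - counts
    for i in np.argsort(-frac)[: n - counts.sum()]:
        counts[i] += 1
    out = [c for c, k in zip(cats, counts) for _ in range(int(k))]
    rng.shuffle(out)
    return out


def generate_cohort(
    n_subjects: int,
    sessions_per_subject: Sequence[int],
    group_mix: dict,
    genotype_mix: dict,
    spec: PhantomSpec,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a phantom cohort, optionally writing NIfTI files + manifest.

    ``sessions_per_subject[i]`` gives the number of repeat sessions of
    subject i. Group and genotype are subject-level attributes allocated by
    the given proportions (seeded). With ``out_dir`` set, the exact NIfTI +
    manifest dialect that :func:`petsynth.volumes.load_cohort` consumes is
    written and the cohort's ``manifest_path`` points at it.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if len(sessions_per_subject) != n_subjects:
        raise ValueError("sessions_per_subject must have length n_subjects")
    rng = np.random.default_rng(_stable_hash("cohort", spec.seed))
    groups = _allocate(n_subjects, {Group(g): p for g, p in group_mix.items()}, rng)
    genotypes = _allocate(n_subjects, {Genotype(g): p for g, p in genotype_mix.items()}, rng)

    scans: list[PairedScan] = []
    for i in range(n_subjects):
        sid = f"sub-{i + 1:03d}"
        for sess in range(1, int(sessions_per_subject[i]) + 1):
            scans.append(generate_phantom(spec, sid, sess, groups[i], genotypes[i]))

    manifest_path = ""
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for scan in scans:
            stem = f"{scan.subject_id}_ses-{scan.session}"
            names = {
                "mri": f"{stem}_mri.nii.gz",
                "pet": f"{stem}_pet.nii.gz",
                "mask": f"{stem}_mask.nii.gz",
                "labels": f"{stem}_labels.nii.gz",
            }
            write_volume(scan.mri, out_dir / names["mri"])
            write_volume(scan.pet, out_dir / names["pet"])
            write_volume(scan.mask, out_dir / names["mask"])
            write_volume(scan.labels, out_dir / names["labels"])
            rows.append(
                {
                    "subject_id": scan.subject_id,
                    "session": scan.session,
                    "group": scan.group.value,
                    "genotype": scan.genotype.value,
                    **names,
                }
            )
        manifest_path = str(out_dir / "manifest.tsv")
        pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
        (out_dir / "phantom_spec.json").write_text(spec.to_json())
    return Cohort(scans=scans, manifest_path=manifest_path)
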