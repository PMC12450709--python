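"""Domain containers for 3-D brain volumes and paired MRI/PET cohorts.

All downstream stages (phantom generation, preprocessing, network training,
evaluation) operate on these types. Volumes live on a voxel grid with known
spacing in millimetres; world-space orientation handling is limited to
RAS-canonicalization on read, and grids are assumed voxel-aligned within a
scan (no resampling between a scan's modalities).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Group",
    "Genotype",
    "Volume",
    "PairedScan",
    "Cohort",
    "read_volume",
    "write_volume",
    "conform",
    "load_cohort",
    "MANIFEST_COLUMNS",
]


class Modality(str, enum.Enum):
    MRI = "MRI"
    PET = "PET"
    MASK = "MASK"
    LABELS = "LABELS"


class Group(str, enum.Enum):
    """Diagnostic group: healthy control, knee osteoarthritis, chronic low-back pain."""

    HC = "HC"
    KOA = "KOA"
    CLB = "CLB"


class Genotype(str, enum.Enum):
    """TSPO Ala147Thr binder status: high-affinity or mixed-affinity binder."""

    HAB = "HAB"
    MAB = "MAB"


@dataclass(frozen=True)
class Volume:
    """One 3-D scalar image with grid metadata.

    Parameters
    ----------
    data:
        3-D array. Stored as float32 for MRI/PET, uint8 for masks and
        int32 for label volumes.
    voxel_size_mm:
        Positive voxel edge lengths (dx, dy, dz) in millimetres.
    modality:
        One of MRI, PET, MASK, LABELS.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: Modality = Modality.MRI

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"volume data must be 3-D with all extents >= 1, got shape {data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive reals, got {self.voxel_size_mm}")
        modality = Modality(self.modality)
        if modality is Modality.MASK:
            data = np.asarray(data)
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("MASK volumes may only contain {0, 1}")
            data = data.astype(np.uint8)
        elif modality is Modality.LABELS:
            if not np.issubdtype(np.asarray(data).dtype, np.integer):
                rounded = np.rint(data)
                if not np.allclose(data, rounded):
                    raise ValueError("LABELS volumes must contain integers")
                data = rounded
            if np.any(np.asarray(data) < 0):
                raise ValueError("LABELS volumes must be non-negative")
            data = data.astype(np.int32)
        else:
            data = data.astype(np.float32)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", vs)
        object.__setattr__(self, "modality", modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass(frozen=True)
class PairedScan:
    """One imaging session: structural MRI, PET SUV map, brain mask, optional atlas."""

    subject_id: str
    session: int
    group: Group
    genotype: Genotype
    mri: Volume
    pet: Volume
    mask: Volume
    labels: Optional[Volume] = None

    def __post_init__(self) -> None:
        if int(self.session) < 1:
            raise ValueError("session must be a positive integer")
        object.__setattr__(self, "session", int(self.session))
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        vols = {"mri": self.mri, "pet": self.pet, "mask": self.mask}
        if self.labels is not None:
            vols["labels"] = self.labels
        ref = self.mri
        for name, vol in vols.items():
            if vol.shape != ref.shape:
                raise ValueError(
                    f"scan {self.subject_id}/{self.session}: {name} shape {vol.shape} "
                    f"!= mri shape {ref.shape}"
                )
            if not np.allclose(vol.voxel_size_mm, ref.voxel_size_mm):
                raise ValueError(
                    f"scan {self.subject_id}/{self.session}: {name} voxel size differs from mri"
                )
        if self.mask.data.sum() < 1:
            raise ValueError(f"scan {self.subject_id}/{self.session}: mask covers no voxels")

    @property
    def key(self) -> tuple[str, int]:
        return (self.subject_id, self.session)


@dataclass
class Cohort:
    """Ordered collection of paired scans with subject-level grouping."""

    scans: list[PairedScan]
    manifest_path: str = ""

    def __post_init__(self) -> None:
        keys = [s.key for s in self.scans]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (subject_id, session) pairs in cohort: {dupes}")
        per_subject: dict[str, tuple[Group, Genotype]] = {}
        for s in self.scans:
            prev = per_subject.setdefault(s.subject_id, (s.group, s.genotype))
            if prev != (s.group, s.genotype):
                raise ValueError(
                    f"subject {s.subject_id} has inconsistent group/genotype across sessions"
                )

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.scans:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def scans_of(self, subject_id: str) -> list[PairedScan]:
        return [s for s in self.scans if s.subject_id == subject_id]

    def subset(self, keys: Sequence[tuple[str, int]]) -> "Cohort":
        wanted = set(keys)
        return Cohort([s for s in self.scans if s.key in wanted], self.manifest_path)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, modality: Modality | str) -> Volume:
    """Read a NIfTI volume, canonicalized to RAS axis order."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return Volume(data=data, voxel_size_mm=tuple(float(z) for z in zooms), modality=Modality(modality))


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with an identity-scaled affine from voxel size."""
    path = Path(path)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    if volume.modality is Modality.MASK:
        data = volume.data.astype(np.uint8)
    elif volume.modality is Modality.LABELS:
        data = volume.data.astype(np.int32)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.voxel_size_mm)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Grid conformance
# ---------------------------------------------------------------------------

def conform(
    volume: Volume,
    target_shape: Sequence[int],
    mode: str = "crop_pad",
) -> Volume:
    """Bring a volume onto a fixed grid shape.

    Default mode ``crop_pad`` center-crops axes that are too large and
    symmetrically zero-pads axes that are too small; it is lossless for the
    retained field of view, involves no interpolation, and is idempotent.
    Mode ``resample`` trilinearly resamples instead (voxel size is rescaled
    accordingly).
    """
    target = tuple(int(t) for t in target_shape)
    if len(target) != 3 or any(t < 1 for t in target):
        raise ValueError(f"target_shape must be 3 positive integers, got {target_shape}")
    if mode == "resample":
        from scipy.ndimage import zoom

        factors = [t / s for t, s in zip(target, volume.shape)]
        order = 0 if volume.modality in (Modality.MASK, Modality.LABELS) else 1
        data = zoom(volume.data.astype(np.float32), factors, order=order)
        # rounding in zoom can be off by one voxel; trim/pad to exact shape
        vol = Volume(
            data=data,
            voxel_size_mm=tuple(v / f for v, f in zip(volume.voxel_size_mm, factors)),
            modality=volume.modality,
        )
        return conform(vol, target, mode="crop_pad")
    if mode != "crop_pad":
        raise ValueError(f"unknown conform mode {mode!r}")

    data = volume.data
    # crop where larger
    slices = []
    for axis, (cur, tgt) in enumerate(zip(data.shape, target)):
        if cur > tgt:
            lo = (cur - tgt) // 2
            slices.append(slice(lo, lo + tgt))
        else:
            slices.append(slice(None))
    data = data[tuple(slices)]
    # pad where smaller
    pads = []
    for cur, tgt in zip(data.shape, target):
        extra = max(tgt - cur, 0)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        data = np.pad(data, pads, mode="constant", constant_values=0)
    return volume.with_data(data)


# ---------------------------------------------------------------------------
# Cohort loading
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("subject_id", "session", "group", "genotype", "mri", "pet", "mask", "labels")


def _read_manifest(manifest: str | Path) -> pd.DataFrame:
    manifest = Path(manifest)
    sep = "\t" if manifest.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(manifest, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {manifest} missing required columns: {missing}")
    if "labels" not in df.columns:
        df["labels"] = ""
    return df


def load_cohort(manifest: str | Path, data_dir: str | Path | None = None) -> Cohort:
    """Load a cohort from a delimited manifest (header row required).

    Columns: subject_id, session, group, genotype, mri, pet, mask, labels
    (labels may be empty). File names are resolved relative to ``data_dir``
    (default: the manifest's directory). Row order is preserved.
    """
    manifest = Path(manifest)
    base = Path(data_dir) if data_dir is not None else manifest.parent
    df = _read_manifest(manifest)
    scans: list[PairedScan] = []
    for idx, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            group = Group(row["group"])
        except ValueError:
            raise ValueError(f"row {idx} (subject {sid}): unknown group token {row['group']!r}") from None
        try:
            genotype = Genotype(row["genotype"])
        except ValueError:
            raise ValueError(
                f"row {idx} (subject {sid}): unknown genotype token {row['genotype']!r}"
            ) from None
        vols = {}
        for col, modality in (("mri", Modality.MRI), ("pet", Modality.PET), ("mask", Modality.MASK)):
            path = base / str(row[col])
            if not path.exists():
                raise FileNotFoundError(
                    f"row {idx} (subject {sid}): missing {col} file {path}"
                )
            vols[col] = read_volume(path, modality)
        labels = None
        if str(row["labels"]).strip():
            lpath = base / str(row["labels"])
            if not lpath.exists():
                raise FileNotFoundError(f"row {idx} (subject {sid}): missing labels file {lpath}")
            labels = read_volume(lpath, Modality.LABELS)
        scans.append(
            PairedScan(
                subject_id=sid,
                session=int(row["session"]),
                group=group,
                genotype=genotype,
                mri=vols["mri"],
                pet=vols["pet"],
                mask=vols["mask"],
                labels=labels,
            )
        )
    return Cohort(scans=scans, manifest_path=str(manifest))
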