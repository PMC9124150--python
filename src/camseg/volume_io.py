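"""Reading/writing CT volumes and masks, dataset manifests and splits.

Volumes travel as NIfTI (``.nii``/``.nii.gz``) or MetaImage
(``.mha``/``.mhd``) via SimpleITK; arrays are indexed ``(z, y, x)`` with
per-axis spacing in the same order (see :mod:`camseg.types`).

A dataset manifest is a CSV with columns
``patient_id,split,image_path,mask_path,has_tumor,tumor_slices,nontumor_slices``;
splits are assigned *per patient* (never per slice) so no patient leaks
across the train/validation/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import CamsegError, NonVolumePayloadError, UnsupportedFormatError
from .types import CTVolume, LabelMask

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")
SPLITS = ("train", "validation", "test")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _EXTENSIONS):
        raise UnsupportedFormatError(
            f"unsupported volume format {path.suffix!r} for {path}; "
            f"expected one of {_EXTENSIONS}")


def read_volume(path) -> CTVolume:
    """Read a 3D volume, preserving spacing/origin/direction from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise NonVolumePayloadError(
            f"{path} holds a {img.GetDimension()}D payload; a 3D volume is required")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    if data.ndim != 3:
        raise NonVolumePayloadError(f"{path} payload is not scalar 3D (shape {data.shape})")
    return CTVolume(
        data=data,
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def write_volume(vol, path) -> Path:
    """Write a CTVolume or LabelMask; readable back with identical data/geometry."""
    path = Path(path)
    _check_extension(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(vol.origin)
    img.SetDirection(vol.direction)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise CamsegError(f"cannot write {path}: {exc}") from exc
    return path


def read_mask(path, labels={0, 1}) -> LabelMask:
    """Read a label mask; every voxel must belong to ``labels`` after int cast."""
    vol = read_volume(path)
    data = vol.data
    cast = np.rint(data).astype(np.int64)
    return LabelMask(cast, labels=frozenset(labels), spacing=vol.spacing,
                     origin=vol.origin, direction=vol.direction)


@dataclass
class ManifestRecord:
    patient_id: str
    split: str
    image_path: str
    mask_path: str
    has_tumor: bool
    tumor_slices: int = 0
    nontumor_slices: int = 0

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")
        if not self.image_path or not self.mask_path:
            raise ValueError("image_path and mask_path must be non-empty")
        if self.tumor_slices < 0 or self.nontumor_slices < 0:
            raise ValueError("slice tallies must be non-negative")


@dataclass
class Manifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rec in self.records:
            prev = seen.setdefault(rec.patient_id, rec.split)
            if prev != rec.split:
                raise ValueError(
                    f"patient {rec.patient_id!r} appears in splits {prev!r} and "
                    f"{rec.split!r}; patients must not leak across splits")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def write_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path) -> "Manifest":
        df = pd.read_csv(path)
        records = [
            ManifestRecord(
                patient_id=str(r.patient_id), split=str(r.split),
                image_path=str(r.image_path), mask_path=str(r.mask_path),
                has_tumor=bool(r.has_tumor),
                tumor_slices=int(r.tumor_slices), nontumor_slices=int(r.nontumor_slices),
            )
            for r in df.itertuples()
        ]
        return cls(records)


def manifest_totals(m: Manifest, slice_counts: dict[str, tuple[int, int]] | None = None
                    ) -> pd.DataFrame:
    """Per-split and grand totals of patients and (tumor / non-tumor / all) slices.

    ``slice_counts`` optionally overrides the per-record tallies, keyed by
    patient id as ``(tumor_slices, nontumor_slices)``.
    """
    rows = []
    for rec in m.records:
        tumor, nontumor = (slice_counts[rec.patient_id] if slice_counts is not None
                           else (rec.tumor_slices, rec.nontumor_slices))
        if tumor < 0 or nontumor < 0:
            raise ValueError(f"negative slice tally for patient {rec.patient_id!r}")
        rows.append((rec.split, rec.patient_id, int(tumor), int(nontumor)))
    table = pd.DataFrame(rows, columns=["split", "patient_id", "tumor", "nontumor"])
    out = pd.DataFrame(index=list(SPLITS) + ["total"],
                       columns=["patients", "tumor_slices", "nontumor_slices", "all_slices"],
                       data=0, dtype=np.int64)
    for split in SPLITS:
        sub = table[table.split == split]
        out.loc[split] = [sub.patient_id.nunique(), sub.tumor.sum(), sub.nontumor.sum(),
                          sub.tumor.sum() + sub.nontumor.sum()]
    out.loc["total"] = out.loc[list(SPLITS)].sum()
    return out


def split_dataset(m: Manifest, fractions: tuple[float, float, float],
                  seed: int) -> Manifest:
    """Assign patients to (train, validation, test) by largest-remainder rounding.

    Assignment is per patient; ties in the remainder are broken by the
    seeded shuffle order, and the same seed always yields the same split.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    patients = sorted({r.patient_id for r in m.records})
    if len(patients) < len(SPLITS):
        raise ValueError(f"need at least {len(SPLITS)} patients, have {len(patients)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    n = len(order)
    quota = [f * n for f in fractions]
    counts = [int(np.floor(q)) for q in quota]
    remainders = [q - c for q, c in zip(quota, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    assignment: dict[str, str] = {}
    start = 0
    for split, count in zip(SPLITS, counts):
        for pid in order[start:start + count]:
            assignment[pid] = split
        start += count
    records = [ManifestRecord(**{**asdict(r), "split": assignment[r.patient_id]})
               for r in m.records]
    return Manifest(records)
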