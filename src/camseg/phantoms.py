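"""Seeded synthetic thorax-CT phantoms with ground-truth nodule masks.

Each case is a geometric thorax on an air background (-1000 HU): a
soft-tissue body ellipsoid (~40 HU), two lung ellipsoids (~-800 HU), a
tubular trachea branching into two bronchi at airway HU, and spherical
tumor nodules (diameters drawn from 5-32 mm, the size range of the lung
nodules the segmentation task targets) placed strictly inside the lungs at
soft-tissue-like intensity.  Gaussian HU noise is added last.  The paired
mask marks nodule voxels only.  Everything is driven by one seed, so a case
is bit-reproducible.

The phantoms are deliberately geometric rather than anatomically realistic:
they exist so the preprocessing, training and evaluation machinery can be
exercised end to end at desk scale with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import CamsegError, ConfigError
from .types import CTVolume, LabelMask
from .volume_io import Manifest, ManifestRecord, split_dataset, write_volume


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    body_hu: tuple[float, float] = (40.0, 20.0)      # mean, sigma (per-case jitter)
    lung_hu: tuple[float, float] = (-800.0, 50.0)
    airway_hu: float = -1000.0
    nodule_hu: tuple[float, float] = (30.0, 15.0)
    nodule_diameter_mm: tuple[float, float] = (5.0, 32.0)
    nodules_per_case: tuple[int, int] = (1, 3)
    noise_sigma_hu: float = 20.0
    lobulated: bool = False  # nodules as unions of overlapping spheres

    def __post_init__(self) -> None:
        extent = min(s * n for s, n in zip(self.spacing, self.shape))
        lo, hi = self.nodule_diameter_mm
        if not 0 < lo <= hi < extent:
            raise ConfigError(
                f"nodule diameters {self.nodule_diameter_mm} must lie in (0, {extent}) mm")
        for _, sigma in (self.body_hu, self.lung_hu, self.nodule_hu):
            if sigma < 0:
                raise ConfigError("intensity sigmas must be >= 0")
        if self.noise_sigma_hu < 0:
            raise ConfigError("noise_sigma_hu must be >= 0")


@dataclass
class PhantomCase:
    volume: CTVolume
    mask: LabelMask
    nodule_centers_mm: list[tuple[float, float, float]] = field(default_factory=list)
    nodule_diameters_mm: list[float] = field(default_factory=list)
    seed: int = 0


def _grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def rasterize_sphere(center_mm, diameter_mm: float, shape, spacing) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within ``diameter/2`` of ``center``.

    A sphere smaller than one voxel still marks its containing voxel.
    """
    center_mm = np.asarray(center_mm, dtype=float)
    radius = diameter_mm / 2.0
    extent = np.array([s * (n - 1) for n, s in zip(shape, spacing)])
    if np.any(center_mm - radius < -1e-9) or np.any(center_mm + radius > extent + 1e-9):
        raise CamsegError(
            f"sphere (center {tuple(center_mm)}, d={diameter_mm} mm) extends outside the grid")
    zz, yy, xx = _grid_mm(shape, spacing)
    d2 = (zz - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2 + (xx - center_mm[2]) ** 2
    mask = d2 <= radius ** 2
    if not mask.any():
        idx = tuple(int(round(c / s)) for c, s in zip(center_mm, spacing))
        mask[idx] = True
    return mask


def _ellipsoid(shape, spacing, center_frac, semi_frac) -> np.ndarray:
    extent = np.array([s * n for n, s in zip(shape, spacing)])
    center = extent * np.asarray(center_frac)
    semi = extent * np.asarray(semi_frac)
    zz, yy, xx = _grid_mm(shape, spacing)
    q = (((zz - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2
         + ((xx - center[2]) / semi[2]) ** 2)
    return q <= 1.0


def _tube(shape, spacing, p0, p1, radius_mm) -> np.ndarray:
    """Voxels within ``radius_mm`` of the segment p0-p1 (fractions of extent)."""
    extent = np.array([s * n for n, s in zip(shape, spacing)])
    a, b = extent * np.asarray(p0), extent * np.asarray(p1)
    zz, yy, xx = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                             indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[..., None] * ab
    d2 = ((pts - closest) ** 2).sum(axis=-1)
    return d2 <= radius_mm ** 2


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """One seeded thorax phantom with paired nodule ground truth."""
    rng = np.random.default_rng(seed)
    shape, spacing = spec.shape, spec.spacing

    body = _ellipsoid(shape, spacing, (0.5, 0.5, 0.5), (0.48, 0.42, 0.45))
    lung_l = _ellipsoid(shape, spacing, (0.5, 0.48, 0.30), (0.34, 0.26, 0.16))
    lung_r = _ellipsoid(shape, spacing, (0.5, 0.48, 0.70), (0.34, 0.26, 0.16))
    lungs = (lung_l | lung_r) & body
    trachea = _tube(shape, spacing, (0.05, 0.45, 0.5), (0.45, 0.45, 0.5),
                    max(1.5, 1.2 * min(spacing)))
    bronchus_l = _tube(shape, spacing, (0.45, 0.45, 0.5), (0.6, 0.47, 0.32),
                       max(1.2, min(spacing)))
    bronchus_r = _tube(shape, spacing, (0.45, 0.45, 0.5), (0.6, 0.47, 0.68),
                       max(1.2, min(spacing)))
    airways = (trachea | bronchus_l | bronchus_r) & body

    body_val = rng.normal(*spec.body_hu)
    lung_val = rng.normal(*spec.lung_hu)
    nodule_val = rng.normal(*spec.nodule_hu)

    hu = np.full(shape, spec.airway_hu, dtype=np.float64)
    hu[body] = body_val
    hu[lungs] = lung_val
    hu[airways] = spec.airway_hu

    # place nodules strictly inside lung tissue (not in airways)
    lung_free = lungs & ~airways
    dist_in = ndimage.distance_transform_edt(lung_free, sampling=spacing)
    n_nodules = int(rng.integers(spec.nodules_per_case[0], spec.nodules_per_case[1] + 1))
    mask = np.zeros(shape, dtype=np.int16)
    centers, diameters = [], []
    for _ in range(n_nodules):
        placed = False
        for _attempt in range(200):
            d = float(rng.uniform(*spec.nodule_diameter_mm))
            candidates = np.argwhere(dist_in > d / 2.0)
            if len(candidates) == 0:
                continue
            idx = candidates[rng.integers(len(candidates))]
            center = tuple(float(i * s) for i, s in zip(idx, spacing))
            sphere = rasterize_sphere(center, d, shape, spacing)
            if spec.lobulated:
                for _lobe in range(int(rng.integers(1, 4))):
                    offset = rng.uniform(-d / 4, d / 4, size=3)
                    c2 = tuple(np.asarray(center) + offset)
                    try:
                        sphere |= rasterize_sphere(c2, d * 0.6, shape, spacing)
                    except CamsegError:
                        pass
            sphere &= lung_free  # lobes may poke out; ground truth stays in lung
            hu[sphere] = nodule_val
            mask[sphere] = 1
            centers.append(center)
            diameters.append(d)
            placed = True
            break
        if not placed:
            raise CamsegError(
                f"could not place a nodule of the requested size range "
                f"{spec.nodule_diameter_mm} mm inside the lungs")
    if spec.noise_sigma_hu > 0:
        hu += rng.normal(0.0, spec.noise_sigma_hu, size=shape)

    vol = CTVolume(hu, spacing=spacing)
    lab = LabelMask(mask, spacing=spacing)
    return PhantomCase(vol, lab, centers, diameters, seed)


def generate_dataset(n_cases: int, spec: PhantomSpec, seed: int,
                     fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     out_dir=None, tumor_fraction: float = 1.0):
    """Generate ``n_cases`` phantoms; returns (manifest, cases).

    When ``out_dir`` is given, volumes/masks are written as NIfTI and the
    manifest as ``manifest.csv``.  ``tumor_fraction`` controls the mix of
    with/without-tumor cases.
    """
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=n_cases)
    cases, records = [], []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, cs in enumerate(case_seeds):
        case_spec = spec
        has_tumor = rng.random() < tumor_fraction
        if not has_tumor:
            case_spec = replace(spec, nodules_per_case=(0, 0))
        case = generate_phantom(case_spec, int(cs))
        cases.append(case)
        image_path, mask_path = f"case_{i:03d}.nii.gz", f"case_{i:03d}_mask.nii.gz"
        if out_dir is not None:
            write_volume(case.volume, out_dir / image_path)
            write_volume(case.mask, out_dir / mask_path)
        tumor_slices = int(np.count_nonzero(case.mask.data.any(axis=(1, 2))))
        records.append(ManifestRecord(
            patient_id=f"case_{i:03d}", split="train",
            image_path=image_path, mask_path=mask_path,
            has_tumor=bool(case.mask.data.any()),
            tumor_slices=tumor_slices,
            nontumor_slices=case.mask.data.shape[0] - tumor_slices,
        ))
    manifest = split_dataset(Manifest(records), fractions, seed)
    if out_dir is not None:
        manifest.write_csv(out_dir / "manifest.csv")
    return manifest, cases
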