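"""CT preprocessing chain and training-time augmentation.

The chain is applied in fixed order: (1) truncate intensities to the
Hounsfield window [-1000, 400] HU — the range that matters for lung
anatomy; (2) z-score the scan to zero mean / unit variance (population
standard deviation, computed after clipping); (3) resample to a cubic grid
(default 128^3), linear interpolation for images and nearest-neighbour for
masks so no new labels are invented.

Augmentation draws, from one seed: an optional left-right flip (applied to
image and mask alike), an optional intensity inversion ``v -> -v`` (image
only; on a z-scored volume this preserves zero mean and unit variance), and
an in-plane (axial) rotation with angle uniform in +/- ``max_rotation_deg``
(default 10 degrees).  Rotated volumes are padded with the volume minimum —
after clip + z-score that is the air value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ConfigError, DegenerateInputError
from .types import CTVolume, LabelMask, require_same_geometry


@dataclass
class PreprocessConfig:
    hu_low: float = -1000.0
    hu_high: float = 400.0
    target_shape: tuple[int, int, int] = (128, 128, 128)
    image_interpolation: str = "linear"
    mask_interpolation: str = "nearest"
    augment_flip_lr: bool = True
    augment_intensity_invert: bool = True
    max_rotation_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise ConfigError(f"hu_low ({self.hu_low}) must be < hu_high ({self.hu_high})")
        if any(s < 8 for s in self.target_shape):
            raise ConfigError(f"target_shape must be >= 8 per axis, got {self.target_shape}")
        if self.max_rotation_deg < 0:
            raise ConfigError("max_rotation_deg must be >= 0")
        if self.image_interpolation != "linear" or self.mask_interpolation != "nearest":
            raise ConfigError("images use linear and masks nearest interpolation")


def clip_hu(vol: CTVolume, cfg: PreprocessConfig | None = None) -> CTVolume:
    """Truncate HU values to the window [hu_low, hu_high]."""
    cfg = cfg or PreprocessConfig()
    return vol.with_data(np.clip(vol.data, cfg.hu_low, cfg.hu_high))


def normalize_zscore(vol: CTVolume) -> CTVolume:
    """Per-scan z-normalization (population standard deviation)."""
    data = np.asarray(vol.data, dtype=np.float64)
    std = data.std()
    if std == 0:
        raise DegenerateInputError("constant volume cannot be z-scored (zero variance)")
    return vol.with_data((data - data.mean()) / std)


def resample(vol_or_mask, target_shape: tuple[int, int, int]):
    """Resample to ``target_shape``: linear for volumes, nearest for masks.

    Spacing is rescaled by the shape ratio so physical extent is preserved.
    """
    obj = vol_or_mask
    target_shape = tuple(int(t) for t in target_shape)
    new_spacing = tuple(s * n / t for s, n, t in zip(obj.spacing, obj.data.shape, target_shape))
    if isinstance(obj, LabelMask):
        out = _sk_resize(obj.data.astype(np.float64), target_shape, order=0,
                         preserve_range=True, anti_aliasing=False, mode="edge")
        return obj.with_data(np.rint(out).astype(obj.data.dtype), spacing=new_spacing)
    out = _sk_resize(np.asarray(obj.data, dtype=np.float64), target_shape, order=1,
                     preserve_range=True, anti_aliasing=False, mode="edge")
    # linear interpolation cannot overshoot, but guard against float fuzz
    out = np.clip(out, obj.data.min(), obj.data.max())
    return obj.with_data(out, spacing=new_spacing)


def augment(vol: CTVolume, mask: LabelMask, cfg: PreprocessConfig,
            seed: int) -> tuple[CTVolume, LabelMask]:
    """Seeded flip / intensity-inversion / small-rotation augmentation.

    The identical spatial transform is applied to volume (linear) and mask
    (nearest); intensity inversion touches the volume only.
    """
    require_same_geometry(vol, mask)
    rng = np.random.default_rng(seed)
    flip = cfg.augment_flip_lr and rng.random() < 0.5
    invert = cfg.augment_intensity_invert and rng.random() < 0.5
    angle = float(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)) \
        if cfg.max_rotation_deg > 0 else 0.0

    vdata = np.asarray(vol.data, dtype=np.float64)
    mdata = mask.data
    if flip:  # left-right = last array axis
        vdata = vdata[:, :, ::-1]
        mdata = mdata[:, :, ::-1]
    if angle != 0.0:
        pad = float(vdata.min())
        vdata = ndimage.rotate(vdata, angle, axes=(1, 2), reshape=False,
                               order=1, mode="constant", cval=pad)
        mdata = ndimage.rotate(mdata, angle, axes=(1, 2), reshape=False,
                               order=0, mode="constant", cval=0)
    if invert:
        vdata = -vdata
    return vol.with_data(np.ascontiguousarray(vdata)), mask.with_data(np.ascontiguousarray(mdata))


def preprocess_case(vol: CTVolume, mask: LabelMask | None,
                    cfg: PreprocessConfig | None = None):
    """Full chain: clip -> z-normalize -> resample (mask: nearest resample)."""
    cfg = cfg or PreprocessConfig()
    out = resample(normalize_zscore(clip_hu(vol, cfg)), cfg.target_shape)
    if mask is None:
        return out, None
    require_same_geometry(vol, mask)
    return out, resample(mask, cfg.target_shape)
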