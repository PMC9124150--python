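"""Core grid types: HU-valued CT volumes and integer label masks.

Arrays are indexed ``(z, y, x)`` (slowest axis first, the order
``SimpleITK.GetArrayFromImage`` returns).  ``spacing`` is stored per *array*
axis in millimetres, i.e. ``spacing[0]`` is the slice thickness along axis 0.
``origin`` and ``direction`` follow the world-coordinate convention of the
file header (x, y, z order, row-major 3x3 direction cosines) and are carried
through unchanged; all in-package geometry (rasterisation, surface
distances) works in voxel space scaled by ``spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryMismatchError, OutOfVocabularyLabelError

_IDENTITY_DIRECTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units with physical geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CTVolume data must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, spacing=None) -> "CTVolume":
        """New volume with replaced voxel data (and optionally spacing), same frame."""
        return replace(self, data=data, spacing=self.spacing if spacing is None else spacing)

    def same_geometry(self, other) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.direction, other.direction)
        )


@dataclass
class LabelMask:
    """An integer label grid aligned with a :class:`CTVolume`.

    ``labels`` is the allowed vocabulary; the binary default is
    {0: background, 1: tumor}.
    """

    data: np.ndarray
    labels: frozenset[int] = field(default_factory=lambda: frozenset({0, 1}))
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMask data must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            cast = self.data.astype(np.int64)
            if not np.array_equal(cast, self.data):
                raise ValueError("LabelMask data must be integer-valued")
            self.data = cast
        self.labels = frozenset(int(v) for v in self.labels)
        present = set(np.unique(self.data).tolist())
        extra = present - self.labels
        if extra:
            value = sorted(extra)[0]
            loc = tuple(int(i) for i in np.argwhere(self.data == value)[0])
            raise OutOfVocabularyLabelError(
                f"voxel value {value} at index {loc} is outside the label set {sorted(self.labels)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, spacing=None) -> "LabelMask":
        return replace(self, data=data, spacing=self.spacing if spacing is None else spacing)

    def same_geometry(self, other) -> bool:
        return CTVolume.same_geometry(self, other)  # type: ignore[arg-type]


def require_same_geometry(a, b, what: str = "volume and mask") -> None:
    if not CTVolume.same_geometry(a, b):  # type: ignore[arg-type]
        raise GeometryMismatchError(
            f"{what} geometry differs: shapes {a.data.shape} vs {b.data.shape}, "
            f"spacings {a.spacing} vs {b.spacing}"
        )
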