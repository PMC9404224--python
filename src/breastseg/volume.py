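"""In-memory containers for 3D volumes and binary masks.

A :class:`Volume3D` is a scalar image on a regular anisotropic grid. Voxel
indices are 0-based and map to world (scanner) coordinates in millimetres via

    world = origin + index * spacing_mm

with a fixed canonical axis order (arrays are indexed ``[i, j, k]`` along the
three spatial axes in the order they are stored on disk after orientation
canonicalization). Every geometric feature downstream (diameters, volumes,
mesh extraction) is defined in mm through this mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Volume3D",
    "Mask3D",
    "GeometryError",
    "PairMismatchError",
    "validate_pair",
]


class GeometryError(ValueError):
    """Invalid geometry metadata (non-positive spacing, wrong rank, ...)."""


class PairMismatchError(ValueError):
    """An image/mask pair disagrees geometrically; ``reasons`` names each mismatch."""

    def __init__(self, reasons: list[str]):
        self.reasons = list(reasons)
        super().__init__("; ".join(reasons))


def _check_geometry(data: np.ndarray, spacing: np.ndarray, origin: np.ndarray) -> None:
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D array, got {data.ndim}D shape {data.shape}")
    if spacing.shape != (3,) or origin.shape != (3,):
        raise GeometryError("spacing_mm and origin must be length-3 vectors")
    if not np.all(spacing > 0):
        raise GeometryError(f"spacing must be strictly positive, got {tuple(spacing)}")


@dataclass(frozen=True)
class Volume3D:
    """3D scalar image with voxel spacing (mm) and world origin."""

    data: np.ndarray
    spacing_mm: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float32)
        spacing = np.asarray(self.spacing_mm, dtype=float)
        origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        )
        _check_geometry(data, spacing, origin)
        if not np.all(np.isfinite(data)):
            raise GeometryError("volume contains non-finite voxels")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return replace(self, data=data)


@dataclass(frozen=True)
class Mask3D:
    """Binary label volume aligned to a :class:`Volume3D`."""

    labels: np.ndarray
    spacing_mm: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        spacing = np.asarray(self.spacing_mm, dtype=float)
        origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        )
        _check_geometry(labels, spacing, origin)
        values = np.unique(labels)
        if not np.all(np.isin(values, (0, 1))):
            raise GeometryError(f"mask is not binary; found values {values[:10]}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.labels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        """Total foreground volume: count x per-voxel volume (exact)."""
        return self.voxel_count * float(np.prod(self.spacing_mm))

    def with_labels(self, labels: np.ndarray) -> "Mask3D":
        return replace(self, labels=labels)


def validate_pair(
    vol: Volume3D,
    mask: Mask3D,
    *,
    spacing_rtol: float = 1e-4,
    origin_atol_mm: float = 1e-3,
) -> tuple[Volume3D, Mask3D]:
    """Check that an image and mask share a voxel grid.

    Each mismatch is reported individually in :class:`PairMismatchError`.
    Mask binarity is re-checked defensively even though ``Mask3D`` enforces it
    at construction, so arrays mutated in place are still caught.
    """
    reasons = []
    if vol.shape != mask.shape:
        reasons.append(f"shape mismatch: image {vol.shape} vs mask {mask.shape}")
    if not np.allclose(vol.spacing_mm, mask.spacing_mm, rtol=spacing_rtol, atol=0):
        reasons.append(
            f"spacing mismatch: image {tuple(vol.spacing_mm)} vs mask {tuple(mask.spacing_mm)}"
        )
    if not np.allclose(vol.origin, mask.origin, atol=origin_atol_mm):
        reasons.append(f"origin mismatch: image {tuple(vol.origin)} vs mask {tuple(mask.origin)}")
    if not np.all(np.isin(np.unique(mask.labels), (0, 1))):
        reasons.append("non-binary mask")
    if reasons:
        raise PairMismatchError(reasons)
    return vol, mask
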