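"""NIfTI I/O and cohort manifests.

Volumes and masks are exchanged as NIfTI-1 (``.nii`` / ``.nii.gz``). On read,
images are reoriented to the closest canonical (RAS) axis order so that all
in-memory arrays share one convention; voxel spacing is taken from the header
zooms and the world origin from the affine translation. Images are stored as
float32 and masks as unsigned 8-bit for interoperability with common viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import GeometryError, Mask3D, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "CohortManifest",
]

MANIFEST_COLUMNS = [
    "case_id",
    "image_path",
    "mask_path",
    "a_mm",
    "b_mm",
    "c_mm",
    "volume_mm3",
    "t_stage",
    "core_volume_mm3",
    "seed",
]


def _load_canonical(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D image, got {img.ndim}D {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return data, spacing, origin


def read_volume(path: str | Path) -> Volume3D:
    """Read a 3D scalar volume; rejects non-3D images and NaN voxels."""
    data, spacing, origin = _load_canonical(path)
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise GeometryError(f"{path}: volume contains NaN/inf voxels")
    return Volume3D(data=data, spacing_mm=spacing, origin=origin)


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(np.append(vol.spacing_mm, 1.0))
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))
    return path


def read_mask(path: str | Path) -> Mask3D:
    """Read a binary mask; any value outside {0, 1} is rejected."""
    data, spacing, origin = _load_canonical(path)
    return Mask3D(labels=np.rint(np.asarray(data)).astype(np.uint8), spacing_mm=spacing, origin=origin)


def write_mask(mask: Mask3D, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(np.append(mask.spacing_mm, 1.0))
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), affine), str(path))
    return path


@dataclass
class CohortManifest:
    """Table of cohort cases: file paths plus optional ground-truth geometry.

    Columns: case_id, image_path, mask_path and, for simulated cohorts,
    a_mm, b_mm, c_mm (ellipsoid semi-axes), volume_mm3, t_stage,
    core_volume_mm3 and seed.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = {"case_id", "image_path", "mask_path"} - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing required columns: {sorted(missing)}")
        if self.table["case_id"].duplicated().any():
            dup = self.table.loc[self.table["case_id"].duplicated(), "case_id"].tolist()
            raise ValueError(f"duplicate case_ids in manifest: {dup}")

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return (row for _, row in self.table.iterrows())

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such manifest: {path}")
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def validate_files(self) -> None:
        """Check that every referenced image/mask file exists."""
        for row in self:
            for key in ("image_path", "mask_path"):
                if not Path(row[key]).exists():
                    raise FileNotFoundError(f"case {row['case_id']}: missing {key} {row[key]}")

    def spacings(self) -> np.ndarray:
        """Per-case voxel spacings read from the image headers, shape (n, 3)."""
        out = []
        for row in self:
            img = nib.load(str(row["image_path"]))
            out.append(np.asarray(img.header.get_zooms()[:3], dtype=float))
        return np.array(out)
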