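"""Intensity normalization, respacing, balanced patch sampling, augmentation.

The preparation applied to every case before training and inference:

1. resample to the cohort's mean voxel spacing (continuous interpolation for
   images, nearest neighbour for masks);
2. per-case z-score normalization after clamping the intensities to the
   [0.5th, 99.5th] percentile range;
3. random patch extraction with the patch center placed on a foreground or
   background voxel with configurable probability (default half-and-half,
   a 2:1 foreground bias is supported as configuration);
4. training-time augmentation: random zoom, intensity scale/shift, Gaussian
   noise, 90-degree rotation and elastic deformation. Geometric transforms
   apply to image and label (nearest interpolation keeps the label binary);
   intensity transforms touch the image only.

Normalization statistics and the percentile clamp are computed per volume
after respacing, over the whole clamped volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import CohortManifest
from .volume import Mask3D, Volume3D

__all__ = [
    "NormalizationParams",
    "PatchConfig",
    "PatchSample",
    "AugmentConfig",
    "clamp_normalize",
    "compute_target_spacing",
    "resample_volume",
    "sample_patches",
    "augment_patch",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Percentile clamp bounds and the fitted per-case z-score statistics."""

    lower_pct: float = 0.5
    upper_pct: float = 99.5
    mean: float | None = None
    sd: float | None = None
    epsilon: float = 1e-8

    def __post_init__(self):
        if not 0 <= self.lower_pct < self.upper_pct <= 100:
            raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class PatchConfig:
    patch_size: tuple[int, int, int] = (96, 96, 96)
    fg_center_prob: float = 0.5
    samples_per_volume: int = 4

    def __post_init__(self):
        if any(d <= 0 or d % 2 for d in self.patch_size):
            raise ValueError(f"each patch dimension must be a positive multiple of 2, got {self.patch_size}")
        if not 0.0 <= self.fg_center_prob <= 1.0:
            raise ValueError("fg_center_prob must lie in [0, 1]")


@dataclass(frozen=True)
class PatchSample:
    image_patch: np.ndarray
    label_patch: np.ndarray
    center_index: tuple[int, int, int]
    source_case_id: str = ""


@dataclass(frozen=True)
class AugmentConfig:
    """Enable flags and parameter ranges for training-time augmentation.

    Magnitudes are conservative defaults in normalized-intensity units; each
    transform fires independently with probability ``p_*``.
    """

    p_zoom: float = 0.2
    zoom_range: tuple[float, float] = (0.9, 1.1)
    p_scale_intensity: float = 0.2
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_shift_intensity: float = 0.2
    shift_range: tuple[float, float] = (-0.1, 0.1)
    p_gaussian_noise: float = 0.2
    noise_sd_max: float = 0.1
    p_rot90: float = 0.2
    p_elastic: float = 0.2
    elastic_sigma_vox: float = 6.0
    elastic_alpha_vox: float = 2.0

    def __post_init__(self):
        for name in ("p_zoom", "p_scale_intensity", "p_shift_intensity",
                     "p_gaussian_noise", "p_rot90", "p_elastic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.zoom_range[0] <= 1.0 <= self.zoom_range[1]:
            raise ValueError("zoom_range must bracket 1.0")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(p_zoom=0, p_scale_intensity=0, p_shift_intensity=0,
                   p_gaussian_noise=0, p_rot90=0, p_elastic=0)


def clamp_normalize(
    vol: Volume3D, params: NormalizationParams | None = None
) -> tuple[Volume3D, NormalizationParams]:
    """Percentile-clamped per-case z-score normalization.

    Voxels are clipped to the [lower_pct, upper_pct] percentile range of the
    volume, then standardized with the mean and SD of the clipped volume. A
    constant volume maps to all zeros (epsilon guard) with a warning.
    """
    params = params or NormalizationParams()
    data = vol.data.astype(np.float64)
    lo, hi = np.percentile(data, [params.lower_pct, params.upper_pct])
    clipped = np.clip(data, lo, hi)
    mean = float(clipped.mean())
    sd = float(clipped.std())
    if sd < params.epsilon:
        warnings.warn("clamp_normalize: constant volume, returning zeros", stacklevel=2)
        out = np.zeros_like(clipped, dtype=np.float32)
    else:
        out = ((clipped - mean) / sd).astype(np.float32)
    return vol.with_data(out), replace(params, mean=mean, sd=sd)


def compute_target_spacing(manifest: CohortManifest) -> np.ndarray:
    """Per-axis arithmetic mean of the cohort's voxel spacings (mm)."""
    if len(manifest) == 0:
        raise ValueError("cannot compute target spacing of an empty manifest")
    return manifest.spacings().mean(axis=0)


def resample_volume(
    obj: Volume3D | Mask3D, target_spacing, mode: str = "continuous"
) -> Volume3D | Mask3D:
    """Resample to a new voxel spacing; shape = round(shape * old / new).

    ``continuous`` (trilinear) for images, ``nearest`` for masks — nearest
    keeps binary masks binary. The world extent is preserved to within one
    voxel by construction of the output shape.
    """
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be positive, got {tuple(target)}")
    if mode not in ("continuous", "nearest"):
        raise ValueError("mode must be 'continuous' or 'nearest'")
    data = obj.data if isinstance(obj, Volume3D) else obj.labels
    old_shape = np.array(data.shape)
    new_shape = np.rint(old_shape * obj.spacing_mm / target).astype(int)
    if np.any(new_shape < 1):
        raise ValueError(
            f"degenerate resample: target {tuple(target)} collapses shape {tuple(old_shape)}"
        )
    if np.array_equal(new_shape, old_shape) and np.allclose(obj.spacing_mm, target):
        return obj
    factors = new_shape / old_shape
    order = 1 if mode == "continuous" else 0
    out = ndimage.zoom(data.astype(np.float32), factors, order=order, mode="nearest", grid_mode=True)
    if isinstance(obj, Volume3D):
        return Volume3D(data=out, spacing_mm=target, origin=obj.origin)
    return Mask3D(labels=np.rint(out).astype(np.uint8), spacing_mm=target, origin=obj.origin)


def _pad_to(data: np.ndarray, shape, constant=0):
    pads = []
    for d, t in zip(data.shape, shape):
        extra = max(t - d, 0)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        data = np.pad(data, pads, constant_values=constant)
    return data


def sample_patches(
    vol: Volume3D,
    mask: Mask3D,
    cfg: PatchConfig,
    rng: np.random.Generator,
    source_case_id: str = "",
) -> list[PatchSample]:
    """Draw foreground/background-balanced random patches.

    With probability ``fg_center_prob`` the patch center is a uniformly drawn
    lesion voxel, otherwise a background voxel; centers are clipped so the
    patch lies fully inside the (zero-padded) volume. If the mask has no
    foreground, sampling falls back to background centers with a warning.
    """
    ps = np.array(cfg.patch_size)
    image = _pad_to(vol.data, ps)
    labels = _pad_to(mask.labels, ps)
    shape = np.array(image.shape)

    fg_idx = np.argwhere(labels > 0)
    bg_idx = np.argwhere(labels == 0)
    if len(fg_idx) == 0 and cfg.fg_center_prob > 0:
        warnings.warn("sample_patches: no foreground voxels, using background centers",
                      stacklevel=2)
    half_lo = ps // 2
    half_hi = ps - half_lo
    samples = []
    for _ in range(cfg.samples_per_volume):
        use_fg = len(fg_idx) > 0 and rng.uniform() < cfg.fg_center_prob
        pool = fg_idx if use_fg else bg_idx
        center = pool[rng.integers(len(pool))]
        center = np.clip(center, half_lo, shape - half_hi)
        lo = center - half_lo
        sl = tuple(slice(a, a + p) for a, p in zip(lo, ps))
        samples.append(
            PatchSample(
                image_patch=np.ascontiguousarray(image[sl]),
                label_patch=np.ascontiguousarray(labels[sl]),
                center_index=tuple(int(c) for c in center),
                source_case_id=source_case_id,
            )
        )
    return samples


def _elastic_displacement(shape, sigma, alpha, rng):
    fields = []
    for _ in range(3):
        f = rng.normal(size=shape)
        f = ndimage.gaussian_filter(f, sigma)
        f *= alpha / max(np.abs(f).max(), 1e-12)
        fields.append(f)
    return fields


def augment_patch(
    sample: PatchSample, cfg: AugmentConfig, rng: np.random.Generator
) -> PatchSample:
    """Apply the configured random transforms to one patch.

    Geometric transforms (zoom, 90-degree rotation, elastic deformation) move
    image and label together, the label with nearest interpolation; intensity
    transforms (scale, shift, noise) touch the image only. With every
    transform disabled the sample passes through bit-identically.
    """
    image, label = sample.image_patch, sample.label_patch
    ps = image.shape

    if cfg.p_zoom > 0 and rng.uniform() < cfg.p_zoom:
        z = rng.uniform(*cfg.zoom_range)
        img_z = ndimage.zoom(image, z, order=1, mode="nearest", grid_mode=True)
        lab_z = ndimage.zoom(label.astype(np.float32), z, order=0, mode="nearest", grid_mode=True)
        img_z = _pad_to(img_z, ps)
        lab_z = _pad_to(lab_z, ps)
        sl = tuple(slice((d - p) // 2, (d - p) // 2 + p) for d, p in zip(img_z.shape, ps))
        image, label = img_z[sl], np.rint(lab_z[sl]).astype(np.uint8)

    if cfg.p_rot90 > 0 and rng.uniform() < cfg.p_rot90:
        k = int(rng.integers(1, 4))
        axes = [(0, 1), (0, 2), (1, 2)][rng.integers(3)]
        # non-cubic patches only support in-plane rotation of square planes
        if image.shape[axes[0]] == image.shape[axes[1]]:
            image = np.rot90(image, k, axes=axes)
            label = np.rot90(label, k, axes=axes)

    if cfg.p_elastic > 0 and rng.uniform() < cfg.p_elastic:
        disp = _elastic_displacement(ps, cfg.elastic_sigma_vox, cfg.elastic_alpha_vox, rng)
        grid = np.indices(ps, dtype=np.float32)
        coords = [g + d for g, d in zip(grid, disp)]
        image = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
        label = ndimage.map_coordinates(label, coords, order=0, mode="nearest")

    if cfg.p_scale_intensity > 0 and rng.uniform() < cfg.p_scale_intensity:
        image = image * np.float32(rng.uniform(*cfg.scale_range))
    if cfg.p_shift_intensity > 0 and rng.uniform() < cfg.p_shift_intensity:
        image = image + np.float32(rng.uniform(*cfg.shift_range))
    if cfg.p_gaussian_noise > 0 and rng.uniform() < cfg.p_gaussian_noise:
        sd = rng.uniform(0, cfg.noise_sd_max)
        image = image + rng.normal(0, sd, size=ps).astype(np.float32)

    return PatchSample(
        image_patch=np.ascontiguousarray(image, dtype=np.float32),
        label_patch=np.ascontiguousarray(label, dtype=np.uint8),
        center_index=sample.center_index,
        source_case_id=sample.source_case_id,
    )
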