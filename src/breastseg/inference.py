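"""Whole-volume prediction: sliding windows, rotation TTA, ensembling, filtering.

Volumes are larger than the network's patch, so prediction tiles the volume
with overlapping windows and averages per-voxel class probabilities over all
covering windows. Test-time augmentation repeats the inference on copies of
the volume rotated by 90/180/270 degrees in the axial plane, rotates each
probability map back, and averages with the identity pass. A checkpoint
ensemble is an unweighted mean of member maps. The final mask is the
per-voxel argmax, from which connected foreground components with fewer than
30 voxels are removed as noise (components of exactly 30 voxels survive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .nn.losses import softmax
from .quantify import remove_small_components
from .volume import Mask3D, Volume3D

__all__ = [
    "InferenceConfig",
    "ProbabilityMap",
    "sliding_window_predict",
    "tta_predict",
    "ensemble_predict",
    "binarize_and_filter",
]


@dataclass(frozen=True)
class InferenceConfig:
    patch_size: tuple[int, int, int] = (96, 96, 96)
    window_overlap: float = 0.5
    tta_enabled: bool = False
    tta_angles: tuple[int, ...] = (90, 180, 270)
    tta_plane: tuple[int, int] = (0, 1)
    min_component_voxels: int = 30
    connectivity: int = 26
    batch_size: int = 1

    def __post_init__(self):
        if not 0.0 <= self.window_overlap < 1.0:
            raise ValueError("window_overlap must lie in [0, 1)")
        if not set(self.tta_angles) <= {90, 180, 270}:
            raise ValueError("tta_angles must be a subset of {90, 180, 270}")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-class probability volume aligned to its source Volume3D."""

    probs: np.ndarray  # (num_classes, D, H, W)
    spacing_mm: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=np.float32)
        if probs.ndim != 4:
            raise ValueError(f"expected (C, D, H, W) probabilities, got {probs.shape}")
        sums = probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("class probabilities must sum to 1 per voxel")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "spacing_mm", np.asarray(self.spacing_mm, dtype=float))
        origin = np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        object.__setattr__(self, "origin", origin)

    @property
    def num_classes(self) -> int:
        return self.probs.shape[0]


def _window_starts(size: int, patch: int, step: int) -> list[int]:
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch, step))
    starts.append(size - patch)  # flush final window covers the tail
    return sorted(set(starts))


def sliding_window_predict(model, vol: Volume3D, cfg: InferenceConfig) -> ProbabilityMap:
    """Tile the volume with overlapping patches and average the probabilities.

    ``model`` maps a ``(N, 1, d, h, w)`` batch to ``(N, C, d, h, w)`` raw
    scores. Every voxel is covered at least once; volumes smaller than the
    patch are zero-padded and cropped back. Windows overlap by
    ``window_overlap`` of the patch size and are averaged uniformly.
    """
    ps = np.array(cfg.patch_size)
    data = vol.data
    pads = [(max(p - s, 0) // 2, max(p - s, 0) - max(p - s, 0) // 2)
            for s, p in zip(data.shape, ps)]
    padded = np.pad(data, pads) if any(p != (0, 0) for p in pads) else data
    shape = np.array(padded.shape)
    step = np.maximum((ps * (1.0 - cfg.window_overlap)).astype(int), 1)
    starts = [_window_starts(shape[i], ps[i], step[i]) for i in range(3)]

    num_classes = None
    accum = None
    count = np.zeros(padded.shape, dtype=np.float32)
    windows = list(product(*starts))
    for batch_start in range(0, len(windows), cfg.batch_size):
        batch = windows[batch_start : batch_start + cfg.batch_size]
        x = np.stack(
            [padded[tuple(slice(s, s + p) for s, p in zip(w, ps))] for w in batch]
        )[:, None].astype(np.float32)
        scores = model.forward(x) if hasattr(model, "forward") else model(x)
        probs = softmax(np.asarray(scores, dtype=np.float32))
        if accum is None:
            num_classes = probs.shape[1]
            accum = np.zeros((num_classes, *padded.shape), dtype=np.float32)
        for w, pr in zip(batch, probs):
            sl = tuple(slice(s, s + p) for s, p in zip(w, ps))
            accum[(slice(None), *sl)] += pr
            count[sl] += 1.0
    accum /= count[None]
    crop = tuple(slice(p[0], p[0] + s) for p, s in zip(pads, data.shape))
    return ProbabilityMap(
        probs=accum[(slice(None), *crop)], spacing_mm=vol.spacing_mm, origin=vol.origin
    )


def _pad_square(data: np.ndarray, plane: tuple[int, int]):
    a, b = plane
    size = max(data.shape[a], data.shape[b])
    pads = [(0, 0)] * data.ndim
    pads[a] = (0, size - data.shape[a])
    pads[b] = (0, size - data.shape[b])
    if any(p != (0, 0) for p in pads):
        return np.pad(data, pads), pads
    return data, pads


def tta_predict(model, vol: Volume3D, cfg: InferenceConfig) -> ProbabilityMap:
    """Rotation test-time augmentation in the in-plane (axial) axes.

    Averages the identity pass with each configured rotation (90/180/270
    degrees), un-rotated back to native orientation. With TTA disabled this
    is exactly :func:`sliding_window_predict`. Non-square in-plane shapes are
    padded to square for the quarter-turn rotations and cropped back.
    """
    if not cfg.tta_enabled or not cfg.tta_angles:
        return sliding_window_predict(model, vol, cfg)
    plane = cfg.tta_plane
    padded, pads = _pad_square(vol.data, plane)
    pvol = Volume3D(data=padded, spacing_mm=vol.spacing_mm, origin=vol.origin)
    maps = [sliding_window_predict(model, pvol, cfg).probs]
    prob_plane = (plane[0] + 1, plane[1] + 1)  # class axis in front
    for angle in cfg.tta_angles:
        k = angle // 90
        rot = Volume3D(
            data=np.ascontiguousarray(np.rot90(padded, k, axes=plane)),
            spacing_mm=vol.spacing_mm,
            origin=vol.origin,
        )
        pm = sliding_window_predict(model, rot, cfg)
        maps.append(np.rot90(pm.probs, -k, axes=prob_plane))
    mean = np.mean(maps, axis=0)
    crop = tuple(slice(0, s) for s in vol.data.shape)
    return ProbabilityMap(
        probs=np.ascontiguousarray(mean[(slice(None), *crop)]),
        spacing_mm=vol.spacing_mm,
        origin=vol.origin,
    )


def ensemble_predict(models: list, vol: Volume3D, cfg: InferenceConfig) -> ProbabilityMap:
    """Unweighted mean of per-member probability maps (members may use TTA)."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    maps = [tta_predict(m, vol, cfg) for m in models]
    classes = {m.num_classes for m in maps}
    if len(classes) > 1:
        raise ValueError(f"ensemble members disagree on class count: {sorted(classes)}")
    if len(maps) == 1:
        return maps[0]
    return ProbabilityMap(
        probs=np.mean([m.probs for m in maps], axis=0),
        spacing_mm=vol.spacing_mm,
        origin=vol.origin,
    )


def binarize_and_filter(prob: ProbabilityMap, cfg: InferenceConfig) -> Mask3D:
    """Argmax labeling followed by small-component removal.

    Foreground connected components (26-connectivity by default) with fewer
    than ``min_component_voxels`` voxels are deleted; an empty result is
    legal (small lesions may vanish entirely). Idempotent by construction.
    """
    labels = (np.argmax(prob.probs, axis=0) == 1).astype(np.uint8)
    labels = remove_small_components(labels, cfg.min_component_voxels, cfg.connectivity)
    return Mask3D(labels=labels, spacing_mm=prob.spacing_mm, origin=prob.origin)
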