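"""Model/Results objects tying the pipeline together.

:class:`SegmentationModel` is constructed from a cohort manifest plus the
architecture/training/preprocessing configurations (statsmodels-style);
``fit()`` runs the patch-based Adam training loop and returns a
:class:`TrainingResult` carrying the trained network, its checkpoints, the
loss history and a ``summary()`` table. Whole-volume prediction (with
optional TTA and checkpoint ensembling) hangs off the result object.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import InferenceConfig, ProbabilityMap, binarize_and_filter, ensemble_predict, tta_predict
from .io import CohortManifest
from .nn.losses import LossConfig, combined_loss_with_grad
from .nn.optim import Adam
from .nn.resunet import NetworkSpec, ResUNet, build_network
from .preprocess import (
    AugmentConfig,
    NormalizationParams,
    PatchConfig,
    augment_patch,
    clamp_normalize,
    compute_target_spacing,
    resample_volume,
    sample_patches,
)
from .volume import Mask3D, Volume3D, validate_pair

__all__ = ["TrainConfig", "Checkpoint", "SegmentationModel", "TrainingResult", "train_model"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 2
    max_iterations: int = 300
    checkpoint_every: int = 100
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class Checkpoint:
    """Serialized network parameters with their architecture and provenance."""

    arrays: list[np.ndarray]
    spec: NetworkSpec
    iteration: int
    config_hash: str

    def to_network(self, seed: int = 0) -> ResUNet:
        net = build_network(self.spec, seed=seed)
        net.load_state_arrays(self.arrays)
        return net

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = json.dumps(
            {"spec": asdict(self.spec), "iteration": self.iteration, "config_hash": self.config_hash}
        )
        np.savez_compressed(
            path, meta=np.array(meta), **{f"p{i:04d}": a for i, a in enumerate(self.arrays)}
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            keys = sorted(k for k in data.files if k.startswith("p"))
            arrays = [data[k] for k in keys]
        return cls(
            arrays=arrays,
            spec=NetworkSpec(**meta["spec"]),
            iteration=meta["iteration"],
            config_hash=meta["config_hash"],
        )


def _config_hash(*cfgs) -> str:
    blob = json.dumps([asdict(c) for c in cfgs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _resample_mask_to_shape(mask: Mask3D, shape, spacing, origin) -> Mask3D:
    """Nearest-neighbour resample of a mask onto an explicit target grid."""
    if mask.shape == tuple(shape):
        return Mask3D(labels=mask.labels, spacing_mm=spacing, origin=origin)
    from scipy import ndimage

    factors = np.array(shape) / np.array(mask.shape)
    out = ndimage.zoom(mask.labels.astype(np.float32), factors, order=0, mode="nearest", grid_mode=True)
    return Mask3D(labels=np.rint(out).astype(np.uint8), spacing_mm=spacing, origin=origin)


class SegmentationModel:
    """Res-UNet lesion segmentation fitted to a cohort of image/mask pairs.

    Parameters mirror the pipeline stages: ``net_spec`` the architecture,
    ``train_cfg`` the optimization schedule, ``patch_cfg`` the balanced patch
    sampler, ``augment_cfg`` the training-time augmentation, ``norm_params``
    the percentile-clamp normalization. The cohort target spacing defaults
    to the manifest's mean spacing.
    """

    def __init__(
        self,
        manifest: CohortManifest,
        net_spec: NetworkSpec | None = None,
        train_cfg: TrainConfig | None = None,
        patch_cfg: PatchConfig | None = None,
        augment_cfg: AugmentConfig | None = None,
        loss_cfg: LossConfig | None = None,
        norm_params: NormalizationParams | None = None,
        target_spacing=None,
    ):
        if len(manifest) == 0:
            raise ValueError("cannot train on an empty manifest")
        self.manifest = manifest
        self.net_spec = net_spec or NetworkSpec()
        self.train_cfg = train_cfg or TrainConfig()
        self.patch_cfg = patch_cfg or PatchConfig()
        self.augment_cfg = augment_cfg if augment_cfg is not None else AugmentConfig()
        self.loss_cfg = loss_cfg or LossConfig()
        self.norm_params = norm_params or NormalizationParams()
        self.net_spec.check_patch_size(self.patch_cfg.patch_size)
        self._target_spacing = (
            np.asarray(target_spacing, dtype=float) if target_spacing is not None else None
        )
        self._cases: list[tuple[str, Volume3D, Mask3D]] | None = None

    @classmethod
    def from_manifest(cls, path: str | Path, **kwargs) -> "SegmentationModel":
        return cls(CohortManifest.from_csv(path), **kwargs)

    @property
    def target_spacing(self) -> np.ndarray:
        if self._target_spacing is None:
            self._target_spacing = compute_target_spacing(self.manifest)
        return self._target_spacing

    def prepare_volume(self, vol: Volume3D) -> Volume3D:
        """Respace to the cohort target spacing, then clamp-normalize."""
        vol = resample_volume(vol, self.target_spacing, mode="continuous")
        vol, _ = clamp_normalize(vol, self.norm_params)
        return vol

    def _load_cases(self) -> list[tuple[str, Volume3D, Mask3D]]:
        if self._cases is None:
            from .io import read_mask, read_volume

            cases = []
            for row in self.manifest:
                vol = read_volume(row["image_path"])
                mask = read_mask(row["mask_path"])
                validate_pair(vol, mask)
                vol = self.prepare_volume(vol)
                mask = resample_volume(mask, self.target_spacing, mode="nearest")
                cases.append((str(row["case_id"]), vol, mask))
            self._cases = cases
        return self._cases

    def fit(self, checkpoint_dir: str | Path | None = None, verbose: bool = False) -> "TrainingResult":
        """Run the patch-based training loop; reproducible under the seed."""
        cfg = self.train_cfg
        cases = self._load_cases()
        net = build_network(self.net_spec, seed=cfg.seed)
        optimizer = Adam(net.params(), lr=cfg.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7A1]))
        cfg_hash = _config_hash(self.net_spec, cfg, self.patch_cfg, self.augment_cfg, self.loss_cfg)

        one_patch = PatchConfig(
            patch_size=self.patch_cfg.patch_size,
            fg_center_prob=self.patch_cfg.fg_center_prob,
            samples_per_volume=1,
        )
        history = []
        checkpoints: list[Checkpoint] = []
        ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
        if ckpt_dir:
            ckpt_dir.mkdir(parents=True, exist_ok=True)

        for it in range(1, cfg.max_iterations + 1):
            xs, ys = [], []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # background-only cases already warned at load
                for _ in range(cfg.batch_size):
                    cid, vol, mask = cases[rng.integers(len(cases))]
                    (sample,) = sample_patches(vol, mask, one_patch, rng, source_case_id=cid)
                    sample = augment_patch(sample, self.augment_cfg, rng)
                    xs.append(sample.image_patch)
                    ys.append(sample.label_patch)
            x = np.stack(xs)[:, None].astype(np.float32)
            y = np.stack(ys).astype(np.uint8)
            scores = net.forward(x)
            loss, grad, parts = combined_loss_with_grad(scores, y, self.loss_cfg)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at iteration {it}: dice={parts['dice_loss']}, "
                    f"ce={parts['ce_loss']}; check learning rate and input scaling"
                )
            optimizer.zero_grad()
            net.backward(grad)
            optimizer.step()
            history.append(
                {"iteration": it, "loss": loss, "dice_loss": parts["dice_loss"], "ce_loss": parts["ce_loss"]}
            )
            if verbose and it % 10 == 0:
                print(f"iter {it:5d}  loss {loss:.4f}  dice {parts['dice_loss']:.4f}  ce {parts['ce_loss']:.4f}")
            if it % cfg.checkpoint_every == 0 or it == cfg.max_iterations:
                ck = Checkpoint(net.state_arrays(), self.net_spec, it, cfg_hash)
                checkpoints.append(ck)
                if ckpt_dir:
                    ck.save(ckpt_dir / f"checkpoint_{it:06d}.npz")

        hist = pd.DataFrame(history)
        if ckpt_dir:
            hist.to_csv(ckpt_dir / "training_log.csv", index=False)
        return TrainingResult(model=self, network=net, checkpoints=checkpoints, history=hist)


@dataclass
class TrainingResult:
    """Fitted segmentation network plus its training trajectory."""

    model: SegmentationModel
    network: ResUNet
    checkpoints: list[Checkpoint]
    history: pd.DataFrame
    _networks_cache: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        h = self.history
        spec = self.model.net_spec
        first = h["loss"].head(10).mean()
        last = h["loss"].tail(10).mean()
        lines = [
            "Res-UNet segmentation fit",
            "=" * 40,
            f"cases:                {len(self.model.manifest)}",
            f"depth / base chans:   {spec.depth} / {spec.base_channels}",
            f"parameters:           {self.network.n_parameters()}",
            f"patch size:           {tuple(self.model.patch_cfg.patch_size)}",
            f"iterations:           {len(h)}",
            f"batch size:           {self.model.train_cfg.batch_size}",
            f"learning rate:        {self.model.train_cfg.learning_rate}",
            f"first-10 mean loss:   {first:.4f}",
            f"final-10 mean loss:   {last:.4f}",
            f"final dice / ce:      {h['dice_loss'].iloc[-1]:.4f} / {h['ce_loss'].iloc[-1]:.4f}",
            f"checkpoints:          {[c.iteration for c in self.checkpoints]}",
        ]
        return "\n".join(lines)

    def member_networks(self, last_k: int | None = None) -> list[ResUNet]:
        cks = self.checkpoints if last_k is None else self.checkpoints[-last_k:]
        nets = []
        for ck in cks:
            key = ck.iteration
            if key not in self._networks_cache:
                self._networks_cache[key] = ck.to_network()
            nets.append(self._networks_cache[key])
        return nets

    def predict_probabilities(
        self, vol: Volume3D, cfg: InferenceConfig | None = None, ensemble_last_k: int | None = None
    ) -> ProbabilityMap:
        cfg = cfg or InferenceConfig(patch_size=self.model.patch_cfg.patch_size)
        prepared = self.model.prepare_volume(vol)
        if ensemble_last_k is not None and ensemble_last_k > 1:
            return ensemble_predict(self.member_networks(ensemble_last_k), prepared, cfg)
        return tta_predict(self.network, prepared, cfg)

    def predict_mask(
        self, vol: Volume3D, cfg: InferenceConfig | None = None, ensemble_last_k: int | None = None
    ) -> Mask3D:
        """Segment a native-spacing volume; the mask is returned on its grid."""
        cfg = cfg or InferenceConfig(patch_size=self.model.patch_cfg.patch_size)
        pm = self.predict_probabilities(vol, cfg, ensemble_last_k)
        mask = binarize_and_filter(pm, cfg)
        return _resample_mask_to_shape(mask, vol.shape, vol.spacing_mm, vol.origin)


def train_model(
    manifest: CohortManifest,
    net_spec: NetworkSpec | None = None,
    train_cfg: TrainConfig | None = None,
    patch_cfg: PatchConfig | None = None,
    augment_cfg: AugmentConfig | None = None,
    loss_cfg: LossConfig | None = None,
    checkpoint_dir: str | Path | None = None,
) -> TrainingResult:
    """Functional wrapper: build a :class:`SegmentationModel` and fit it."""
    model = SegmentationModel(
        manifest,
        net_spec=net_spec,
        train_cfg=train_cfg,
        patch_cfg=patch_cfg,
        augment_cfg=augment_cfg,
        loss_cfg=loss_cfg,
    )
    return model.fit(checkpoint_dir=checkpoint_dir)
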