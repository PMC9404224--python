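"""Declarative YAML pipeline configuration.

One YAML file drives every stage. Section names mirror the pipeline:
``simulate``, ``preprocess``, ``augment``, ``network``, ``train``, ``infer``,
``quantify``, ``evaluate`` plus a global ``seed`` and ``output_root``.
Unknown keys are rejected by name; cross-field constraints (patch size vs
network depth) are enforced at load time. Every run writes its resolved
configuration, the package version and the seed next to its outputs so
artifact directories are self-describing.

The global seed fans out deterministically to per-stage seeds (a hash of
seed and stage name), so stages are individually reproducible without
reusing one RNG stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inference import InferenceConfig
from .model import TrainConfig
from .nn.losses import LossConfig
from .nn.resunet import NetworkSpec
from .preprocess import AugmentConfig, NormalizationParams, PatchConfig

__all__ = ["SimulateConfig", "QuantifyConfig", "EvaluateConfig", "PipelineConfig",
           "load_config", "dump_config", "stage_seed"]


@dataclass(frozen=True)
class SimulateConfig:
    n: int = 10
    stage_mix: tuple[float, float, float] = (0.5, 0.4, 0.1)
    core_fraction: float = 0.0
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 1.1)
    noise_sd: float = 20.0


@dataclass(frozen=True)
class QuantifyConfig:
    min_component_voxels: int = 30
    otsu_bins: int = 128
    cystic: bool = False
    staging_feature: str = "maximal_diameter_mm"


@dataclass(frozen=True)
class EvaluateConfig:
    staging_feature: str = "maximal_diameter_mm"


@dataclass(frozen=True)
class PreprocessConfig:
    lower_pct: float = 0.5
    upper_pct: float = 99.5
    patch_size: tuple[int, int, int] = (96, 96, 96)
    fg_center_prob: float = 0.5
    samples_per_volume: int = 4

    def normalization(self) -> NormalizationParams:
        return NormalizationParams(lower_pct=self.lower_pct, upper_pct=self.upper_pct)

    def patches(self) -> PatchConfig:
        return PatchConfig(
            patch_size=self.patch_size,
            fg_center_prob=self.fg_center_prob,
            samples_per_volume=self.samples_per_volume,
        )


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_root: str = "runs"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    infer: InferenceConfig = field(default_factory=InferenceConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def __post_init__(self):
        # cross-field checks
        self.network.check_patch_size(self.preprocess.patch_size)
        self.network.check_patch_size(self.infer.patch_size)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    kwargs = {}
    for key, value in data.items():
        f = fields[key]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)
        ):
            target = f.default_factory if f.default_factory is not dataclasses.MISSING else f.type
            if not isinstance(value, dict):
                raise ValueError(f"config key '{path}.{key}' must be a mapping")
            kwargs[key] = _build(target, value, f"{path}.{key}")
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config under '{path}': {exc}") from exc


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; an empty file means defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return _build(PipelineConfig, raw, "pipeline")


def dump_config(cfg: PipelineConfig, path: str | Path | None = None) -> str:
    """Serialize the resolved config to canonical YAML (round-trip stable)."""
    text = yaml.safe_dump(
        json.loads(json.dumps(dataclasses.asdict(cfg), default=list)), sort_keys=True
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def write_run_metadata(out_dir: str | Path, cfg: PipelineConfig, stage: str) -> None:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out_dir / "resolved_config.yaml")
    (out_dir / "run_info.json").write_text(
        json.dumps({"package_version": __version__, "stage": stage, "seed": cfg.seed}, indent=2)
    )
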