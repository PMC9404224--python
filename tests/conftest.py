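"""Shared fixtures: small phantoms, a quickly trained toy model, and the
scaled-down training study (40 train / 10 held-out phantoms, depth-3 Res-UNet)
used by the acceptance tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import breastseg as bs
from breastseg.inference import InferenceConfig, binarize_and_filter, ensemble_predict, tta_predict
from breastseg.model import SegmentationModel, TrainConfig
from breastseg.nn import NetworkSpec
from breastseg.preprocess import AugmentConfig, PatchConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sphere_spec():
    """Digitized sphere, r = 10 mm, isotropic 1 mm spacing, no noise."""
    return bs.PhantomSpec(
        grid_shape=(40, 40, 40),
        spacing_mm=(1.0, 1.0, 1.0),
        semi_axes_mm=(10.0, 10.0, 10.0),
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def toy_training(tmp_path_factory):
    """A small but genuinely trained model for inference behaviour tests.

    3 phantoms on a 48^3 grid, depth-2/base-4 network, 32^3 patches,
    80 iterations: enough to localize the lesion (DSC well above chance)
    while staying fast.
    """
    root = tmp_path_factory.mktemp("toy")
    manifest = bs.generate_cohort(
        n=3, stage_mix=(1.0, 0.0, 0.0), seed=5, out_dir=root, grid_shape=(48, 48, 48)
    )
    model = SegmentationModel(
        manifest,
        net_spec=NetworkSpec(depth=2, base_channels=4),
        train_cfg=TrainConfig(max_iterations=80, checkpoint_every=40, seed=1),
        patch_cfg=PatchConfig(patch_size=(32, 32, 32), samples_per_volume=1),
        augment_cfg=AugmentConfig.disabled(),
    )
    result = model.fit()
    return manifest, result


@pytest.fixture(scope="session")
def scaled_study(tmp_path_factory):
    """The scaled-down segmentation study: train on 40 phantoms, hold out 10.

    Depth-3/base-8 Res-UNet, 48^3 patches (whole-volume windows), 300 Adam
    iterations at a fixed seed; checkpoints at 100/200/300 iterations form
    the ensemble members. Returns held-out mean DSC for the plain, TTA,
    per-member and ensemble predictions.
    """
    root = tmp_path_factory.mktemp("study")
    train_man = bs.generate_cohort(
        n=40, stage_mix=(1.0, 0.0, 0.0), seed=101, out_dir=root / "train",
        grid_shape=(48, 48, 48),
    )
    test_man = bs.generate_cohort(
        n=10, stage_mix=(1.0, 0.0, 0.0), seed=202, out_dir=root / "test",
        grid_shape=(48, 48, 48),
    )
    model = SegmentationModel(
        train_man,
        net_spec=NetworkSpec(depth=3, base_channels=8),
        train_cfg=TrainConfig(max_iterations=300, checkpoint_every=100, seed=7),
        patch_cfg=PatchConfig(patch_size=(48, 48, 48), samples_per_volume=1),
    )
    result = model.fit()

    plain_cfg = InferenceConfig(patch_size=(48, 48, 48), tta_enabled=False)
    tta_cfg = InferenceConfig(patch_size=(48, 48, 48), tta_enabled=True)

    members = result.member_networks()
    dscs = {"plain": [], "tta": [], "ensemble": []}
    member_dscs = [[] for _ in members]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row in test_man:
            vol = bs.read_volume(row["image_path"])
            gt = bs.read_mask(row["mask_path"])
            prepared = model.prepare_volume(vol)
            for key, pm in (
                ("plain", tta_predict(result.network, prepared, plain_cfg)),
                ("tta", tta_predict(result.network, prepared, tta_cfg)),
                ("ensemble", ensemble_predict(members, prepared, plain_cfg)),
            ):
                dscs[key].append(bs.dsc(binarize_and_filter(pm, plain_cfg), gt))
            for i, net in enumerate(members):
                pm = tta_predict(net, prepared, plain_cfg)
                member_dscs[i].append(bs.dsc(binarize_and_filter(pm, plain_cfg), gt))
    return {
        "result": result,
        "train_manifest": train_man,
        "test_manifest": test_man,
        "mean_dsc": float(np.mean(dscs["plain"])),
        "mean_dsc_tta": float(np.mean(dscs["tta"])),
        "mean_dsc_ensemble": float(np.mean(dscs["ensemble"])),
        "member_mean_dscs": [float(np.mean(d)) for d in member_dscs],
    }
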