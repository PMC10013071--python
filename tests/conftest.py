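"""Shared fixtures: synthetic scene sets and trained models.

Training fixtures are session-scoped so the (CPU-minutes) cost of fitting
the segmenters and classifiers is paid once. Scene sets use a 512x512
canvas with segmentation at 128 px (split skin) / 256 px (esophagus),
preserving the 4x segmentation-to-classification scale ratio of the
full-resolution configuration.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from iifseg.eso import EsoNetConfig, train_eso_classifier
from iifseg.segmentation import SegModelConfig, train_segmenter
from iifseg.sss import PatchNetConfig, train_patch_net
from iifseg.synthetic import GenConfig, render_scenes
from iifseg.training import build_eso_dataset, build_sss_patch_dataset

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

CANVAS = (512, 512)


def _scenes(substrate: str, counts: dict[str, int], seed: int):
    cfg = GenConfig(substrate=substrate, counts=counts, output_size=CANVAS,
                    seed=seed)
    return [(img, gt) for _, img, gt in render_scenes(cfg)]


# -- split skin --------------------------------------------------------------


@pytest.fixture(scope="session")
def sss_train_scenes():
    return _scenes("split_skin", {"none": 16, "epidermal": 12, "dermal": 12}, 11)


@pytest.fixture(scope="session")
def sss_test_scenes():
    return _scenes("split_skin", {"none": 4, "epidermal": 3, "dermal": 3}, 99)


@pytest.fixture(scope="session")
def sss_seg_model(sss_train_scenes):
    return train_segmenter(sss_train_scenes,
                           SegModelConfig(substrate="split_skin",
                                          working_size=128, epochs=10, seed=1))


@pytest.fixture(scope="session")
def roof_model(sss_train_scenes):
    patches = build_sss_patch_dataset(sss_train_scenes, "roof", seed=5)
    return train_patch_net(patches, "roof", PatchNetConfig(epochs=40, seed=2))


@pytest.fixture(scope="session")
def floor_model(sss_train_scenes):
    patches = build_sss_patch_dataset(sss_train_scenes, "floor", seed=6)
    return train_patch_net(patches, "floor", PatchNetConfig(epochs=40, seed=3))


# -- esophagus ---------------------------------------------------------------


@pytest.fixture(scope="session")
def eso_train_scenes():
    return _scenes("esophagus", {"none": 14, "BMZ": 11, "intercellular": 11}, 21)


@pytest.fixture(scope="session")
def eso_test_scenes():
    return _scenes("esophagus", {"none": 4, "BMZ": 3, "intercellular": 3}, 77)


@pytest.fixture(scope="session")
def eso_seg_model(eso_train_scenes):
    return train_segmenter(eso_train_scenes,
                           SegModelConfig(substrate="esophagus",
                                          working_size=256, epochs=10, seed=1,
                                          pixels_per_image=3500))


@pytest.fixture(scope="session")
def eso_model(eso_train_scenes, eso_seg_model):
    return train_eso_classifier(build_eso_dataset(eso_train_scenes),
                                eso_seg_model,
                                EsoNetConfig(cls_size=512, epochs=80, seed=2))


# -- tiny helpers ------------------------------------------------------------


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
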