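"""Shared fixtures: small lip images and the full synthetic study run.

The expensive end-to-end product (segment + extract over the default
257-image fixture set, with hybrid and Otsu-only Dice scores) is computed
once per session and shared by the acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from lipdx.colorspace import color_planes
from lipdx.features import extract_all
from lipdx.segmentation import (
    dice,
    mean_shift_smooth,
    otsu_threshold,
    segment_lip,
)
from lipdx.synthetic import FixtureConfig, make_dataset, make_lip_image


@pytest.fixture(scope="session")
def fixture_config() -> FixtureConfig:
    return FixtureConfig(seed=7)


@pytest.fixture(scope="session")
def one_lip(fixture_config):
    """A single Deep-red lip image with its ground-truth mask."""
    rng = np.random.default_rng(42)
    img, mask, info = make_lip_image(fixture_config, "Deep-red", rng)
    return img, mask, info


@pytest.fixture(scope="session")
def pipeline_products(fixture_config):
    """Full study run on the default 257-image fixture set.

    Returns a dict with the feature matrix, labels, and per-image Dice of
    the hybrid segmenter and of the Otsu-only initialization.
    """
    images, masks, labels = make_dataset(fixture_config)
    X, dice_hybrid, dice_otsu = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for img, gt in zip(images, masks):
            m = segment_lip(img)
            smoothed = mean_shift_smooth(img)
            _, om = otsu_threshold(color_planes(smoothed)["Cr"])
            dice_hybrid.append(dice(m, gt))
            dice_otsu.append(dice(om, gt))
            X.append(extract_all(img, m).values)
    return {
        "X": np.asarray(X),
        "y": np.asarray(labels, dtype=object),
        "dice_hybrid": np.asarray(dice_hybrid),
        "dice_otsu": np.asarray(dice_otsu),
    }
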