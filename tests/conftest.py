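"""Shared fixtures: phantom geometries and pre-built shape models.

Expensive artefacts (shape families, optimized particle systems) are
session-scoped so the whole suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from shapepost import (BinaryMask, LabelVolume, build_shape_model,
                       generate_shape_family, optimize_correspondences)
from shapepost.phantoms import PhantomSpec


def ball_mask(radius: float, shape=(40, 40, 40), center=None,
              spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    if center is None:
        center = [(s - 1) / 2.0 for s in shape]
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((c - cc) ** 2 for c, cc in zip(coords, center))
    return BinaryMask(d2 <= radius ** 2, spacing=spacing)


def cube_mask(side: int, pad: int = 2) -> BinaryMask:
    return BinaryMask(np.pad(np.ones((side,) * 3, bool), pad))


@pytest.fixture(scope="session")
def sphere8() -> BinaryMask:
    return ball_mask(8.0)


@pytest.fixture(scope="session")
def bent_tube() -> BinaryMask:
    spec = PhantomSpec(n_subjects=1, volume_shape=(48, 48, 64), base_radius=7,
                       variability=1.0, bend_amplitude=2.0, seed=7)
    return generate_shape_family(spec)[0]


@pytest.fixture(scope="session")
def radius_family():
    """10-member family varying only in the uniform radius offset."""
    spec = PhantomSpec(n_subjects=10, volume_shape=(48, 48, 64), base_radius=7,
                       variability=2.0, bend_amplitude=0.0, harmonics=(0,),
                       seed=3)
    masks, params = generate_shape_family(spec, return_params=True)
    return masks, params[:, 0]


@pytest.fixture(scope="session")
def radius_family_model(radius_family):
    """Optimized correspondences + PCA model for the radius family."""
    masks, params = radius_family
    ps, trace = optimize_correspondences(masks, m=64, iterations=80, seed=0)
    model = build_shape_model(ps)
    return ps, trace, model


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_label_volume(rng, shape=(8, 8, 8), n_labels=3) -> LabelVolume:
    return LabelVolume(rng.integers(0, n_labels + 1, size=shape).astype(np.int16))
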