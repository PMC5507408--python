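"""Shared fixtures: phantoms and registration products are expensive, so
they are built once per session and reused across test modules."""

import numpy as np
import pytest

from microval.io import GreyVolume
from microval.phantom import PhantomSpec, generate_phantom
from microval.segmentation import build_mask


@pytest.fixture(scope="session")
def phantom64():
    """Default 64-cube vertebral phantom: (grey, bone ground truth, labels)."""
    return generate_phantom(PhantomSpec(dims=(64, 64, 64), seed=1))


@pytest.fixture(scope="session")
def phantom64_mask(phantom64):
    grey, _, _ = phantom64
    lo, hi = float(grey.data.min()), float(grey.data.max())
    return build_mask(grey, lo + 0.25 * (hi - lo), 2)


@pytest.fixture(scope="session")
def phantom48():
    """Smaller phantom for segmentation-level tests."""
    return generate_phantom(PhantomSpec(dims=(48, 48, 48), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def noisy(vol: GreyVolume, sigma: float, seed: int) -> GreyVolume:
    """Independent Gaussian-noise rendering of a volume."""
    r = np.random.default_rng(seed)
    return GreyVolume(vol.data + r.normal(0.0, sigma, vol.data.shape), vol.voxel_size, vol.name)
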