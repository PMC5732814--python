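import numpy as np
import pandas as pd
import pytest

from radsurv.imaging import ImageVolume, QuantizedROI, ROIMask
from radsurv.simulate import SimulationConfig, simulate_cohort


def random_quantized(rng: np.random.Generator, shape=(5, 5, 5), ng=4, p_mask=0.7) -> QuantizedROI:
    """A random small quantized ROI with a random (non-empty) mask."""
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    data = np.zeros(shape, dtype=np.int32)
    data[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return QuantizedROI(data=data, n_levels=ng)


def ball_mask(radius: int, spacing=(1.0, 1.0, 1.0)) -> ROIMask:
    """Digitized ball of given voxel radius, padded by 2 voxels."""
    n = 2 * radius + 5
    c = (n - 1) / 2
    g = np.arange(n)
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius**2
    return ROIMask(data=mask, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_cohort() -> pd.DataFrame:
    """Phantom cohort with the default texture-hazard coupling in LCC."""
    return simulate_cohort(SimulationConfig(n_patients=277, seed=1))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Phantom cohort with no texture-hazard coupling (beta absent)."""
    cfg = SimulationConfig(n_patients=300, seed=7, effect=None)
    return simulate_cohort(cfg)


def toy_volume(data, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing)
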