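import numpy as np
import pytest

from plantseg3d.cloud import LabeledPointCloud
from plantseg3d.network import NetworkConfig, SegmentationNetwork
from plantseg3d.plantgen import PlantSpec, generate_plant


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_config():
    """Narrow network for fast forward/backward in tests."""
    return NetworkConfig(n_points=512, level_points=(128, 64, 32, 16),
                         level_channels=(16, 32, 64, 128), fused_channels=32)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest legal pyramid, for gradient checks on ~20-point clouds."""
    return NetworkConfig(n_points=20, level_points=(10, 6, 4, 2),
                         level_channels=(6, 6, 6, 6), fused_channels=6,
                         k_schedule=(3, 3, 2, 2))


@pytest.fixture(scope="session")
def tiny_network(tiny_config):
    return SegmentationNetwork(tiny_config, seed=7)


@pytest.fixture(scope="session")
def broadleaf_plant():
    return generate_plant(PlantSpec(species="broadleaf", n_leaves=5,
                                    points_per_organ=(300, 600), seed=42))


@pytest.fixture(scope="session")
def labeled_cube(rng):
    """1000 uniform points in a unit cube with consistent random labels."""
    coords = rng.uniform(size=(1000, 3))
    ins = rng.integers(0, 4, size=1000)
    sem = ins % 2  # instance-pure by construction
    return LabeledPointCloud(coords, sem_label=sem, ins_label=ins)
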