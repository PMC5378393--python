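import numpy as np
import pytest

from trabmorph.phantoms import DistSpec, RodNetworkSpec, _rasterize_capsules
from trabmorph.volume import BinaryMask

VOXEL = 0.009  # mm, the working resolution of the study design


@pytest.fixture(scope="session")
def small_network():
    """A small but non-trivial rod network with its generative truth."""
    from trabmorph.phantoms import generate_rod_network

    spec = RodNetworkSpec(
        volume_shape=(80, 80, 80),
        voxel_size=VOXEL,
        n_nodes=8,
        mean_degree=4.0,
        length_dist=DistSpec("normal", 30 * VOXEL, 5 * VOXEL),
        radius_dist=DistSpec("normal", 3.5 * VOXEL, 0.5 * VOXEL),
        seed=1234,
    )
    return spec, generate_rod_network(spec, noise_sd=0.0)


def capsule_mask(shape, a, b, r, voxel=VOXEL):
    """Digitized capsule as a BinaryMask; endpoints in voxel coordinates."""
    m = _rasterize_capsules(
        tuple(shape),
        np.asarray([a], dtype=float),
        np.asarray([b], dtype=float),
        np.asarray([r], dtype=float),
    )
    return BinaryMask(data=m, voxel_size=voxel)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
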