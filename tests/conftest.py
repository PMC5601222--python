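import numpy as np
import pytest

import rhizopore as rp


@pytest.fixture(scope="session")
def dexter_volume():
    """Microcosm with a root, hairs and a compaction gradient (k_D = 0.34)."""
    dex = rp.DexterParameters(bulk_porosity=0.22, root_radius=235.0, k_D=0.34)
    cfg = rp.MicrocosmConfig(
        volume_shape=(60, 250, 250),
        voxel_size=8.0,
        root_radius=235.0,
        hair_surface_density=60.0,
        hair_decay_length=250.0,
        compaction=dex,
        seed=0,
    )
    return rp.generate_microcosm(cfg)


@pytest.fixture(scope="session")
def plain_volume():
    """Root-free granular medium used by transport and PSD tests."""
    cfg = rp.MicrocosmConfig(
        volume_shape=(48, 48, 48),
        voxel_size=8.0,
        root_radius=None,
        hair_surface_density=0.0,
        seed=5,
    )
    volume, _ = rp.generate_microcosm(cfg)
    return volume


@pytest.fixture(scope="session")
def dexter_annuli(dexter_volume):
    volume, _ = dexter_volume
    return rp.build_annuli(volume)


def make_tube(radius: float, cross: int, length: int) -> np.ndarray:
    """Axis-aligned cylindrical channel along array axis 0."""
    yy, xx = np.mgrid[0:cross, 0:cross]
    disc = ((yy - (cross - 1) / 2) ** 2 + (xx - (cross - 1) / 2) ** 2) <= radius**2
    return np.broadcast_to(disc, (length, cross, cross)).copy()
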