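import numpy as np
import pytest

from liverroi import PhantomSpec, generate_phantom


def compact_spec(**overrides) -> PhantomSpec:
    """A smaller phantom grid for Monte-Carlo runs; same physical regime."""
    kwargs = dict(
        grid_shape=(112, 128, 40),
        liver_semiaxes_mm=(32.0, 42.0, 40.0),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def default_phantom():
    """The reference ellipsoid phantom at package defaults."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free, vessel-free phantom: every liver voxel equals 60 HU."""
    spec = compact_spec(parenchyma_mu_hu=60.0, noise_sd_hu=0.0, vessel_fraction=0.0, seed=3)
    return generate_phantom(spec)


def brute_force_circle_pixels(radius_mm: float, s0: float, s1: float) -> int:
    """Exhaustive lattice-point count: pixel centers within radius of a lattice point."""
    ni = int(np.ceil(radius_mm / s0))
    nj = int(np.ceil(radius_mm / s1))
    count = 0
    for i in range(-ni, ni + 1):
        for j in range(-nj, nj + 1):
            if (i * s0) ** 2 + (j * s1) ** 2 <= radius_mm ** 2 + 1e-9:
                count += 1
    return count
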