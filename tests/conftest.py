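import numpy as np
import pytest

from periomri import RigidTransform
from periomri.phantom import LesionSpec, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def lesion_phantom():
    """Noisy (SNR 10) phantom with one +6 SD ellipsoidal lesion at baseline."""
    cfg = PhantomConfig(
        lesions_t0=[LesionSpec((20, 20, 15), (5, 5, 5), 6.0)],
        seed=12345,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def null_phantom():
    """Lesion-free noisy phantom on a large grid (>= 1e5 ROI voxels)."""
    cfg = PhantomConfig(grid_shape=(80, 80, 80), seed=54321)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def misaligned_phantom():
    """Noiseless phantom pair misaligned by a known rigid transform."""
    true = RigidTransform.from_euler(
        np.radians([3.0, 0.0, 0.0]), [2.0, -1.0, 1.5], [20.475] * 3
    )
    cfg = PhantomConfig(
        lesions_t0=[LesionSpec((20, 20, 15), (5, 4, 6), 6.0)],
        lesions_t1=[LesionSpec((20, 20, 15), (4, 3, 5), 6.0)],
        true_transform=true,
        noise_sd=0.0,
    )
    return generate_phantom(cfg)
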