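import numpy as np
import pytest

from remicro import kernel as ker
from remicro.constants import GRID_DIM, SIDE_LENGTH_MM

#: the derived production voxel pitch (22 mm / 735)
PITCH_UM = SIDE_LENGTH_MM * 1000.0 / GRID_DIM


@pytest.fixture(scope="session")
def radial_kernel():
    """Synthetic 90Y dose-point kernel (moderate statistics, fixed seed)."""
    return ker.synthetic_radial_kernel(n_histories=100_000, seed=5)


@pytest.fixture(scope="session")
def production_kernel(radial_kernel):
    """Energy-normalized near/far kernel pair at the production pitch."""
    return ker.build_two_scale_kernel(radial_kernel, pitch_um=PITCH_UM,
                                      n_quadrature=2000, seed=7)


@pytest.fixture(scope="session")
def inverse_square_radial():
    r = np.geomspace(1e-4, 50.0, 800)
    return ker.RadialDoseKernel(radii_mm=r, dose_gy_per_decay=1.0 / r ** 2,
                                provenance="synthetic 1/r^2 test kernel")


def small_geometry(grid_dim=100, **kw):
    """Geometry helper: integer-voxel cube at the production pitch."""
    from remicro.deposition import ModelConfig
    return ModelConfig(side_length_mm=grid_dim * PITCH_UM / 1000.0,
                       grid_dim=grid_dim, **kw)
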