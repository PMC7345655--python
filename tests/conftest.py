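"""Shared fixtures: small seeded phantoms and hand-built deformation fields."""

import numpy as np
import pytest

from dvctk.dvc_core import DeformationField
from dvctk.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def speckle_vol():
    """Noiseless 96-cube speckle phantom used across correlation tests."""
    spec = PhantomSpec(
        shape=(96, 96, 96), spacing=(0.53, 0.53, 0.73),
        fiber_count=120, seed=7, noise_snr=None,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_block(speckle_vol):
    """A 32-cube speckle block with healthy texture for subset-level tests."""
    return np.asarray(speckle_vol.data[32:64, 32:64, 32:64], dtype=np.float64)


@pytest.fixture()
def field_factory():
    """Build a DeformationField on a regular grid from a callable u(x_um)."""

    def make(
        grid_shape=(8, 8, 6),
        origin=(16, 16, 16),
        step=(8, 8, 8),
        spacing=(0.5, 0.5, 0.75),
        fn=None,
        valid=None,
    ):
        axes = [
            (origin[a] + step[a] * np.arange(grid_shape[a])) * spacing[a]
            for a in range(3)
        ]
        X = np.meshgrid(*axes, indexing="ij")
        u = np.zeros(tuple(grid_shape) + (3,), dtype=np.float64)
        if fn is not None:
            ux, uy, uz = fn(*X)
            u[..., 0], u[..., 1], u[..., 2] = ux, uy, uz
        if valid is None:
            valid = np.ones(grid_shape, dtype=bool)
        return DeformationField(
            origin=tuple(origin), step=tuple(step), spacing=tuple(spacing),
            u=u, quality=np.ones(grid_shape), valid=valid,
        )

    return make
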