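import numpy as np
import pytest

import episcan as ep


@pytest.fixture(scope="session")
def small_curved_gt():
    """Curved small-cell phantom shared by the read-only pipeline tests."""
    cfg = ep.PhantomConfig(nx=256, ny=256, nz=50, surface_kind="quadratic",
                           tissue_xy_coverage=0.3, cell_diameter=2.5, seed=11)
    return ep.generate(cfg)


@pytest.fixture(scope="session")
def small_curved_estimate(small_curved_gt):
    return ep.estimate_shell(small_curved_gt.volume, eta=0.002, pfa=0.01,
                             epsilon=3.0, seed=12)


def constant_background_model(value: float, sigma: float,
                              shape=(64, 64, 16)) -> ep.NormalizationModel:
    """Hand-built normalization model with a(x,y,z) = value everywhere."""
    coeffs = np.zeros(10)
    coeffs[0] = value
    hi = np.asarray(shape, dtype=float) - 1
    return ep.NormalizationModel(coeffs=coeffs, center=hi / 2,
                                 halfwidth=np.maximum(hi / 2, 1.0),
                                 sigma_hat=sigma)


def flat_shell(nx, ny, nz, plane, epsilon=3.0, dz=0.5) -> ep.Shell:
    surf = ep.SurfaceModel(z=np.full((nx, ny), plane * dz),
                           support=np.ones((nx, ny), dtype=bool))
    return ep.build_shell(surf, epsilon, nz, dz)
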