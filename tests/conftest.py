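import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tristream as ts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_cfg() -> ts.BioOpticalConfig:
    return ts.BioOpticalConfig.ref()


@pytest.fixture(scope="session")
def geom() -> ts.GeometryParams:
    return ts.GeometryParams.from_sun_zenith(30.0)


@pytest.fixture()
def boundary(ref_cfg) -> ts.SurfaceBoundary:
    n = len(ref_cfg.grid)
    return ts.SurfaceBoundary(
        ref_cfg.grid,
        e_dir0=0.7 * np.ones(n),
        e_dif0=0.3 * np.ones(n),
        par=500.0,
        sun_zenith=30.0,
    )


def random_physical_iops(rng, grid):
    """A random but physically admissible bulk-IOP draw for property tests."""
    n = len(grid)
    a = rng.uniform(0.005, 1.0, n)
    b = rng.uniform(0.001, 2.0, n)
    b_b = b * rng.uniform(1e-4, 0.45, n)
    return ts.BulkIOP(grid=grid, a=a, b=b, b_b=b_b)


def random_geometry(rng):
    return ts.GeometryParams(
        cos_theta_d=rng.uniform(0.6, 1.0),
        v_dif=rng.uniform(0.7, 0.95),
        v_u=rng.uniform(0.3, 0.6),
        r_dir=rng.uniform(0.5, 1.5),
        r_dif=rng.uniform(1.0, 2.0),
        r_u=rng.uniform(2.0, 4.0),
        q_factor=rng.uniform(3.0, 5.0),
    )
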