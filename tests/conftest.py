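import numpy as np
import pytest

import rootpore as rp


@pytest.fixture(scope="session")
def spec():
    return rp.ColumnSpec()


@pytest.fixture(scope="session")
def pores(spec):
    return rp.build_pores(spec)


@pytest.fixture(scope="session")
def compact_profile():
    return rp.DEFAULT_PROFILES[("compact_1.6", "combined")]


@pytest.fixture(scope="session")
def loose_profile():
    return rp.DEFAULT_PROFILES[("loose_1.2", "combined")]


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def straight_root(root_id="r", z0=0.0, z1=100.0, x=0.0, y=0.0, radius=0.25,
                  step=1.0):
    z = np.arange(z0, z1 + step / 2, step)
    pts = np.column_stack([np.full_like(z, x), np.full_like(z, y), z])
    return rp.RootPolyline(root_id, pts, radius_mm=radius)
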