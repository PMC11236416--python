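import numpy as np
import pytest

from emdtrack.synthetic_data import generate_probe


@pytest.fixture(scope="session")
def probe96():
    """Single-shank, 96-site (48 rows x 2 columns) probe section."""
    return generate_probe(n_shanks=1, sites_per_shank=96)


@pytest.fixture(scope="session")
def probe384():
    """Four-shank, 384-site default layout."""
    return generate_probe()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def monopole_amplitudes(probe, sites, x, y, z, alpha):
    """Forward 1/R model: amplitude on each site from a source at (x,y,z)."""
    r = np.sqrt((probe.x[sites] - x) ** 2 + (probe.z[sites] - z) ** 2
                + y ** 2)
    return {int(s): float(alpha / ri) for s, ri in zip(sites, r)}
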