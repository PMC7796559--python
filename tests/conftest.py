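import numpy as np
import pytest

from depsikin import exsy, io


@pytest.fixture(scope="session")
def worked_example():
    """Packaged PF1022A EXSY worked example: volumes + network."""
    return io.packaged_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def random_exchange_rate_matrix(rng, r1_scale=5.0, k_scale=0.3):
    """Random valid 3-site rate matrix for the canonical sym/asym topology.

    Nonnegative pathway rates, forbidden B<->C entries exactly zero,
    diagonals carrying outgoing rates plus positive auto-relaxation.
    """
    k_ab, k_ac = rng.uniform(0.02, k_scale, 2)
    k_ba, k_ca = rng.uniform(0.02, k_scale, 2)
    r1 = rng.uniform(0.5, r1_scale, 3)
    L = np.array(
        [
            [-(k_ab + k_ac) - r1[0], k_ba, k_ca],
            [k_ab, -k_ba - r1[1], 0.0],
            [k_ac, 0.0, -k_ca - r1[2]],
        ]
    )
    return L


@pytest.fixture()
def canonical_network():
    return exsy.two_conformer_network(magnetic_fractions={"A": 1.0, "B": 1.5, "C": 1.5})
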