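import numpy as np
import pytest

from flexsas.ensemble import ChainSpec, build_pool
from flexsas.seqtools import sfpq_sequence


@pytest.fixture(scope="session")
def sfpq():
    return sfpq_sequence()


@pytest.fixture(scope="session")
def sfpq_construct():
    return sfpq_sequence(construct=True)


@pytest.fixture(scope="session")
def coil_pool():
    """Shared pool of free 80-residue coil conformers."""
    return build_pool(ChainSpec(length=80), n_conformers=300, seed=7,
                      q_grid=np.linspace(0.008, 0.35, 200))


@pytest.fixture(scope="session")
def recovery_pool():
    """Larger pool used by the ensemble-recovery acceptance checks."""
    return build_pool(ChainSpec(length=80), n_conformers=2000, seed=7,
                      q_grid=np.linspace(0.008, 0.35, 200))
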