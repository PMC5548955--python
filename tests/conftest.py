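import dataclasses

import pytest

from trapshift.synthetic_data import SimConfig, generate


SMALL_SIM = SimConfig(
    n_genes=2000,
    n_pairs=6,
    seed=11,
    n_up=30,
    n_down=10,
    target_size=200,
    n_clans=20,
)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated experiment shared across tests (read-only)."""
    return generate(SMALL_SIM)


@pytest.fixture(scope="session")
def small_null_sim():
    return generate(dataclasses.replace(SMALL_SIM, n_up=0, n_down=0, target_size=0))
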