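import pytest

from scatdiet.reference import builtin_reference
from scatdiet.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def reference():
    return builtin_reference()


@pytest.fixture(scope="session")
def small_sim(reference):
    """A small deterministic synthetic dataset shared across tests."""
    cfg = SimConfig(
        n_bears=8,
        years=(2017, 2018),
        scats_per_bear_per_season={"spring": 1, "summer": 2, "fall": 2},
        seed=11,
    )
    bears, truth, scats = simulate_dataset(cfg, reference)
    return cfg, bears, truth, scats
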