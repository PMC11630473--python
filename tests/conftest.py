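import numpy as np
import pytest

from prophagekit import (
    PlantedElement,
    SimulationConfig,
    simulate_depth_profile,
)


@pytest.fixture(scope="session")
def small_profile():
    """200-kb genome with one planted element and one multi-copy plasmid."""
    cfg = SimulationConfig(
        seed=11,
        contig_lengths=[200_000],
        planted_elements=[PlantedElement("contig_1", 50_000, 60_000, 5.0)],
        plasmids=[(30_000, 4.0)],
    )
    profile, truth = simulate_depth_profile(cfg)
    return cfg, profile, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
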