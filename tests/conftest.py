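import numpy as np
import pytest

from synaptometry import (PairConfig, PopulationConfig, generate_coupled_pairs,
                          generate_population, generate_spine_mesh)


@pytest.fixture(scope="session")
def population():
    """287-spine synthetic population at the default calibration."""
    return generate_population(PopulationConfig(seed=11))


@pytest.fixture(scope="session")
def paired_population(population):
    """Population with 17 planted axon-coupled same-dendrite pairs."""
    pairs, records = generate_coupled_pairs(population, PairConfig(seed=11))
    return pairs, records


@pytest.fixture(scope="session")
def spine_mesh():
    """Toy spine fixture: 0.0655 µm³ sphere head (r=0.25 µm), 0.5 µm neck."""
    head_volume = 4.0 / 3.0 * np.pi * 0.25 ** 3
    return generate_spine_mesh(head_volume=head_volume, neck_length=0.5,
                               neck_diameter=0.12, subdivisions=3)
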