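import numpy as np
import pytest

import pirnakit as pk


@pytest.fixture(scope="session")
def phasing_sim():
    """Default phasing-mode simulation: genome, truth table, alignments."""
    cfg = pk.SimConfig(seed=11, mechanism="phasing")
    genome = pk.generate_genome(cfg)
    truth = pk.simulate_phasing(cfg, genome)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def pingpong_sim():
    cfg = pk.SimConfig(seed=12, mechanism="pingpong")
    genome = pk.generate_genome(cfg)
    truth = pk.simulate_pingpong(cfg, genome)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def sliced_sim():
    cfg = pk.SimConfig(seed=13, mechanism="sliced_phasing")
    genome = pk.generate_genome(cfg)
    truth = pk.simulate_sliced_phasing(cfg, genome)
    return cfg, genome, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_genome(rng, length=2000, name="chrT"):
    return {name: "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])}
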