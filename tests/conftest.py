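import numpy as np
import pytest

from tdsim import fixtures
from tdsim.seqio import Genome


def random_genome(rng: np.random.Generator, length: int, label: str = "g") -> Genome:
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return Genome(label, {"c1": seq})


@pytest.fixture(scope="session")
def element():
    return fixtures.make_element(seed=7)


@pytest.fixture(scope="session")
def population(element):
    """4 samples x 5 loci; locus 1 (site 300 bp away) absent from the last sample."""
    presence = np.ones((5, 4), dtype=int)
    presence[0, 3] = 0
    genomes, truth = fixtures.make_population(
        presence=presence,
        seed=1,
        element=element,
        site_offsets=[300, 450, 620, 800, 1000],
    )
    return genomes, truth
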