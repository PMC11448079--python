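import numpy as np
import pytest
from hypothesis import settings

from mobilome import element_catalog as ec
from mobilome import genome_diff as gd
from mobilome import synthetic_data as sd

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_sim():
    """The 120-kb two-strain fixture used across the suite."""
    return sd.simulate_genome_pair(sd.small_spec(1))


@pytest.fixture(scope="session")
def small_catalogs(small_sim):
    cats = {e.name: e.seq for e in small_sim.library}
    cats[small_sim.spec.mite.name] = small_sim.mite_seq
    return cats


@pytest.fixture(scope="session")
def small_diff(small_sim, small_catalogs):
    return gd.diff_genomes(small_sim.genome_a, small_sim.genome_b, catalogs=small_catalogs)


@pytest.fixture(scope="session")
def small_hits_b(small_sim):
    return ec.dedupe_overlaps(ec.match_library(small_sim.genome_b, small_sim.library))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n, gc=0.42):
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])
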