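import numpy as np
import pytest

from amplifun import (FixtureSpec, assemble_database,
                      generate_reference_fixture)


@pytest.fixture(scope="session")
def three_org_inputs():
    """Hand-written 3-organism reference world: markers identical to genomes,
    copy numbers (1, 2, 4), small disjoint-ish KO repertoires."""
    genomes = {
        "orgA": "ACGTACGTACGTACGTACGT",
        "orgB": "TTTTCCCCGGGGAAAATTTT",
        "orgC": "GAGAGAGATCTCTCTCAAGG",
    }
    markers = {"refA": genomes["orgA"], "refB": genomes["orgB"],
               "refC": genomes["orgC"]}
    ko_counts = {
        "orgA": {"K00001": 3, "K00002": 1},
        "orgB": {"K00002": 2, "K00003": 2},
        "orgC": {"K00003": 1, "K00004": 4, "K00005": 5},
    }
    copy_numbers = {"orgA": 1, "orgB": 2, "orgC": 4}
    return markers, genomes, ko_counts, copy_numbers


@pytest.fixture(scope="session")
def three_org_db(three_org_inputs):
    markers, genomes, ko_counts, copy_numbers = three_org_inputs
    return assemble_database(markers, genomes, ko_counts, copy_numbers,
                             min_identity=0.97)


@pytest.fixture(scope="session")
def ten_org_fixture():
    """Generated 10-organism world with markers identical to genome 16S."""
    return generate_reference_fixture(FixtureSpec(seed=7, mutation_rate=0.0))


@pytest.fixture(scope="session")
def ten_org_db(ten_org_fixture):
    return ten_org_fixture.build_database(min_identity=0.97)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
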