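import os

import pytest
from hypothesis import settings

from graphpress.chemgraph import read_smiles_file
from graphpress.patterns import load_default_registry
from graphpress.synthdata import GenParams, generate_corpus
from graphpress.tensorize import FeatureSchema

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")
FIXTURE_CORPUS = os.path.join(DATA_DIR, "fixture_corpus.smi")
FIXTURE_SEED = 2020  # recorded in the corpus header

# Molecules realizing the two worked compression examples:
# an oxime ether (aza + two ether bridges, two of them overlapping) and a
# methyl-dihydrothiopyran (ethylene + vinylene bridges across one ring).
EXAMPLE_1 = "C=NOC(C)(C)OC"
EXAMPLE_2 = "CC1CCSC=C1"


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def schema(registry):
    return FeatureSchema.for_registry(registry)


@pytest.fixture(scope="session")
def fixture_graphs():
    """The packaged 500-molecule synthetic corpus, parsed."""
    return [g for g, _ in read_smiles_file(FIXTURE_CORPUS, strict=True)]


@pytest.fixture(scope="session")
def small_graphs():
    """300 random molecules of at most 12 heavy atoms (oracle-sized)."""
    params = GenParams(
        n_heavy_atoms=(3, 12),
        pattern_insertion_rate=(0.4, 0.4, 0.4, 0.4, 0.4, 0.4),
        seed=11,
    )
    return [r.graph for r in generate_corpus(300, params)]
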