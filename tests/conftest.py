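import pytest
from hypothesis import settings

from trialsql import default_catalog

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")
from trialsql.synth import SynthVocabSpec, generate_mini_cdm, generate_vocabulary
from trialsql.vocabulary import Concept, ConceptInventory


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def vocab_pair():
    """A 1,000-concept universe with a 100-concept loaded inventory."""
    spec = SynthVocabSpec(universe_size=1000, loaded_fraction=0.1, seed=42)
    return generate_vocabulary(spec)


@pytest.fixture(scope="session")
def universe(vocab_pair):
    return vocab_pair[0]


@pytest.fixture(scope="session")
def loaded(vocab_pair):
    return vocab_pair[1]


@pytest.fixture(scope="session")
def mini_cdm(loaded):
    return generate_mini_cdm(loaded, n_persons=200, seed=7)


@pytest.fixture()
def tiny_inventory():
    """Hand-built inventory: a 3-node Condition chain a->b->c plus one Drug."""
    concepts = {
        101: Concept(101, "diabetes mellitus", "Condition"),
        102: Concept(102, "type 2 diabetes mellitus", "Condition"),
        103: Concept(103, "type 2 diabetes with nephropathy", "Condition"),
        201: Concept(201, "metformin", "Drug"),
    }
    pairs = {(101, 102), (102, 103)}
    return ConceptInventory(concepts=concepts, ancestor_pairs=pairs)
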