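import pytest

from lumigen.graph import parse_structure
from lumigen.model import ModelConfig, train
from lumigen.synthdata import build_database, training_pairs
from lumigen.trajectory import AtomVocabulary


@pytest.fixture(scope="session")
def small_db():
    """A small but structured synthetic property database."""
    return build_database(120, seed=5)


@pytest.fixture(scope="session")
def tiny_model(small_db):
    """A briefly trained model: cheap, but past the uniform-policy stage."""
    return train(training_pairs(small_db), ModelConfig(epochs=2, seed=7))


@pytest.fixture(scope="session")
def basic_vocab():
    mols = [
        parse_structure(s)
        for s in [
            "O=[N+]([O-])c1ccccc1",
            "c1ccncc1",
            "c1cc[nH]c1",
            "c1ccsc1",
            "c1ccoc1",
            "CC(=O)O",
            "FC(F)(F)Cl",
            "C#N",
        ]
    ]
    return AtomVocabulary.from_molecules(mols)
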