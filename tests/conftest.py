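import numpy as np
import pytest

from foldkit import fixtures
from foldkit.bioio import ProteinSequence, SecondaryStructure


@pytest.fixture(scope="session")
def helix30():
    """30-residue ideal helix fixture with one exact template."""
    return fixtures.generate_fixture("helix", 30, perturbation=0.0, seed=11,
                                     n_templates=1)


@pytest.fixture(scope="session")
def noisy_pair():
    """Two mildly perturbed helix templates (high mutual GDT_TS)."""
    return fixtures.generate_fixture("helix", 30, perturbation=0.4, seed=5,
                                     n_templates=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def seq10():
    return ProteinSequence("ACDEFGHIKL")


@pytest.fixture()
def ss_all_c():
    def make(n: int) -> SecondaryStructure:
        return SecondaryStructure("C" * n)
    return make
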