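import pytest

from topodesc import from_smiles
from topodesc.synthetic import GraphRecipe, generate


@pytest.fixture(scope="session")
def ethanol():
    return from_smiles("CCO", name="ethanol")


@pytest.fixture(scope="session")
def benzene():
    return from_smiles("c1ccccc1", name="benzene")


@pytest.fixture(scope="session")
def cyclohexane():
    return from_smiles("C1CCCCC1", name="cyclohexane")


@pytest.fixture(scope="session")
def cyclopentane():
    return from_smiles("C1CCCC1", name="cyclopentane")


@pytest.fixture(scope="session")
def methylbutane():
    """2-methylbutane skeleton: chain 0-1-2-3 with branch 4 on atom 1."""
    return from_smiles("CC(C)CC", name="2-methylbutane")


@pytest.fixture(scope="session")
def isobutane():
    return from_smiles("CC(C)C", name="isobutane")


def skeleton(kind, n, seed=0):
    return generate(GraphRecipe(kind=kind, n=n, seed=seed))


@pytest.fixture(scope="session")
def path4():
    return skeleton("path", 4)


@pytest.fixture(scope="session")
def random_trees():
    return [skeleton("random_tree", 4 + s % 17, seed=s) for s in range(50)]


@pytest.fixture(scope="session")
def random_connected_graphs():
    return [skeleton("random_connected", 4 + s % 9, seed=s) for s in range(100)]
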