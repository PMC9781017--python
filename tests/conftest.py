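import pytest
from rdkit import Chem

from trpv1screen import fixture_molecules


@pytest.fixture(scope="session")
def fixtures():
    return fixture_molecules()


@pytest.fixture(scope="session")
def capsaicin(fixtures):
    return fixtures["capsaicin"]


@pytest.fixture(scope="session")
def amg517(fixtures):
    return fixtures["AMG-517"]


@pytest.fixture(scope="session")
def capsazepine(fixtures):
    return fixtures["capsazepine"]


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    return m
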