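import pytest

from fragrank import BDETable, parse_structure
from fragrank.synthetic import make_toy_library


@pytest.fixture(scope="session")
def bde_table():
    return BDETable.default()


@pytest.fixture(scope="session")
def toy_library():
    return make_toy_library()


@pytest.fixture(scope="session")
def ethanol():
    return parse_structure("CCO")


@pytest.fixture(scope="session")
def propane():
    return parse_structure("CCC")


@pytest.fixture(scope="session")
def benzene():
    return parse_structure("c1ccccc1")


# the five triazines of the worked isobar example, by standard connectivity
TRIAZINE_SMILES = {
    "terbutylazine": "CCNc1nc(Cl)nc(NC(C)(C)C)n1",
    "propazine": "CC(C)Nc1nc(Cl)nc(NC(C)C)n1",
    "secbutylazine": "CCC(C)Nc1nc(Cl)nc(NCC)n1",
    "triethazine": "CCN(CC)c1nc(Cl)nc(NCC)n1",
    "nbutylazine": "CCCCNc1nc(Cl)nc(NCC)n1",
}


@pytest.fixture(scope="session")
def triazines():
    return {k: parse_structure(v) for k, v in TRIAZINE_SMILES.items()}
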