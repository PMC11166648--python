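import numpy as np
import pandas as pd
import pytest

from spaceomics.io import CountMatrix, GeneSetDB
from spaceomics.simulate import MissionDesign


@pytest.fixture(scope="session")
def design() -> MissionDesign:
    return MissionDesign()


@pytest.fixture(scope="session")
def metas(design):
    return design.sample_meta()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture()
def small_db() -> GeneSetDB:
    sets = {
        "PW_A": frozenset({"G1", "G2", "G3"}),
        "PW_B": frozenset({"G4", "G5"}),
    }
    return GeneSetDB(sets=sets, descriptions={k: "" for k in sets})


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    data = pd.DataFrame(
        {
            "s1": [10.0, 30.0, 60.0],
            "s2": [1.0, 1.0, 2.0],
        },
        index=["G1", "G2", "G3"],
    )
    return CountMatrix(data)
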