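import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from qsar3d import QSAR3D, default_scenario


def embed(smiles: str, seed: int = 42) -> Chem.Mol:
    """Deterministic 3D structure from SMILES (test scaffolding only)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    return mol


@pytest.fixture(scope="session")
def scenario60():
    """The documented desk-scale study: 60 compounds, noise sd 0.2."""
    return default_scenario(n_compounds=60)


@pytest.fixture(scope="session")
def fitted60_comsia(scenario60):
    """Five-field CoMSIA pipeline fitted on the 60-compound scenario."""
    model = QSAR3D.from_scenario(scenario60, method="comsia",
                                 run_group_cv=False, run_bootstrap=False)
    return model, model.fit()


@pytest.fixture(scope="session")
def fitted60_comfa(scenario60):
    model = QSAR3D.from_scenario(scenario60, method="comfa",
                                 run_group_cv=False, run_bootstrap=False)
    return model, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
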