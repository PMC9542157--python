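import numpy as np
import pytest

from torsionrl import chem


@pytest.fixture(scope="session")
def pentane():
    """n-pentane MolSpec: 17 atoms, 2 rotatable torsions."""
    return chem.mol_spec_from_smiles("CCCCC")


@pytest.fixture(scope="session")
def butane():
    """n-butane MolSpec: 14 atoms, 1 rotatable torsion."""
    return chem.mol_spec_from_smiles("CCCC")


@pytest.fixture(scope="session")
def pentane_random_conformers(pentane):
    """20 relaxed pentane conformers from seeded uniform torsion starts."""
    rng = np.random.default_rng(11)
    g = pentane.molecule
    confs = []
    for _ in range(20):
        angles = rng.uniform(0.0, 360.0, g.n_torsions)
        confs.append(chem.relax(chem.set_torsions(pentane.reference, g, angles), g))
    return confs
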