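import numpy as np
import pytest

from mdsom.structure_io import AtomRecord, StructureModel
from mdsom.synthetic_data import build_helix_peptide, build_synthetic_complex


def make_model(spec_rows, chain="A"):
    """Build a StructureModel from (name, element, resid, resname, xyz) rows."""
    atoms = [AtomRecord(serial=i + 1, name=n, element=e, residue_index=ri,
                        residue_name=rn, chain_id=chain, coords=xyz)
             for i, (n, e, ri, rn, xyz) in enumerate(spec_rows)]
    return StructureModel(atoms)


@pytest.fixture(scope="session")
def helix12():
    return build_helix_peptide(12)


@pytest.fixture(scope="session")
def reference_complex():
    return build_synthetic_complex()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
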