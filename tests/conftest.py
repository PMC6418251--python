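"""Shared fixtures: small synthetic models and trajectories."""

import numpy as np
import pytest

from epistat.structures import AtomRecord, ResidueKey, StructureModel
from epistat.synthetic_data import make_interface_standin, make_toy_complex


def build_model(residues):
    """Hand-build a StructureModel from {(chain, seq, resname): {atom: xyz}}."""
    model = StructureModel(model_index=1)
    serial = 1
    for (chain, seq, name), atoms in residues.items():
        key = ResidueKey(chain_id=chain, res_seq=seq, i_code="", res_name=name)
        model.residues[key] = [
            AtomRecord(serial=serial + i, name=an, element=an[0], alt_loc="",
                       coords=np.asarray(xyz, float))
            for i, (an, xyz) in enumerate(atoms.items())
        ]
        serial += len(atoms)
    return model


@pytest.fixture(scope="session")
def standin():
    return make_interface_standin()


@pytest.fixture(scope="session")
def planted_toy():
    """Two-chain toy complex with one Lys-Asp pair planted at 3.6 A."""
    return make_toy_complex(6, 6, [(("A", 10, "LYS"), ("B", 20, "ASP"), 3.6)],
                            seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
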