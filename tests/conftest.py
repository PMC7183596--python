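"""Shared geometry fixtures: ideal helix, antiparallel sheet, random coils."""

import numpy as np
import pytest

from poorqa import make_antiparallel_sheet, make_coil, make_helix
from poorqa.structure_io import ProteinModel, Residue


@pytest.fixture(scope="session")
def helix15():
    return make_helix(15)


@pytest.fixture(scope="session")
def sheet():
    return make_antiparallel_sheet(6)


@pytest.fixture(scope="session")
def coil200():
    return make_coil(200, seed=42)


def toy_model(coords_by_residue, names=None, start=1):
    """Build a bare model from {atom: xyz} dicts, one per residue."""
    names = names or ["ALA"] * len(coords_by_residue)
    residues = [
        Residue(number=start + k, name=names[k],
                atoms={a: np.asarray(xyz, dtype=float)
                       for a, xyz in atom_map.items()})
        for k, atom_map in enumerate(coords_by_residue)
    ]
    return ProteinModel(model_id="toy", residues=residues)
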