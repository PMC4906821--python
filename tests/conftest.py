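"""Shared fixtures: hand-written mini-PDB files and toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from tksa.structure import Atom, ProteinStructure, Residue

# Three residues (Asp, Lys, Gly) on one chain, written by hand so every
# coordinate is known exactly.  The Asp carboxylate midpoint is (2, 0, 0).
MINI_PDB = """\
ATOM      1  N   ASP A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ASP A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  OD1 ASP A   1       2.000   1.000   0.000  1.00  0.00           O
ATOM      4  OD2 ASP A   1       2.000  -1.000   0.000  1.00  0.00           O
ATOM      5  CA  LYS A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      6  NZ  LYS A   2       7.000   2.000   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   3       9.000   0.000   0.000  1.00  0.00           C
ATOM      8  O   GLY A   3      10.000   0.000   0.000  1.00  0.00           O
TER
END
"""

# One atom with two alternate locations: A at occupancy 0.6, B at 0.4.
ALTLOC_PDB = """\
ATOM      1  N   ASP A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AASP A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BASP A   1       1.200   0.000   0.000  0.40  0.00           C
ATOM      4  OD1 ASP A   1       2.000   1.000   0.000  1.00  0.00           O
ATOM      5  OD2 ASP A   1       2.000  -1.000   0.000  1.00  0.00           O
ATOM      6  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
TER
END
"""

INSERTION_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   1A      2.000   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


def bare_structure(positions, elements=None, names=None, radii=None) -> ProteinStructure:
    """One single-atom Gly per position; handy for geometric SASA tests."""
    from tksa.constants import VDW_DEFAULT_A, VDW_RADII_A
    positions = np.asarray(positions, dtype=float)
    elements = elements or ["C"] * len(positions)
    names = names or ["CA"] * len(positions)
    if radii is None:
        radii = [VDW_RADII_A.get(e, VDW_DEFAULT_A) for e in elements]
    residues = []
    for i, (pos, elem, name, rad) in enumerate(zip(positions, elements, names, radii)):
        atom = Atom(serial=i + 1, name=name, element=elem, residue_index=i,
                    coordinates=pos, radius=rad)
        residues.append(Residue(chain="A", seq_number=i + 1, name="GLY",
                                atoms=[atom]))
    return ProteinStructure(residues=residues, source_id="bare")
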