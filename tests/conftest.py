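"""Shared fixtures: toy PDB text, one synthetic complex, and its database."""

import numpy as np
import pytest

from pdmsite.pipeline import build_database, load_complex
from pdmsite.structure import AtomRecord, Structure, compute_sasa
from pdmsite.synthetic import SyntheticComplexSpec, make_complex

# hand-written 3-residue peptide (ALA-SER-GLY): 20 heavy atoms
TOY_PDB = """\
ATOM      1  N   ALA A   1      -1.458   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       0.546   1.424   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.653   1.670   0.467  1.00  0.00           O
ATOM      5  CB  ALA A   1       0.434  -0.630   1.325  1.00  0.00           C
ATOM      6  N   SER A   2      -0.278   2.378  -0.585  1.00  0.00           N
ATOM      7  CA  SER A   2       0.130   3.780  -0.661  1.00  0.00           C
ATOM      8  C   SER A   2       0.663   4.213  -2.023  1.00  0.00           C
ATOM      9  O   SER A   2       1.682   3.695  -2.487  1.00  0.00           O
ATOM     10  CB  SER A   2      -1.051   4.666  -0.264  1.00  0.00           C
ATOM     11  OG  SER A   2      -0.688   6.033  -0.377  1.00  0.00           O
ATOM     12  N   GLY A   3      -0.042   5.137  -2.667  1.00  0.00           N
ATOM     13  CA  GLY A   3       0.342   5.656  -3.970  1.00  0.00           C
ATOM     14  C   GLY A   3       1.651   6.424  -3.911  1.00  0.00           C
ATOM     15  O   GLY A   3       2.244   6.602  -2.848  1.00  0.00           O
ATOM     16  N   ALA A   4       2.114   6.898  -5.061  1.00  0.00           N
ATOM     17  CA  ALA A   4       3.355   7.654  -5.166  1.00  0.00           C
ATOM     18  C   ALA A   4       4.547   6.800  -4.760  1.00  0.00           C
ATOM     19  O   ALA A   4       5.546   7.321  -4.265  1.00  0.00           O
ATOM     20  CB  ALA A   4       3.558   8.162  -6.589  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def toy_pdb() -> str:
    return TOY_PDB


@pytest.fixture(scope="session")
def fixture_spec() -> SyntheticComplexSpec:
    return SyntheticComplexSpec(seed=1)


@pytest.fixture(scope="session")
def fixture_pdb(fixture_spec) -> str:
    return make_complex(fixture_spec)


@pytest.fixture(scope="session")
def fixture_complex(fixture_pdb):
    """Parsed synthetic complex: (structure with SASA, ligands, waters)."""
    return load_complex(fixture_pdb)


@pytest.fixture(scope="session")
def fixture_db(fixture_complex):
    return build_database([fixture_complex])


def make_structure(coords, type_ids=None, resseqs=None, names=None,
                   resnames=None, with_sasa=True) -> Structure:
    """Build a bare Structure from coordinates for geometry-level tests."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)
    type_ids = type_ids if type_ids is not None else [8] * n
    resseqs = resseqs if resseqs is not None else list(range(1, n + 1))
    names = names if names is not None else [f"C{i}" for i in range(n)]
    resnames = resnames if resnames is not None else ["ALA"] * n
    atoms = [
        AtomRecord(serial=i + 1, name=names[i], chain="A", resseq=resseqs[i],
                   icode="", resname=resnames[i], coord=coords[i],
                   type_id=type_ids[i], element="C")
        for i in range(n)
    ]
    s = Structure(atoms)
    if with_sasa:
        compute_sasa(s)
    return s
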