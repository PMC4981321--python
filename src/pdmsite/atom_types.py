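"""Atom typing for protein, water and ligand heavy atoms.

The method classifies every heavy atom into one of 53 types: 30 protein
atom types (a chemical-environment partition of the heavy atoms of the 20
standard amino acids), one water oxygen type, and 22 Sybyl-style ligand
atom types.  Each type carries a van der Waals radius used for surface
computation, occupancy masking and contact-shell placement.

The 53-entry table ships as a TSV data file (``data/atom_types.tsv``) so it
can be audited and re-exported; the residue/atom-name partition for the
protein types lives here as an explicit mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable
import warnings

__all__ = [
    "AtomTypeEntry",
    "AtomTypeTable",
    "ProteinAtomType",
    "LigandAtomType",
    "TypingError",
    "load_atom_type_table",
    "type_protein_atom",
    "type_ligand_atom",
    "vdw_radius",
    "STANDARD_RESIDUES",
    "PROTEIN_TYPE_PARTITION",
]


class TypingError(ValueError):
    """Raised when an atom cannot be assigned a type."""


@dataclass(frozen=True)
class AtomTypeEntry:
    id: int
    name: str
    radius: float
    description: str
    atom_class: str  # protein | water | ligand


@dataclass(frozen=True)
class ProteinAtomType:
    id: int
    name: str


@dataclass(frozen=True)
class LigandAtomType:
    id: int
    sybyl_name: str


class AtomTypeTable:
    """The 53-entry atom-type table with id, name, radius, class."""

    def __init__(self, entries: Iterable[AtomTypeEntry]):
        self.entries = sorted(entries, key=lambda e: e.id)
        ids = [e.id for e in self.entries]
        if ids != list(range(1, 54)):
            raise ValueError("atom type table must contain exactly ids 1..53")
        for e in self.entries:
            if e.radius <= 0:
                raise ValueError(f"non-positive radius for type {e.id}")
        expected_class = lambda i: "protein" if i <= 30 else ("water" if i == 31 else "ligand")
        for e in self.entries:
            if e.atom_class != expected_class(e.id):
                raise ValueError(f"type {e.id} has class {e.atom_class!r}")
        self._by_id = {e.id: e for e in self.entries}
        self._by_name = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, type_id: int) -> AtomTypeEntry:
        try:
            return self._by_id[type_id]
        except KeyError:
            raise TypingError(f"unknown atom type id {type_id!r}") from None

    def by_name(self, name: str) -> AtomTypeEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise TypingError(f"unknown atom type name {name!r}") from None

    def radius(self, type_id: int) -> float:
        return self[type_id].radius

    @property
    def radii(self) -> dict[int, float]:
        return {e.id: e.radius for e in self.entries}

    def to_tsv(self) -> str:
        lines = ["id\tname\tradius\tdescription\tclass"]
        for e in self.entries:
            lines.append(f"{e.id}\t{e.name}\t{e.radius:.2f}\t{e.description}\t{e.atom_class}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "AtomTypeTable":
        entries = []
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[:5] != ["id", "name", "radius", "description", "class"]:
            raise ValueError("unexpected atom-type table header")
        for ln in lines[1:]:
            f = ln.split("\t")
            entries.append(AtomTypeEntry(int(f[0]), f[1], float(f[2]), f[3], f[4]))
        return cls(entries)


def load_atom_type_table() -> AtomTypeTable:
    """Load the packaged 53-entry atom type table."""
    text = resources.files("pdmsite.data").joinpath("atom_types.tsv").read_text()
    return AtomTypeTable.from_tsv(text)


_TABLE: AtomTypeTable | None = None


def _table() -> AtomTypeTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = load_atom_type_table()
    return _TABLE


def vdw_radius(type_id: int) -> float:
    """Van der Waals radius (Å) for a type id in 1..53."""
    return _table().radius(type_id)


STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# Residues with a documented mapping onto a standard parent (modified or
# alternative protonation-state names).  Atom renames handle the substituted
# heteroatom where applicable.
NONSTANDARD_PARENT = {
    "MSE": ("MET", {"SE": "SD"}),
    "SEC": ("CYS", {"SE": "SG"}),
    "HID": ("HIS", {}),
    "HIE": ("HIS", {}),
    "HIP": ("HIS", {}),
    "HSD": ("HIS", {}),
    "HSE": ("HIS", {}),
    "HSP": ("HIS", {}),
}

# Backbone heavy atoms common to all residues.  OXT (terminal carboxyl
# oxygen) is typed as backbone O: chemically an equivalent carboxyl oxygen.
_BACKBONE = {"N": 1, "CA": 3, "C": 2, "O": 4, "OXT": 4}

# Side-chain partition.  Type ids follow the chemical-environment classes:
# 5 CH0 (carbonyl/guanidinium C without H), 6 CH1S, 7 CH2E, 8 CH3E,
# 9 CR1E aromatic CH, 10 OH1, 11 OC, 12 OS, 14 CH2P, 15 NH1S, 16 NC2,
# 17 NH2, 18 CR1W, 19 CY2, 20 SC, 21 CF, 22 SM, 23 CY, 24 CW, 25 CRHH,
# 26 NH3, 27 CR1H, 28 C5, 30 C5W.  Gly CA (13) and Pro N (29) override the
# backbone defaults.
_SIDECHAIN: dict[str, dict[str, int]] = {
    "ALA": {"CB": 7},  # row 7 reads "All CB": Ala CB follows the generic CB class
    "ARG": {"CB": 7, "CG": 7, "CD": 7, "NE": 15, "CZ": 5, "NH1": 16, "NH2": 16},
    "ASN": {"CB": 7, "CG": 5, "OD1": 12, "ND2": 17},
    "ASP": {"CB": 7, "CG": 5, "OD1": 11, "OD2": 11},
    "CYS": {"CB": 7, "SG": 20},
    "GLN": {"CB": 7, "CG": 7, "CD": 5, "OE1": 12, "NE2": 17},
    "GLU": {"CB": 7, "CG": 7, "CD": 5, "OE1": 11, "OE2": 11},
    "GLY": {},
    "HIS": {"CB": 7, "CG": 28, "ND1": 15, "CD2": 27, "CE1": 25, "NE2": 15},
    "ILE": {"CB": 6, "CG1": 7, "CG2": 8, "CD1": 8, "CD": 8},
    "LEU": {"CB": 7, "CG": 6, "CD1": 8, "CD2": 8},
    "LYS": {"CB": 7, "CG": 7, "CD": 7, "CE": 7, "NZ": 26},
    "MET": {"CB": 7, "CG": 7, "SD": 22, "CE": 8},
    "PHE": {"CB": 7, "CG": 21, "CD1": 9, "CD2": 9, "CE1": 9, "CE2": 9, "CZ": 9},
    "PRO": {"CB": 14, "CG": 14, "CD": 14},
    "SER": {"CB": 7, "OG": 10},
    "THR": {"CB": 6, "OG1": 10, "CG2": 8},
    "TRP": {
        "CB": 7, "CG": 30, "CD1": 9, "CD2": 24, "NE1": 15, "CE2": 24,
        "CE3": 9, "CZ2": 18, "CZ3": 9, "CH2": 18,
    },
    "TYR": {"CB": 7, "CG": 23, "CD1": 9, "CD2": 9, "CE1": 9, "CE2": 9, "CZ": 19, "OH": 10},
    "VAL": {"CB": 6, "CG1": 8, "CG2": 8},
}

# Full (residue, atom) -> type-id partition, exported for enumeration tests.
PROTEIN_TYPE_PARTITION: dict[tuple[str, str], int] = {}
for _res in STANDARD_RESIDUES:
    for _a, _t in _BACKBONE.items():
        PROTEIN_TYPE_PARTITION[(_res, _a)] = _t
    for _a, _t in _SIDECHAIN[_res].items():
        PROTEIN_TYPE_PARTITION[(_res, _a)] = _t
PROTEIN_TYPE_PARTITION[("GLY", "CA")] = 13
PROTEIN_TYPE_PARTITION[("PRO", "N")] = 29


def type_protein_atom(residue_name: str, atom_name: str) -> ProteinAtomType:
    """Assign the protein atom type (id 1-30) for a heavy atom.

    ``residue_name`` is a 3-letter amino-acid code (nonstandard residues
    with a known standard parent, e.g. MSE, are mapped with a warning);
    ``atom_name`` is the PDB atom name.
    """
    res = residue_name.strip().upper()
    atom = atom_name.strip().upper()
    if res in NONSTANDARD_PARENT:
        parent, renames = NONSTANDARD_PARENT[res]
        warnings.warn(f"mapping nonstandard residue {res} to {parent}", stacklevel=2)
        res, atom = parent, renames.get(atom, atom)
    if res not in STANDARD_RESIDUES:
        raise TypingError(f"unknown residue {residue_name!r}")
    try:
        tid = PROTEIN_TYPE_PARTITION[(res, atom)]
    except KeyError:
        raise TypingError(f"unknown atom {atom_name!r} in residue {residue_name!r}") from None
    return ProteinAtomType(tid, _table()[tid].name)


# --- Sybyl-style ligand typing -------------------------------------------

_HALOGEN = {"F": 51, "Cl": 52, "Br": 53}


def type_ligand_atom(mol, atom_index: int) -> LigandAtomType:
    """Assign a Sybyl-style ligand atom type (id 32-53) to a heavy atom.

    ``mol`` is an RDKit molecule with perceived bonds/aromaticity.  The
    classification follows the standard Sybyl element + hybridization +
    aromaticity rules, restricted to the 22 supported types; elements
    outside the table (metals, Si, I, ...) raise :class:`TypingError`.
    """
    from rdkit import Chem

    atom = mol.GetAtomWithIdx(int(atom_index))
    sym = atom.GetSymbol()
    hyb = atom.GetHybridization()
    name = None
    if sym == "C":
        if _is_guanidinium_carbon(atom):
            name = "C.cat"
        elif atom.GetIsAromatic():
            name = "C.ar"
        elif hyb == Chem.HybridizationType.SP:
            name = "C.1"
        elif hyb == Chem.HybridizationType.SP2:
            name = "C.2"
        else:
            name = "C.3"
    elif sym == "O":
        if _is_carboxylate_or_phosphate_oxygen(atom):
            name = "O.co2"
        elif _has_multiple_bond(atom) or atom.GetIsAromatic():
            name = "O.2"
        else:
            name = "O.3"
    elif sym == "N":
        if _is_amide_nitrogen(atom):
            name = "N.am"
        elif atom.GetIsAromatic():
            name = "N.ar"
        elif hyb == Chem.HybridizationType.SP:
            name = "N.1"
        elif atom.GetFormalCharge() > 0 and not _has_multiple_bond(atom):
            name = "N.4"
        elif hyb == Chem.HybridizationType.SP3:
            name = "N.3"
        elif _has_multiple_bond(atom):
            name = "N.2"
        else:
            # sp2 nitrogen with three single bonds (aniline, guanidine NH2)
            name = "N.pl3"
    elif sym == "S":
        n_oxo = sum(
            1
            for nb in atom.GetNeighbors()
            if nb.GetSymbol() == "O"
            and mol.GetBondBetweenAtoms(atom.GetIdx(), nb.GetIdx()).GetBondType()
            == Chem.BondType.DOUBLE
        )
        if n_oxo >= 2:
            name = "S.O2"
        elif _has_multiple_bond(atom):
            name = "S.2"
        else:
            name = "S.3"
    elif sym == "P":
        name = "P.3"
    elif sym in _HALOGEN:
        name = sym
    if name is None:
        raise TypingError(f"unsupported ligand element {sym!r} at atom {atom_index}")
    entry = _table().by_name(name)
    return LigandAtomType(entry.id, entry.name)


def _has_multiple_bond(atom) -> bool:
    from rdkit import Chem

    return any(
        b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)
        for b in atom.GetBonds()
    )


def _is_guanidinium_carbon(atom) -> bool:
    if atom.GetSymbol() != "C" or atom.GetIsAromatic():
        return False
    nbrs = atom.GetNeighbors()
    n_n = sum(1 for nb in nbrs if nb.GetSymbol() == "N")
    charged = any(nb.GetFormalCharge() > 0 for nb in nbrs) or atom.GetFormalCharge() > 0
    return n_n == 3 and len(nbrs) == 3 and charged


def _is_carboxylate_or_phosphate_oxygen(atom) -> bool:
    # terminal oxygen on a carboxylate carbon or on phosphorus
    if atom.GetDegree() != 1:
        return False
    nb = atom.GetNeighbors()[0]
    if nb.GetSymbol() == "P":
        return True
    if nb.GetSymbol() != "C":
        return False
    term_o = [
        o for o in nb.GetNeighbors() if o.GetSymbol() == "O" and o.GetDegree() == 1
    ]
    if len(term_o) < 2:
        return False
    charged = any(o.GetFormalCharge() < 0 for o in term_o)
    has_double = any(
        nb.GetOwningMol().GetBondBetweenAtoms(nb.GetIdx(), o.GetIdx()).GetBondTypeAsDouble() == 2.0
        for o in term_o
    )
    return charged or has_double


def _is_amide_nitrogen(atom) -> bool:
    from rdkit import Chem

    if atom.GetSymbol() != "N" or atom.GetIsAromatic():
        return False
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() != "C":
            continue
        for b in nb.GetBonds():
            other = b.GetOtherAtom(nb)
            if (
                b.GetBondType() == Chem.BondType.DOUBLE
                and other.GetSymbol() in ("O", "S")
            ):
                return True
    return False
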