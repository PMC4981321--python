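"""Protein structure handling: PDB parsing, SASA, ligands and contacts.

Structures are reduced to typed heavy-atom records.  Solvent accessibility
is computed with the Shrake-Rupley method using the packaged van der Waals
radii and a solvent probe, always in the absence of waters and hetero
groups; atoms with SASA > 0 are the "surface atoms" every downstream stage
operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .atom_types import (
    NONSTANDARD_PARENT,
    STANDARD_RESIDUES,
    TypingError,
    load_atom_type_table,
    type_ligand_atom,
    type_protein_atom,
)
from .geometry import fibonacci_sphere, kabsch_superpose

__all__ = [
    "AtomRecord",
    "Structure",
    "LigandInstance",
    "UnusableStructureError",
    "parse_structure",
    "extract_ligands",
    "extract_waters",
    "ligand_from_coords",
    "compute_sasa",
    "ligand_contact_atoms",
    "superpose_and_center_distance",
    "ligand_neighborhood_rmsd",
    "write_pdb_with_confidence",
]

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class UnusableStructureError(ValueError):
    """Structure cannot be used (e.g. C-alpha-only chain)."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    chain: str
    resseq: int
    icode: str
    resname: str
    coord: np.ndarray
    type_id: int
    element: str
    sasa: float = float("nan")
    is_surface: bool = False

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.resseq, self.icode)


@dataclass
class LigandInstance:
    """Heavy atoms of one bound small-molecule ligand."""

    het_code: str
    elements: list
    type_ids: list  # Sybyl ids 32-53
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise ValueError("ligand must contain at least one heavy atom")

    def __len__(self) -> int:
        return len(self.coords)


class Structure:
    """An ordered list of typed protein heavy atoms grouped into residues."""

    def __init__(self, atoms: list[AtomRecord]):
        self.atoms = atoms
        self._table = load_atom_type_table()
        self._coords: np.ndarray | None = None
        self._radii: np.ndarray | None = None
        self._tree = None

    def __len__(self) -> int:
        return len(self.atoms)

    # coordinates are treated as immutable after parsing; derived arrays and
    # the KD-tree are cached
    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array([a.coord for a in self.atoms], float).reshape(-1, 3)
        return self._coords

    @property
    def radii(self) -> np.ndarray:
        if self._radii is None:
            self._radii = np.array([self._table.radius(a.type_id) for a in self.atoms])
        return self._radii

    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.coords)
        return self._tree

    @property
    def residues(self) -> dict:
        """Ordered mapping residue_key -> list of atom indices."""
        out: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def residue_name(self, key: tuple) -> str:
        return self.atoms[self.residues[key][0]].resname

    def surface_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_surface], int)

    def ca_coords(self) -> dict:
        return {
            a.residue_key: a.coord for a in self.atoms if a.name == "CA"
        }

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Structure":
        new = []
        for a in self.atoms:
            b = AtomRecord(
                a.serial, a.name, a.chain, a.resseq, a.icode, a.resname,
                np.asarray(a.coord, float) @ np.asarray(R).T + t,
                a.type_id, a.element, a.sasa, a.is_surface,
            )
            new.append(b)
        return Structure(new)


def _gemmi_structure(pdb_text: str):
    import gemmi

    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    return st


def _select_altlocs(residue) -> list:
    """Resolve alternate locations: keep highest occupancy, first on tie."""
    best: dict[str, object] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def parse_structure(pdb_text: str, chain: str | None = None) -> Structure:
    """Parse protein heavy atoms of one chain from PDB text.

    Hydrogens, waters and hetero groups are skipped; alternate locations
    resolve to the highest-occupancy conformer (first in file order on a
    tie).  A chain containing only C-alpha atoms raises
    :class:`UnusableStructureError`.
    """
    st = _gemmi_structure(pdb_text)
    if len(st) == 0:
        raise UnusableStructureError("no models in PDB text")
    model = st[0]
    records: list[AtomRecord] = []
    chain_seen = False
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        chain_seen = True
        for res in ch:
            rname = res.name.strip().upper()
            if rname in _WATER_NAMES:
                continue
            if rname not in STANDARD_RESIDUES and rname not in NONSTANDARD_PARENT:
                continue  # hetero group in the polymer record
            for atom in _select_altlocs(res):
                if atom.element.is_hydrogen:
                    continue
                try:
                    ptype = type_protein_atom(rname, atom.name)
                except TypingError as exc:
                    warnings.warn(f"skipping atom: {exc}", stacklevel=2)
                    continue
                records.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        chain=ch.name,
                        resseq=res.seqid.num,
                        icode=(res.seqid.icode or " ").strip() or "",
                        resname=rname,
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        type_id=ptype.id,
                        element=atom.element.name,
                    )
                )
    if not records:
        where = f"chain {chain!r}" if chain is not None else "file"
        if chain is not None and not chain_seen:
            raise UnusableStructureError(f"{where} not found in PDB text")
        raise UnusableStructureError(f"no standard protein atoms in {where}")
    if all(a.name == "CA" for a in records):
        raise UnusableStructureError("chain contains only C-alpha atoms")
    return Structure(records)


_FALLBACK_LIGAND_TYPE = {"C": 32, "O": 37, "N": 41, "S": 48, "P": 47,
                         "F": 51, "CL": 52, "BR": 53}


def _perceive_bonds_obabel(elements: list, coords: np.ndarray) -> list[tuple[int, int, str]]:
    """Bond list (i, j, order) perceived by OpenBabel from 3D coordinates.

    Uses the ``obabel`` command-line tool (xyz in, mol2 out); the mol2 atom
    block preserves input atom order.
    """
    import shutil
    import subprocess
    import tempfile

    exe = shutil.which("obabel")
    if exe is None:
        raise RuntimeError("obabel executable not found")
    xyz = [str(len(elements)), ""]
    for el, c in zip(elements, coords):
        xyz.append(f"{el.capitalize()} {c[0]:.4f} {c[1]:.4f} {c[2]:.4f}")
    with tempfile.NamedTemporaryFile("w", suffix=".xyz", delete=False) as fh:
        fh.write("\n".join(xyz) + "\n")
        path = fh.name
    try:
        out = subprocess.run([exe, path, "-omol2"], capture_output=True,
                             text=True, check=True, timeout=60)
    finally:
        import os

        os.unlink(path)
    bonds = []
    section = None
    for line in out.stdout.splitlines():
        if line.startswith("@<TRIPOS>"):
            section = line.strip()
            continue
        if section == "@<TRIPOS>BOND" and line.strip():
            _bid, i, j, order = line.split()[:4]
            bonds.append((int(i) - 1, int(j) - 1, order))
    return bonds


_MOL2_BOND = {"1": 1.0, "2": 2.0, "3": 3.0, "am": 1.0, "ar": 1.5, "du": 1.0}


def _mol_from_bonds(elements: list, coords: np.ndarray,
                    bonds: list[tuple[int, int, str]]):
    from rdkit import Chem
    from rdkit.Chem import rdmolops

    rw = Chem.RWMol()
    conf = Chem.Conformer(len(elements))
    for i, el in enumerate(elements):
        rw.AddAtom(Chem.Atom(el.capitalize()))
        conf.SetAtomPosition(i, [float(x) for x in coords[i]])
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for i, j, o in bonds:
        rw.AddBond(i, j, order_map[_MOL2_BOND.get(o, 1.0)])
    # minimal formal-charge repair for common over-valent cases
    for atom in rw.GetAtoms():
        if atom.GetSymbol() == "N" and atom.GetDegree() == 4:
            atom.SetFormalCharge(1)
        if atom.GetSymbol() == "O" and atom.GetDegree() == 3:
            atom.SetFormalCharge(1)
    mol = rw.GetMol()
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    rdmolops.SetAromaticity(mol)
    return mol


def ligand_from_coords(het_code: str, elements: list, coords) -> LigandInstance:
    """Build a typed ligand from elements + coordinates.

    Connectivity and bond orders are perceived with OpenBabel from the 3D
    coordinates; aromaticity is then perceived on the reconstructed
    molecular graph and Sybyl types assigned.  If perception fails, atoms
    fall back to the default sp3 type of their element, with a warning.
    """
    coords = np.asarray(coords, float).reshape(-1, 3)
    type_ids = None
    try:
        bonds = _perceive_bonds_obabel(elements, coords)
        mol = _mol_from_bonds(elements, coords, bonds)
        type_ids = [type_ligand_atom(mol, i).id for i in range(mol.GetNumAtoms())]
    except Exception as exc:  # perception failure -> element defaults
        warnings.warn(f"bond perception failed for {het_code}: {exc}; "
                      "using element-default ligand types", stacklevel=2)
    if type_ids is None:
        type_ids = []
        for el in elements:
            tid = _FALLBACK_LIGAND_TYPE.get(el.upper())
            if tid is None:
                raise TypingError(f"unsupported ligand element {el!r}")
            type_ids.append(tid)
    return LigandInstance(het_code, list(elements), type_ids, coords)


def extract_ligands(pdb_text: str, het_code: str | None = None,
                    min_atoms: int = 1) -> list[LigandInstance]:
    """Extract HETATM ligands (waters excluded) as typed ligand instances."""
    st = _gemmi_structure(pdb_text)
    out = []
    for ch in st[0]:
        for res in ch:
            rname = res.name.strip().upper()
            if rname in _WATER_NAMES or rname in STANDARD_RESIDUES:
                continue
            if rname in NONSTANDARD_PARENT:
                continue
            if het_code is not None and rname != het_code.upper():
                continue
            elements, coords = [], []
            for atom in _select_altlocs(res):
                if atom.element.is_hydrogen:
                    continue
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if len(elements) >= min_atoms:
                out.append(ligand_from_coords(rname, elements, np.array(coords)))
    return out


def extract_waters(pdb_text: str) -> np.ndarray:
    """Coordinates of water oxygens, shape (n, 3)."""
    st = _gemmi_structure(pdb_text)
    coords = []
    for ch in st[0]:
        for res in ch:
            if res.name.strip().upper() in _WATER_NAMES:
                for atom in res:
                    if atom.element.name == "O":
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return np.array(coords, float).reshape(-1, 3)


def compute_sasa(s: Structure, probe_radius: float = 1.4, n_points: int = 960) -> Structure:
    """Fill per-atom SASA (Shrake-Rupley) and set the surface flag in place.

    Uses the packaged van der Waals radii; waters/ligands are never part of
    a :class:`Structure`, so accessibility is always ligand-free.
    """
    coords = s.coords
    radii = s.radii + probe_radius
    sphere = fibonacci_sphere(n_points)
    tree = s.kdtree()
    rmax = radii.max()
    for i, atom in enumerate(s.atoms):
        ri = radii[i]
        pts = coords[i] + ri * sphere
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        accessible = np.ones(n_points, bool)
        if nbrs:
            d = np.linalg.norm(pts[:, None, :] - coords[nbrs][None, :, :], axis=2)
            accessible = np.all(d >= radii[nbrs][None, :], axis=1)
        frac = accessible.mean()
        atom.sasa = float(4.0 * np.pi * ri * ri * frac)
        atom.is_surface = atom.sasa > 0.0
    return s


def ligand_contact_atoms(s: Structure, lig: LigandInstance, cutoff: float = 4.5) -> set[int]:
    """Protein atoms whose minimum distance to any ligand heavy atom is <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(lig) == 0:
        raise ValueError("empty ligand")
    tree = cKDTree(lig.coords)
    d, _ = tree.query(s.coords, k=1)
    return set(np.nonzero(d <= cutoff)[0].tolist())


def _matched_ca(model: Structure, actual: Structure):
    ca_m, ca_a = model.ca_coords(), actual.ca_coords()
    keys = [k for k in ca_a if k in ca_m]
    if len(keys) < 3:
        raise ValueError("fewer than 3 corresponding C-alpha pairs")
    return (
        np.array([ca_m[k] for k in keys]),
        np.array([ca_a[k] for k in keys]),
    )


def superpose_and_center_distance(model: Structure, actual: Structure,
                                  center_m, center_a) -> float:
    """Distance between two predicted centers after C-alpha superposition.

    The model structure is rigidly superposed onto the actual structure by
    least-squares fit of corresponding C-alpha atoms; the model-side center
    is co-transformed before the Euclidean distance is taken.
    """
    m, a = _matched_ca(model, actual)
    R, t, _ = kabsch_superpose(m, a)
    cm = np.asarray(center_m, float) @ R.T + t
    return float(np.linalg.norm(cm - np.asarray(center_a, float)))


def ligand_neighborhood_rmsd(model: Structure, actual: Structure,
                             lig: LigandInstance, contact_cutoff: float = 4.5,
                             neighborhood: float = 10.0) -> float:
    """RMSD over the ligand-neighboring atoms after C-alpha superposition.

    Ligand-binding atoms are the actual-structure atoms within
    ``contact_cutoff`` of any ligand heavy atom; the neighborhood extends to
    all atoms within ``neighborhood`` of any ligand-binding atom.
    Correspondence is by residue identity and atom name.
    """
    binding = ligand_contact_atoms(actual, lig, contact_cutoff)
    if not binding:
        raise ValueError("no ligand-binding atoms within cutoff")
    acoords = actual.coords
    btree = cKDTree(acoords[sorted(binding)])
    d, _ = btree.query(acoords, k=1)
    nbhd = np.nonzero(d <= neighborhood)[0]
    if len(nbhd) == 0:
        raise ValueError("empty ligand neighborhood")
    m, a = _matched_ca(model, actual)
    R, t, _ = kabsch_superpose(m, a)
    mindex = {(at.residue_key, at.name): i for i, at in enumerate(model.atoms)}
    pairs = []
    for i in nbhd:
        at = actual.atoms[i]
        j = mindex.get((at.residue_key, at.name))
        if j is not None:
            pairs.append((j, i))
    if not pairs:
        raise ValueError("no corresponding atoms in the ligand neighborhood")
    mc = np.array([model.atoms[j].coord for j, _ in pairs]) @ R.T + t
    ac = np.array([actual.atoms[i].coord for _, i in pairs])
    return float(np.sqrt(np.mean(np.sum((mc - ac) ** 2, axis=1))))


def write_pdb_with_confidence(s: Structure, confidences) -> str:
    """PDB text with prediction confidence x100 in the B-factor column."""
    confidences = np.asarray(confidences, float)
    if len(confidences) != len(s):
        raise ValueError("one confidence per atom required")
    lines = []
    for a, c in zip(s.atoms, confidences):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name}{'':1s}{a.resname:>3s} {a.chain:1s}"
            f"{a.resseq:4d}{a.icode or ' ':1s}   "
            f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
            f"{1.0:6.2f}{100.0 * c:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
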