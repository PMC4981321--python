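"""Database of non-covalent atomistic interactions around protein surface atoms.

Every surface atom of a complex of known structure contributes a set of
interaction records: for each non-covalently contacting heavy atom (protein
atom of a sequence-non-adjacent residue, water oxygen, or ligand atom)
within the contact cutoff, the contacting atom's type and its displacement
expressed in the central atom's local covalent frame are stored.  Records
are keyed by the central-atom context -- atom type x parent residue type x
parent-residue conformational class -- so that interacting-atom
distributions can later be retrieved for any query atom in the same
context and remapped onto a new protein surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import dihedral, local_frame
from .structure import LigandInstance, Structure

__all__ = [
    "ComplexMetadata",
    "ContextKey",
    "InteractionRecord",
    "InteractionDatabase",
    "filter_complexes",
    "conformation_class",
    "residue_conformations",
    "covalent_bond_graph",
    "harvest",
    "sequence_identity",
]

BOND_CUTOFF = 1.9  # Å; heavy-atom pairs closer than this are covalent


@dataclass
class ComplexMetadata:
    pdb_id: str
    method: str
    resolution: float
    has_nucleic_in_atom: bool
    ca_only: bool
    covalent_ligand: bool
    n_ligand_atoms: int
    n_interacting_atoms: int
    seq: str
    ligand_code: str


class ContextKey(NamedTuple):
    central_type: int
    residue_type: str
    conf_class: str


@dataclass
class InteractionRecord:
    interacting_type: int
    local_coord: np.ndarray
    source_class: str = "protein"  # protein | water | ligand


# --- complex filtering -----------------------------------------------------

_REQUIRED_FIELDS = (
    "pdb_id method resolution has_nucleic_in_atom ca_only covalent_ligand "
    "n_ligand_atoms n_interacting_atoms seq ligand_code"
).split()


def rejection_reason(m: ComplexMetadata) -> str | None:
    """First removal criterion matched by a complex, or None if acceptable."""
    missing = [f for f in _REQUIRED_FIELDS if getattr(m, f) is None]
    if missing:
        raise ValueError(f"metadata for {m.pdb_id!r} missing fields: {missing}")
    if "x-ray" not in m.method.lower().replace(" ", "-"):
        return "non X-ray method"
    if m.resolution > 3.0:
        return "resolution higher than 3 A"
    if m.has_nucleic_in_atom:
        return "ATOM record contains DNA or RNA"
    if m.ca_only:
        return "only C-alpha atoms"
    if m.covalent_ligand:
        return "covalent link between ligand and protein"
    if m.n_ligand_atoms < 10:
        return "fewer than 10 ligand atoms"
    if m.n_interacting_atoms < 15:
        return "fewer than 15 interacting atoms"
    return None


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity fraction in [0, 1]."""
    if not a or not b:
        return 0.0
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def filter_complexes(candidates: Iterable[ComplexMetadata],
                     identity_threshold: float = 0.30,
                     report: dict | None = None) -> list[ComplexMetadata]:
    """Apply the structure-removal criteria and redundancy reduction.

    A complex is removed if it matches any criterion: non X-ray method,
    resolution worse than 3 Å, nucleic acids in the ATOM records, C-alpha-
    only coordinates, a protein-ligand covalent link, fewer than 10 ligand
    atoms, or fewer than 15 interacting atoms.  Among survivors binding the
    same ligand code, pairwise redundancy above the 30% sequence-identity
    threshold is removed greedily, keeping the best-resolution structure
    first.
    """
    accepted: list[ComplexMetadata] = []
    for m in candidates:
        reason = rejection_reason(m)
        if reason is not None:
            if report is not None:
                report[m.pdb_id] = reason
            continue
        accepted.append(m)
    # redundancy reduction per ligand code
    kept: list[ComplexMetadata] = []
    by_ligand: dict[str, list[ComplexMetadata]] = {}
    for m in accepted:
        by_ligand.setdefault(m.ligand_code, []).append(m)
    kept_ids = set()
    for code, group in by_ligand.items():
        group_sorted = sorted(group, key=lambda m: (m.resolution, m.pdb_id))
        retained: list[ComplexMetadata] = []
        for m in group_sorted:
            if all(sequence_identity(m.seq, r.seq) <= identity_threshold for r in retained):
                retained.append(m)
            elif report is not None:
                report[m.pdb_id] = f"redundant (>{identity_threshold:.0%} id, ligand {code})"
        kept_ids.update(m.pdb_id for m in retained)
    for m in accepted:
        if m.pdb_id in kept_ids:
            kept.append(m)
    return kept


# --- conformational classes ------------------------------------------------

def conformation_class(phi: float | None, psi: float | None,
                       chi1: float | None) -> str:
    """Conformational class label from backbone and side-chain dihedrals.

    Three backbone bins (helix-like, strand-like, other) crossed with a
    chi-1 rotamer bin {g+, t, g-, none}.  Missing backbone dihedrals (chain
    termini) collapse to the single class ``"other"``.
    """
    if phi is None or psi is None:
        return "other"
    if -180.0 <= phi < 0.0 and -120.0 <= psi < 45.0:
        bb = "H"
    elif -180.0 <= phi < 0.0 and (45.0 <= psi <= 180.0 or -180.0 <= psi < -135.0):
        bb = "E"
    else:
        bb = "O"
    if chi1 is None:
        rot = "none"
    else:
        c = chi1 % 360.0
        if c < 120.0:
            rot = "g+"
        elif c < 240.0:
            rot = "t"
        else:
            rot = "g-"
    return f"{bb}/{rot}"


_CHI1_GAMMA = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}


def residue_conformations(s: Structure) -> dict:
    """Conformational class per residue key of a structure."""
    residues = s.residues
    keys = list(residues)
    atom_of = {}
    for key, idxs in residues.items():
        atom_of[key] = {s.atoms[i].name: s.atoms[i].coord for i in idxs}
    out = {}
    for pos, key in enumerate(keys):
        a = atom_of[key]
        resname = s.residue_name(key)
        phi = psi = chi1 = None
        prev_key = keys[pos - 1] if pos > 0 and keys[pos - 1][0] == key[0] else None
        next_key = keys[pos + 1] if pos + 1 < len(keys) and keys[pos + 1][0] == key[0] else None
        try:
            if prev_key is not None:
                phi = dihedral(atom_of[prev_key]["C"], a["N"], a["CA"], a["C"])
            if next_key is not None:
                psi = dihedral(a["N"], a["CA"], a["C"], atom_of[next_key]["N"])
            gamma = _CHI1_GAMMA.get(resname)
            if gamma and gamma in a and "CB" in a:
                chi1 = dihedral(a["N"], a["CA"], a["CB"], a[gamma])
        except KeyError:
            phi = psi = None  # missing backbone atoms -> class "other"
        out[key] = conformation_class(phi, psi, chi1)
    return out


# --- covalent graph and frames ---------------------------------------------

def covalent_bond_graph(s: Structure) -> dict[int, list[int]]:
    """Adjacency of covalently bonded protein heavy atoms.

    Bonds are inferred from distance (< 1.9 Å) restricted to atom pairs in
    the same or sequence-adjacent residues of one chain.
    """
    coords = s.coords
    tree = cKDTree(coords)
    adj: dict[int, list[int]] = {i: [] for i in range(len(s))}
    for i, j in tree.query_pairs(BOND_CUTOFF):
        ai, aj = s.atoms[i], s.atoms[j]
        if ai.chain == aj.chain and abs(ai.resseq - aj.resseq) <= 1:
            adj[i].append(j)
            adj[j].append(i)
    return adj


def atom_frame(s: Structure, i: int, adj: dict[int, list[int]] | None = None) -> np.ndarray:
    """Local covalent frame of atom ``i`` (columns are the frame axes)."""
    if adj is None:
        adj = covalent_bond_graph(s)
    coords = s.coords
    bonded = [coords[j] for j in adj[i]]
    support = [coords[k] for j in adj[i] for k in adj[j] if k != i]
    return local_frame(coords[i], bonded, support)


# --- the database -----------------------------------------------------------

class InteractionDatabase:
    """Interaction records grouped by central-atom context key."""

    def __init__(self):
        self._store: dict[ContextKey, list[InteractionRecord]] = {}

    def add(self, key: ContextKey, rec: InteractionRecord) -> None:
        self._store.setdefault(key, []).append(rec)

    def extend(self, items: Iterable[tuple[ContextKey, InteractionRecord]]) -> None:
        for key, rec in items:
            self.add(key, rec)

    def __len__(self) -> int:
        return sum(len(v) for v in self._store.values())

    @property
    def keys(self) -> list[ContextKey]:
        return list(self._store)

    def source_counts(self) -> dict[str, int]:
        counts = {"protein": 0, "water": 0, "ligand": 0}
        for recs in self._store.values():
            for r in recs:
                counts[r.source_class] += 1
        return counts

    def query(self, key: ContextKey):
        """Records for a context key, grouped by interacting type.

        Falls back to coarser contexts when the exact key is unseen:
        level 0 = exact, level 1 = any conformation class, level 2 = any
        residue and conformation (possibly empty).  Returns
        ``(groups, fallback_level)`` with ``groups`` mapping interacting
        type id to an (n, 3) array of local displacements.
        """
        recs = self._store.get(key)
        level = 0
        if not recs:
            level = 1
            recs = [
                r for k, v in self._store.items()
                if k.central_type == key.central_type and k.residue_type == key.residue_type
                for r in v
            ]
        if not recs:
            level = 2
            recs = [
                r for k, v in self._store.items()
                if k.central_type == key.central_type
                for r in v
            ]
        groups: dict[int, np.ndarray] = {}
        by_type: dict[int, list] = {}
        for r in recs:
            by_type.setdefault(r.interacting_type, []).append(r.local_coord)
        for t, coords in by_type.items():
            groups[t] = np.asarray(coords, float).reshape(-1, 3)
        return groups, level

    # serialization: flat arrays in a single .npz container
    def save(self, path) -> None:
        n = len(self)
        central = np.empty(n, np.int16)
        restype = np.empty(n, "U3")
        conf = np.empty(n, "U8")
        itype = np.empty(n, np.int16)
        source = np.empty(n, "U7")
        coords = np.empty((n, 3), np.float64)
        pos = 0
        for key, recs in self._store.items():
            for r in recs:
                central[pos] = key.central_type
                restype[pos] = key.residue_type
                conf[pos] = key.conf_class
                itype[pos] = r.interacting_type
                source[pos] = r.source_class
                coords[pos] = r.local_coord
                pos += 1
        np.savez(path, central=central, residue=restype, conf=conf,
                 itype=itype, source=source, coords=coords)

    @classmethod
    def load(cls, path) -> "InteractionDatabase":
        data = np.load(path)
        db = cls()
        for c, res, cf, it, src, xyz in zip(
            data["central"], data["residue"], data["conf"],
            data["itype"], data["source"], data["coords"]
        ):
            db.add(ContextKey(int(c), str(res), str(cf)),
                   InteractionRecord(int(it), np.array(xyz), str(src)))
        return db

    def to_tsv(self) -> str:
        lines = ["central_type\tresidue_type\tconf_class\tinteracting_type\tsource\tx\ty\tz"]
        for key, recs in self._store.items():
            for r in recs:
                x, y, z = r.local_coord
                lines.append(
                    f"{key.central_type}\t{key.residue_type}\t{key.conf_class}\t"
                    f"{r.interacting_type}\t{r.source_class}\t{x:.6f}\t{y:.6f}\t{z:.6f}"
                )
        return "\n".join(lines) + "\n"


def harvest(s: Structure,
            ligands: list[LigandInstance] | None = None,
            waters: np.ndarray | None = None,
            cutoff: float = 4.5,
            min_seq_separation: int = 2) -> list[tuple[ContextKey, InteractionRecord]]:
    """Collect non-covalent contacts around every surface atom of a complex.

    For each surface protein atom, records every heavy atom within
    ``cutoff``: protein atoms of residues at least ``min_seq_separation``
    apart in sequence (or on another chain), water oxygens, and ligand
    atoms.  Displacements are stored in the central atom's local frame, so
    the harvested geometry is independent of the complex's global pose.
    """
    if any(np.isnan(a.sasa) for a in s.atoms):
        raise ValueError("SASA must be computed before harvesting")
    ligands = ligands or []
    coords = s.coords
    adj = covalent_bond_graph(s)
    conf = residue_conformations(s)
    ptree = cKDTree(coords)
    ligand_pts = []
    for lig in ligands:
        for tid, xyz in zip(lig.type_ids, lig.coords):
            ligand_pts.append((tid, xyz))
    lig_tree = cKDTree(np.array([p[1] for p in ligand_pts])) if ligand_pts else None
    wat_tree = (cKDTree(waters) if waters is not None and len(waters) else None)

    out: list[tuple[ContextKey, InteractionRecord]] = []
    for i, atom in enumerate(s.atoms):
        if not atom.is_surface:
            continue
        try:
            frame = atom_frame(s, i, adj)
        except ValueError:
            warnings.warn(f"no covalent neighbors for atom {atom.serial}; skipped",
                          stacklevel=2)
            continue
        key = ContextKey(atom.type_id, atom.resname, conf[atom.residue_key])
        inv = frame.T
        # protein partners
        for j in ptree.query_ball_point(coords[i], cutoff):
            if j == i:
                continue
            other = s.atoms[j]
            if other.chain == atom.chain and abs(other.resseq - atom.resseq) < min_seq_separation:
                continue
            out.append((key, InteractionRecord(
                other.type_id, inv @ (coords[j] - coords[i]), "protein")))
        # waters
        if wat_tree is not None:
            for j in wat_tree.query_ball_point(coords[i], cutoff):
                out.append((key, InteractionRecord(
                    31, inv @ (waters[j] - coords[i]), "water")))
        # ligand atoms
        if lig_tree is not None:
            for j in lig_tree.query_ball_point(coords[i], cutoff):
                tid, xyz = ligand_pts[j]
                out.append((key, InteractionRecord(
                    tid, inv @ (xyz - coords[i]), "ligand")))
    return out
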