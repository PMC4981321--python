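"""Binding-site assembly and labeling.

Atom-level prediction confidences are integrated into ranked surface
patches: atoms with confidence above the seed threshold (strictly > 0.50)
nucleate patches; surface atoms within 5 Å of a seed with confidence
strictly > 0.10 join the patch; seed pairs closer than 10 Å merge their
patches transitively.  Patches are ranked by the sum of member confidences
and converted to residue-level predictions (a residue is positive when
strictly more than 30% of its surface atoms belong to the patch).  The same
module labels the *actual* binding residues of a holo complex under both
definitions used for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure import LigandInstance, Structure, ligand_contact_atoms

__all__ = [
    "Patch",
    "ResiduePrediction",
    "assemble_patches",
    "residue_predictions",
    "actual_residues_fractional",
    "actual_residues_vdw",
    "success_top1",
]


@dataclass
class Patch:
    member_atoms: list[int]
    seed_atoms: list[int]
    score: float
    center: np.ndarray

    def __post_init__(self):
        if not set(self.seed_atoms) <= set(self.member_atoms):
            raise ValueError("seeds must be a subset of members")


@dataclass(frozen=True)
class ResiduePrediction:
    residue_key: tuple
    predicted: bool
    fraction_in_patch: float


def assemble_patches(s: Structure, confidences,
                     seed_threshold: float = 0.50,
                     member_threshold: float = 0.10,
                     member_radius: float = 5.0,
                     merge_distance: float = 10.0) -> list[Patch]:
    """Ranked binding-site patches from per-atom confidences.

    Thresholds are strict (> 0.50 for seeds, > 0.10 for members,
    < 10 Å for merging) and the member radius is inclusive (within 5 Å).
    Returns patches sorted by descending summed-confidence score; an empty
    list means no site was predicted.
    """
    conf = np.asarray(confidences, float)
    if len(conf) != len(s):
        raise ValueError("one confidence per atom required")
    if np.any((conf < 0) | (conf > 1)):
        raise ValueError("confidences must lie in [0, 1]")
    surface = s.surface_indices()
    coords = s.coords
    seeds = np.array([i for i in surface if conf[i] > seed_threshold], int)
    if len(seeds) == 0:
        return []
    # transitive merging of seeds closer than merge_distance
    stree = cKDTree(coords[seeds])
    pairs = list(stree.query_pairs(merge_distance))
    pairs = [(i, j) for i, j in pairs
             if np.linalg.norm(coords[seeds[i]] - coords[seeds[j]]) < merge_distance]
    n = len(seeds)
    if pairs:
        rows = [p[0] for p in pairs] + [p[1] for p in pairs]
        cols = [p[1] for p in pairs] + [p[0] for p in pairs]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        adj = csr_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    # member atoms: surface atoms within member_radius of any seed of the patch
    eligible = np.array([i for i in surface if conf[i] > member_threshold], int)
    etree = cKDTree(coords[eligible]) if len(eligible) else None
    patches = []
    for comp in range(n_comp):
        comp_seeds = seeds[labels == comp]
        members: set[int] = set(int(i) for i in comp_seeds)
        if etree is not None:
            for si in comp_seeds:
                for k in etree.query_ball_point(coords[si], member_radius):
                    members.add(int(eligible[k]))
        member_list = sorted(members)
        score = float(conf[member_list].sum())
        center = coords[member_list].mean(axis=0)
        patches.append(Patch(member_list, sorted(int(i) for i in comp_seeds),
                             score, center))
    patches.sort(key=lambda p: (-p.score, p.member_atoms[0]))
    return patches


def residue_predictions(s: Structure, patch: Patch,
                        fraction_threshold: float = 0.30) -> list[ResiduePrediction]:
    """Residue-level conversion of an atom-based patch.

    A residue is positive when strictly more than ``fraction_threshold`` of
    its surface atoms (SASA > 0) belong to the patch; residues with no
    surface atoms are never positive.
    """
    members = set(patch.member_atoms)
    out = []
    for key, idxs in s.residues.items():
        surf = [i for i in idxs if s.atoms[i].is_surface]
        if not surf:
            out.append(ResiduePrediction(key, False, 0.0))
            continue
        frac = len([i for i in surf if i in members]) / len(surf)
        out.append(ResiduePrediction(key, frac > fraction_threshold, frac))
    return out


def actual_residues_fractional(s: Structure, lig: LigandInstance,
                               contact_cutoff: float = 4.5,
                               fraction_threshold: float = 0.30) -> set[tuple]:
    """Actual binding residues: > 30% of surface atoms within 4.5 Å of ligand."""
    if len(lig) == 0:
        raise ValueError("no ligand")
    contacts = ligand_contact_atoms(s, lig, contact_cutoff)
    labeled = set()
    for key, idxs in s.residues.items():
        surf = [i for i in idxs if s.atoms[i].is_surface]
        if not surf:
            continue
        frac = len([i for i in surf if i in contacts]) / len(surf)
        if frac > fraction_threshold:
            labeled.add(key)
    return labeled


def actual_residues_vdw(s: Structure, lig: LigandInstance,
                        tolerance: float = 0.5) -> set[tuple]:
    """Actual binding residues under the van der Waals contact definition.

    A residue is labeled when at least one of its heavy atoms lies within
    (r_protein + r_ligand + tolerance) of any ligand heavy atom.
    """
    if len(lig) == 0:
        raise ValueError("no ligand")
    coords = s.coords
    radii = s.radii
    from .atom_types import vdw_radius

    lig_r = np.array([vdw_radius(t) for t in lig.type_ids])
    labeled = set()
    d = np.linalg.norm(coords[:, None, :] - lig.coords[None, :, :], axis=2)
    within = d <= radii[:, None] + lig_r[None, :] + tolerance
    hit = within.any(axis=1)
    for key, idxs in s.residues.items():
        if any(hit[i] for i in idxs):
            labeled.add(key)
    return labeled


def success_top1(patches: list[Patch], lig: LigandInstance,
                 cutoff: float = 4.0) -> bool:
    """Top-1 success: geometry center of the best patch within 4 Å of the ligand.

    The distance is taken to the nearest ligand heavy atom; with no
    predicted patch the case counts as a failure.
    """
    if len(lig) == 0:
        raise ValueError("no ligand")
    if not patches:
        return False
    center = patches[0].center
    d = np.linalg.norm(lig.coords - center, axis=1).min()
    return bool(d <= cutoff)
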