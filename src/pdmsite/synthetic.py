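"""Deterministic synthetic protein-ligand complexes for end-to-end testing.

Real training corpora (thousands of curated PDB complexes) are out of reach
for a test suite, so this module builds small artificial complexes that
reproduce the *statistical shape* the prediction method relies on: a
globular protein with a designed concave pocket, and an organic ligand
seated in the pocket so that every ligand atom touches the lining.

The protein is a ball of real amino-acid residues (GLY/ALA/SER/CYS/THR/VAL/
LEU/ASP/LYS/PHE templates with proper covalent geometry) placed on a
jittered cubic lattice; a spherical bite near the surface carves the
pocket.  The ligand is a benzene ring with an aminoethyl tail, an aldehyde
and a hydroxymethyl group, covering the C.ar, C.3, C.2, N.3, O.3 and O.2
interacting types that dominate real binding sites.  All randomness flows
through the spec seed, so outputs are byte-identical per seed.  No force
field is involved: placement is hard-sphere rejection sampling only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .interaction_db import ComplexMetadata

__all__ = [
    "SyntheticComplexSpec",
    "make_complex",
    "make_apo",
    "make_corpus",
    "make_decoy_complex",
    "corpus_metadata_tsv",
]

RESIDUE_SPACING = 5.7       # Å lattice constant for residue (CA) sites
CLASH_PROTEIN = 2.4         # Å minimum heavy-atom separation between residues
CLASH_LIGAND = 3.0          # Å minimum protein-ligand separation
SITE_CLEARANCE = 1.5        # Å extra clearance for CA sites around the ligand
CONTACT_CUTOFF = 4.5        # Å ligand-contact distance

ONE_LETTER = {
    "GLY": "G", "ALA": "A", "SER": "S", "CYS": "C", "THR": "T",
    "VAL": "V", "LEU": "L", "ASP": "D", "LYS": "K", "PHE": "F",
}
ALPHABET = list(ONE_LETTER)


@dataclass(frozen=True)
class SyntheticComplexSpec:
    seed: int = 0
    n_residues: int = 60
    pocket_depth: float = 6.0
    pocket_radius: float = 4.0
    ligand_size: int = 13
    noise: float = 0.25

    def __post_init__(self):
        if self.ligand_size < 10:
            raise ValueError("ligand_size must be >= 10 (complex-filter criterion)")
        if self.pocket_radius <= 0 or self.pocket_depth <= 0:
            raise ValueError("pocket geometry must be positive")


# --- residue templates ------------------------------------------------------

def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _zigzag(start, d, p, bonds, angle_deg=111.0):
    """Chain of atoms from ``start`` along ``d``, zigzagging in the (d, p) plane."""
    d, p = _unit(d), _unit(p - np.dot(p, _unit(d)) * _unit(d))
    half = np.radians(180.0 - angle_deg) / 2.0
    out = []
    x = np.asarray(start, float)
    sign = 1.0
    for L in bonds:
        step = np.cos(half) * d + sign * np.sin(half) * p
        x = x + L * _unit(step)
        out.append(x.copy())
        sign = -sign
    return out


def _build_templates() -> dict[str, list[tuple[str, np.ndarray]]]:
    N = np.array([-1.458, 0.0, 0.0])
    CA = np.zeros(3)
    C = np.array([0.546, 1.424, 0.0])
    O = C + 1.23 * _unit([0.9, 0.2, 0.38])
    CB = np.array([0.434, -0.630, 1.325])
    bb = [("N", N), ("CA", CA), ("C", C), ("O", O)]
    d = _unit(CB - CA)          # outward side-chain direction
    p = _unit(np.cross(d, [1.0, 0.0, 0.0]))

    t: dict[str, list] = {}
    t["GLY"] = list(bb)
    t["ALA"] = bb + [("CB", CB)]
    og = _zigzag(CB, d, p, [1.42])
    t["SER"] = bb + [("CB", CB), ("OG", og[0])]
    sg = _zigzag(CB, d, p, [1.81])
    t["CYS"] = bb + [("CB", CB), ("SG", sg[0])]
    b1 = CB + 1.53 * _unit(np.cos(0.9) * d + np.sin(0.9) * p)
    b2 = CB + 1.53 * _unit(np.cos(0.9) * d - np.sin(0.9) * p)
    t["VAL"] = bb + [("CB", CB), ("CG1", b1), ("CG2", b2)]
    o1 = CB + 1.42 * _unit(np.cos(0.9) * d + np.sin(0.9) * p)
    t["THR"] = bb + [("CB", CB), ("OG1", o1), ("CG2", b2)]
    cg = _zigzag(CB, d, p, [1.53])[0]
    g1 = cg + 1.53 * _unit(np.cos(0.9) * d + np.sin(0.9) * p)
    g2 = cg + 1.53 * _unit(np.cos(0.9) * d - np.sin(0.9) * p)
    t["LEU"] = bb + [("CB", CB), ("CG", cg), ("CD1", g1), ("CD2", g2)]
    do1 = cg + 1.25 * _unit(np.cos(1.0) * d + np.sin(1.0) * p)
    do2 = cg + 1.25 * _unit(np.cos(1.0) * d - np.sin(1.0) * p)
    t["ASP"] = bb + [("CB", CB), ("CG", cg), ("OD1", do1), ("OD2", do2)]
    chain = _zigzag(CB, d, p, [1.53, 1.53, 1.53, 1.47])
    t["LYS"] = bb + [("CB", CB), ("CG", chain[0]), ("CD", chain[1]),
                     ("CE", chain[2]), ("NZ", chain[3])]
    # phenyl ring in the (d, p) plane
    cgf = CB + 1.50 * d
    center = cgf + 1.39 * d
    ring = []
    for name, ang in [("CG", 180.0), ("CD1", 120.0), ("CE1", 60.0),
                      ("CZ", 0.0), ("CE2", 300.0), ("CD2", 240.0)]:
        a = np.radians(ang)
        ring.append((name, center + 1.39 * (np.cos(a) * -d + np.sin(a) * p)))
    t["PHE"] = bb + [("CB", CB)] + ring
    return {k: [(n, np.asarray(x)) for n, x in v] for k, v in t.items()}


_TEMPLATES = _build_templates()

# --- ligand template --------------------------------------------------------

_LIGAND_BASE = [
    # (name, element, sybyl type id, xyz)
    ("C1", "C", 35, (1.390, 0.000, 0.000)),
    ("C2", "C", 35, (0.695, 1.204, 0.000)),
    ("C3", "C", 35, (-0.695, 1.204, 0.000)),
    ("C4", "C", 35, (-1.390, 0.000, 0.000)),
    ("C5", "C", 35, (-0.695, -1.204, 0.000)),
    ("C6", "C", 35, (0.695, -1.204, 0.000)),
    ("C7", "C", 32, (2.890, 0.000, 0.000)),       # benzylic CH2
    ("C8", "C", 32, (4.143, 0.000, 0.878)),       # CH2
    ("N1", "N", 41, (5.347, 0.000, 0.035)),       # amine
    ("C9", "C", 33, (-2.860, 0.000, 0.000)),      # aldehyde C
    ("O1", "O", 38, (-3.470, 1.057, 0.000)),      # aldehyde O
    ("C10", "C", 32, (-1.445, 2.503, 0.000)),     # hydroxymethyl CH2
    ("O2", "O", 37, (-2.155, 3.416, 0.824)),      # hydroxyl
]
_TRIM_ORDER = ["O2", "C10", "N1"]  # 13 -> 12 -> 11 -> 10 atoms


def ligand_template(size: int = 13):
    """Names, elements, Sybyl type ids and coordinates of the toy ligand."""
    atoms = list(_LIGAND_BASE)
    if size < 10:
        raise ValueError("ligand_size must be >= 10")
    k = 13 - size
    if k > len(_TRIM_ORDER):
        raise ValueError("ligand_size must be <= 13")
    for name in _TRIM_ORDER[:max(0, k)]:
        atoms = [a for a in atoms if a[0] != name]
    names = [a[0] for a in atoms]
    elements = [a[1] for a in atoms]
    type_ids = [a[2] for a in atoms]
    coords = np.array([a[3] for a in atoms], float)
    return names, elements, type_ids, coords - coords.mean(axis=0)


# --- complex construction ---------------------------------------------------

class InfeasibleGeometryError(RuntimeError):
    pass


def _ligand_pose(spec: SyntheticComplexSpec, rng) -> np.ndarray:
    """Seat the ligand at the pocket position, lying roughly in the xy plane.

    The complex is built around the ligand: the ligand center sits
    ``pocket_depth`` below the nominal protein surface on the +z axis, spun
    by a random angle about z with a small random tilt, so the rod-shaped
    molecule stays buried while the mouth channel above it remains open.
    """
    _, _, _, base = ligand_template(spec.ligand_size)
    a = RESIDUE_SPACING
    r_ball = a * (3.0 * spec.n_residues / (4.0 * np.pi)) ** (1.0 / 3.0)
    center = np.array([0.0, 0.0, r_ball - spec.pocket_depth])
    spin = Rotation.from_euler("z", rng.uniform(0.0, 360.0), degrees=True)
    tilt = Rotation.from_euler("xy", rng.uniform(-12.0, 12.0, 2), degrees=True)
    return center + base @ (tilt * spin).as_matrix().T


def _try_place(site, rname, rng, ltree, coords_so_far, pocket_radius, zc,
               tries: int = 40):
    """Random-orientation hard-sphere placement of one residue at a CA site."""
    template = _TEMPLATES[rname]
    local = np.array([x for _, x in template])
    names = [n for n, _ in template]
    tree = cKDTree(np.vstack(coords_so_far)) if coords_so_far else None
    for _ in range(tries):
        R = Rotation.from_quat(_unit(rng.normal(size=4))).as_matrix()
        cand = site + local @ R.T
        d, _n = ltree.query(cand, k=1)
        if d.min() < CLASH_LIGAND:
            continue
        rad = np.hypot(cand[:, 0], cand[:, 1])
        if np.any((rad < pocket_radius) & (cand[:, 2] > zc)):
            continue
        if tree is not None:
            dd, _m = tree.query(cand, k=1)
            if dd.min() < CLASH_PROTEIN:
                continue
        return names, cand
    return None


def _place_residues(spec: SyntheticComplexSpec, rng, ligand: np.ndarray):
    """Pack residues around the seated ligand: lining pass, then lattice fill.

    The lining pass puts one residue next to each ligand atom not yet
    within contact range, guaranteeing full ligand burial; the fill pass
    packs the remaining residues on a jittered cubic lattice by increasing
    distance from the origin.  All atoms keep >= CLASH_LIGAND Å from every
    ligand atom, stay out of the mouth channel (a vertical cylinder of
    radius ``pocket_radius`` above the ligand center), and avoid hard-sphere
    clashes; crowded lattice sites are dropped.
    """
    zc = ligand[:, 2].mean()
    centroid = ligand.mean(axis=0)
    ltree = cKDTree(ligand)
    placed: list[tuple[str, np.ndarray, np.ndarray]] = []  # (resname, names, coords)
    coords_so_far: list[np.ndarray] = []

    # lining pass: cover every ligand atom snugly
    for i in range(len(ligand)):
        if coords_so_far:
            tree = cKDTree(np.vstack(coords_so_far))
            if tree.query(ligand[i], k=1)[0] <= CONTACT_CUTOFF - 1.0:
                continue
        u = ligand[i] - centroid
        if np.linalg.norm(u) < 1e-6:
            u = np.array([1.0, 0.0, 0.0])
        u = _unit(u)
        if u[2] > 0.2:  # keep the mouth channel open
            u = _unit(u - (u[2] - 0.2) * np.array([0.0, 0.0, 1.0]))
        rname = ALPHABET[int(rng.integers(0, len(ALPHABET)))]
        hit = None
        for dist in (4.0, 4.3, 3.7):
            site = ligand[i] + dist * u
            hit = _try_place(site, rname, rng, ltree, coords_so_far,
                             spec.pocket_radius, zc)
            if hit is None and rname != "ALA":
                hit = _try_place(site, "ALA", rng, ltree, coords_so_far,
                                 spec.pocket_radius, zc)
                if hit is not None:
                    rname = "ALA"
            if hit is not None:
                break
        if hit is None:
            continue
        names, cand = hit
        placed.append((rname, names, cand))
        coords_so_far.extend(cand)

    # lattice fill
    a = RESIDUE_SPACING
    r_ball = a * (3.0 * spec.n_residues / (4.0 * np.pi)) ** (1.0 / 3.0)
    k = int(np.ceil((r_ball + 2 * a) / a))
    g = a * np.arange(-k, k + 1)
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts + rng.normal(0.0, spec.noise, pts.shape)
    d_lig, _ = ltree.query(pts, k=1)
    in_channel = (np.hypot(pts[:, 0], pts[:, 1]) < spec.pocket_radius + 2.0) & (
        pts[:, 2] > zc)
    keep = (d_lig >= CLASH_LIGAND + SITE_CLEARANCE) & ~in_channel
    pts = pts[keep]
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    n_fill = max(0, spec.n_residues - len(placed))
    sites = pts[order][:n_fill]
    resnames = [ALPHABET[i] for i in rng.integers(0, len(ALPHABET), len(sites))]
    for site, rname in zip(sites, resnames):
        hit = _try_place(site, rname, rng, ltree, coords_so_far,
                         spec.pocket_radius, zc)
        if hit is None:
            continue  # crowded site; drop the residue
        names, cand = hit
        placed.append((rname, names, cand))
        coords_so_far.extend(cand)

    # coverage repair: any ligand atom still out of contact range gets a
    # dedicated small residue, searching over directions around the radial one
    from .geometry import fibonacci_sphere

    probe_dirs = fibonacci_sphere(26)
    for i in range(len(ligand)):
        tree = cKDTree(np.vstack(coords_so_far))
        if tree.query(ligand[i], k=1)[0] <= CONTACT_CUTOFF - 0.2:
            continue
        u0 = ligand[i] - centroid
        u0 = _unit(u0) if np.linalg.norm(u0) > 1e-6 else np.array([1.0, 0.0, 0.0])
        dirs = sorted(probe_dirs, key=lambda d: -float(d @ u0))
        done = False
        for u in dirs:
            for dist in (3.9, 4.2):
                site = ligand[i] + dist * np.asarray(u)
                for rname in ("ALA", "GLY", "SER"):
                    hit = _try_place(site, rname, rng, ltree, coords_so_far,
                                     spec.pocket_radius, zc, tries=20)
                    if hit is not None:
                        names, cand = hit
                        placed.append((rname, names, cand))
                        coords_so_far.extend(cand)
                        done = True
                        break
                if done:
                    break
            if done:
                break
        if not done:
            raise InfeasibleGeometryError(
                f"could not bury ligand atom {i} within contact range")

    placed_atoms: list[tuple[str, int, str, np.ndarray]] = []
    for ridx, (rname, names, cand) in enumerate(placed, start=1):
        for name, xyz in zip(names, cand):
            placed_atoms.append((rname, ridx, name, xyz))
    if not placed_atoms:
        raise InfeasibleGeometryError("no residues could be placed")
    return placed_atoms


def _check_seated(ligand: np.ndarray, protein_coords: np.ndarray) -> None:
    tree = cKDTree(protein_coords)
    dmin, _ = tree.query(ligand, k=1)
    if dmin.min() < CLASH_LIGAND - 1e-9:
        raise InfeasibleGeometryError("protein-ligand clash in constructed complex")
    if dmin.max() > CONTACT_CUTOFF:
        raise InfeasibleGeometryError(
            f"ligand atom {dmin.argmax()} is {dmin.max():.2f} Å from the protein")
    n_contacts = len(set(
        j for c in ligand for j in tree.query_ball_point(c, CONTACT_CUTOFF)))
    if n_contacts < 15:
        raise InfeasibleGeometryError("fewer than 15 interacting protein atoms")


def _format_pdb(placed_atoms, ligand=None, het_code="LIG", chain="A") -> str:
    buf = io.StringIO()
    serial = 0
    last_res = max(r for _, r, _, _ in placed_atoms)
    for rname, rseq, name, xyz in placed_atoms:
        serial += 1
        el = name[0]
        aname = name if len(name) == 4 else f" {name:<3s}"
        buf.write(
            f"ATOM  {serial:5d} {aname} {rname:>3s} {chain}{rseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {el:>2s}\n"
        )
    if ligand is not None:
        names, elements, _tids, _ = ligand_template(len(ligand))
        for name, el, xyz in zip(names, elements, ligand):
            serial += 1
            aname = name if len(name) == 4 else f" {name:<3s}"
            buf.write(
                f"HETATM{serial:5d} {aname} {het_code:>3s} {chain}{last_res + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {el:>2s}\n"
            )
    buf.write("END\n")
    return buf.getvalue()


def _build(spec: SyntheticComplexSpec):
    rng = np.random.default_rng([spec.seed, 0x5EED])
    ligand = _ligand_pose(spec, rng)
    placed_atoms = _place_residues(spec, rng, ligand)
    coords = np.array([xyz for _, _, _, xyz in placed_atoms])
    _check_seated(ligand, coords)
    return placed_atoms, ligand


def make_complex(spec: SyntheticComplexSpec) -> str:
    """PDB text of a synthetic holo complex (protein chain + HETATM ligand)."""
    placed_atoms, ligand = _build(spec)
    return _format_pdb(placed_atoms, ligand)


def make_apo(spec: SyntheticComplexSpec, displacement: float = 0.3,
             rotation_deg: float = 4.0) -> str:
    """Apo counterpart: same protein, ligand removed, conformation perturbed.

    Each residue moves as a rigid body (random rotation about its centroid,
    sigma ``rotation_deg`` per axis, plus a random translation with sigma
    ``displacement`` per coordinate).  This emulates the conformational
    differences between independently solved apo and holo structures —
    side-chain repacking and small backbone shifts — while preserving
    covalent geometry exactly; independent per-atom noise would stretch
    bonds unphysically.
    """
    placed_atoms, _ = _build(spec)
    rng = np.random.default_rng([spec.seed, 0xA90])
    by_res: dict[int, list[int]] = {}
    for idx, (_rn, rs, _n, _xyz) in enumerate(placed_atoms):
        by_res.setdefault(rs, []).append(idx)
    coords = np.array([xyz for _, _, _, xyz in placed_atoms])
    for rs, idxs in by_res.items():
        R = Rotation.from_rotvec(
            rng.normal(0.0, np.radians(rotation_deg), 3)).as_matrix()
        t = rng.normal(0.0, displacement, 3)
        centroid = coords[idxs].mean(axis=0)
        coords[idxs] = (coords[idxs] - centroid) @ R.T + centroid + t
    moved = [(rn, rs, n, coords[i])
             for i, (rn, rs, n, _xyz) in enumerate(placed_atoms)]
    return _format_pdb(moved, ligand=None)


def make_decoy_complex(spec: SyntheticComplexSpec, min_separation: float = 8.0) -> str:
    """Negative control: the ligand floats >= 8 Å away from the protein."""
    placed_atoms, _ = _build(spec)
    coords = np.array([xyz for _, _, _, xyz in placed_atoms])
    _, _, _, base = ligand_template(spec.ligand_size)
    lig_extent = np.linalg.norm(base, axis=1).max()
    zmax = coords[:, 2].max()
    ligand = base + np.array([0.0, 0.0, zmax + min_separation + lig_extent + 1.0])
    d = np.linalg.norm(coords[:, None, :] - ligand[None, :, :], axis=2).min()
    while d < min_separation:
        ligand = ligand + np.array([0.0, 0.0, 2.0])
        d = np.linalg.norm(coords[:, None, :] - ligand[None, :, :], axis=2).min()
    return _format_pdb(placed_atoms, ligand)


def _metadata_for(spec: SyntheticComplexSpec, pdb_id: str, pdb_text: str,
                  resolution: float) -> ComplexMetadata:
    from .structure import extract_ligands, parse_structure

    s = parse_structure(pdb_text)
    ligs = extract_ligands(pdb_text)
    n_lig = len(ligs[0]) if ligs else 0
    n_int = 0
    if ligs:
        from .structure import ligand_contact_atoms

        n_int = len(ligand_contact_atoms(s, ligs[0], CONTACT_CUTOFF))
    seq_keys = list(s.residues)
    seq = "".join(ONE_LETTER.get(s.residue_name(k), "X") for k in seq_keys)
    return ComplexMetadata(
        pdb_id=pdb_id, method="X-RAY DIFFRACTION", resolution=resolution,
        has_nucleic_in_atom=False, ca_only=False, covalent_ligand=False,
        n_ligand_atoms=n_lig, n_interacting_atoms=n_int, seq=seq,
        ligand_code=f"L{pdb_id[-2:]}",
    )


def make_corpus(n: int, seed: int = 0):
    """A corpus of ``n`` varied synthetic complexes with filter-passing metadata.

    Returns a list of dicts with keys ``pdb_id``, ``spec``, ``pdb_text`` and
    ``metadata``.
    """
    if n < 10:
        raise ValueError("a corpus needs at least 10 complexes")
    rng = np.random.default_rng([seed, 0xC0])
    out = []
    for i in range(n):
        spec = SyntheticComplexSpec(
            seed=int(seed * 10000 + i),
            n_residues=int(rng.integers(55, 71)),
            pocket_depth=float(rng.uniform(5.5, 6.5)),
            pocket_radius=float(rng.uniform(3.9, 4.3)),
            ligand_size=13,
            noise=0.25,
        )
        pdb_id = f"SYN{i:03d}"
        pdb_text = make_complex(spec)
        resolution = float(np.round(rng.uniform(1.3, 2.4), 2))
        out.append({
            "pdb_id": pdb_id,
            "spec": spec,
            "pdb_text": pdb_text,
            "metadata": _metadata_for(spec, pdb_id, pdb_text, resolution),
        })
    return out


def corpus_metadata_tsv(corpus) -> str:
    cols = ("pdb_id method resolution has_nucleic_in_atom ca_only covalent_ligand "
            "n_ligand_atoms n_interacting_atoms seq ligand_code").split()
    lines = ["\t".join(cols)]
    for entry in corpus:
        m = entry["metadata"]
        lines.append("\t".join(str(getattr(m, c)) for c in cols))
    return "\n".join(lines) + "\n"
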