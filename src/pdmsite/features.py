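"""Per-surface-atom input attributes from probability density maps (PDMs).

For a query surface atom, the interaction database is queried with the
atom's context key; the retrieved interacting-atom displacements (one set
per interacting atom type) are mapped through the atom's local covalent
frame, accumulated on a cubic grid with a Gaussian kernel, masked to
exclude space inside the protein's van der Waals volume, and normalized to
a unit-mass 3D probability density.  Attribute *t* (t = 1..53) is the
density mass inside the contact shell where an atom of type *t* would touch
the query atom, rescaled by a corpus-level normalizer so values live in
[0, 1].  Attribute 54 is a local-geometry descriptor: the fraction of the
10 Å sphere around the atom not occupied by protein van der Waals volume.

The PDM grid lives in the query atom's local frame, which makes the whole
attribute vector exactly invariant under rigid motion of the structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .atom_types import vdw_radius
from .interaction_db import ContextKey, InteractionDatabase, atom_frame, \
    covalent_bond_graph, residue_conformations
from .structure import Structure

__all__ = [
    "PDM",
    "PdmParams",
    "AttributeNormalizer",
    "build_pdms",
    "pdm_attribute",
    "geometry_attribute",
    "attribute_vector",
    "featurize_structure",
    "N_ATTRIBUTES",
    "N_PDM_ATTRIBUTES",
]

N_PDM_ATTRIBUTES = 53
N_ATTRIBUTES = 54


@dataclass(frozen=True)
class PdmParams:
    """Grid and kernel parameters for PDM reconstruction."""

    radius: float = 6.0       # Å, half-edge of the cubic grid
    spacing: float = 0.5      # Å between grid nodes (odd node count)
    sigma: float = 0.75       # Å, Gaussian kernel width
    shell_delta: float = 1.0  # Å, contact-shell half width
    max_records: int = 4000   # per-type cap on retrieved records (even subsample)


@dataclass
class PDM:
    """Unit-mass 3D density of one interacting atom type around a query atom.

    The grid is axis-aligned in the query atom's local frame; ``origin`` and
    ``frame`` place it in world coordinates.
    """

    interacting_type: int
    grid: np.ndarray           # (n, n, n) density, zero if no records
    spacing: float
    origin: np.ndarray         # world coordinates of the central node
    frame: np.ndarray          # local frame (columns = axes)
    normalization: float       # total mass before unit normalization (0 if empty)

    @property
    def axis(self) -> np.ndarray:
        n = self.grid.shape[0]
        half = (n - 1) // 2
        return self.spacing * (np.arange(n) - half)

    def world_points(self) -> np.ndarray:
        g = self.axis
        local = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
        return self.origin + local @ self.frame.T

    def total_mass(self) -> float:
        return float(self.grid.sum() * self.spacing**3)


@lru_cache(maxsize=8)
def _grid_axis(radius: float, spacing: float) -> np.ndarray:
    half = int(round(radius / spacing))
    return spacing * np.arange(-half, half + 1)


@lru_cache(maxsize=8)
def _grid_radii(radius: float, spacing: float) -> np.ndarray:
    g = _grid_axis(radius, spacing)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    return np.sqrt(xx * xx + yy * yy + zz * zz)


def _free_space_mask(s: Structure, atom_index: int, frame: np.ndarray,
                     params: PdmParams) -> np.ndarray:
    """Boolean grid: True where no protein atom's vdW sphere covers the node.

    Each nearby atom is transformed into the query atom's local frame and
    only the grid subwindow it can reach is tested.
    """
    g = _grid_axis(params.radius, params.spacing)
    n = len(g)
    center = s.atoms[atom_index].coord
    coords = s.coords
    radii = s.radii
    occupied = np.zeros((n, n, n), bool)
    for j in s.kdtree().query_ball_point(center, params.radius * np.sqrt(3) + radii.max()):
        d = frame.T @ (coords[j] - center)
        r = radii[j]
        lo = np.searchsorted(g, d - r)
        hi = np.searchsorted(g, d + r, side="right")
        if np.any(lo >= hi) or np.any(hi <= 0) or np.any(lo >= n):
            continue
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        dx = g[sl[0]] - d[0]
        dy = g[sl[1]] - d[1]
        dz = g[sl[2]] - d[2]
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        occupied[sl] |= d2 < r * r
    return ~occupied


def _splat(points: np.ndarray, params: PdmParams) -> np.ndarray:
    """Sum of unit Gaussians at local points, sampled on the grid (separable)."""
    g = _grid_axis(params.radius, params.spacing)
    s2 = 2.0 * params.sigma**2
    gx = np.exp(-((g[None, :] - points[:, 0:1]) ** 2) / s2)
    gy = np.exp(-((g[None, :] - points[:, 1:2]) ** 2) / s2)
    gz = np.exp(-((g[None, :] - points[:, 2:3]) ** 2) / s2)
    return np.einsum("ni,nj,nk->ijk", gx, gy, gz)


def _cap_records(pts: np.ndarray, cap: int) -> np.ndarray:
    if len(pts) <= cap:
        return pts
    stride = int(np.ceil(len(pts) / cap))
    return pts[::stride]


def build_pdms(s: Structure, atom_index: int, db: InteractionDatabase,
               params: PdmParams = PdmParams()) -> list[PDM]:
    """The 53 PDMs (interacting types 1..53) around one surface atom."""
    atom = s.atoms[atom_index]
    if not atom.is_surface:
        raise ValueError(f"atom {atom.serial} is buried (SASA = 0)")
    frame = atom_frame(s, atom_index)
    conf = residue_conformations(s)[atom.residue_key]
    key = ContextKey(atom.type_id, atom.resname, conf)
    groups, _ = db.query(key)
    free = _free_space_mask(s, atom_index, frame, params)
    n = free.shape[0]
    pdms = []
    for t in range(1, 54):
        pts = groups.get(t)
        if pts is None or len(pts) == 0:
            pdms.append(PDM(t, np.zeros((n, n, n)), params.spacing,
                            atom.coord, frame, 0.0))
            continue
        pts = _cap_records(pts[np.linalg.norm(pts, axis=1) <= params.radius * np.sqrt(3)],
                           params.max_records)
        if len(pts) == 0:
            pdms.append(PDM(t, np.zeros((n, n, n)), params.spacing,
                            atom.coord, frame, 0.0))
            continue
        grid = _splat(pts, params)
        grid[~free] = 0.0
        mass = grid.sum() * params.spacing**3
        if mass > 0:
            grid = grid / mass
        pdms.append(PDM(t, grid, params.spacing, atom.coord, frame, float(mass)))
    return pdms


def pdm_attribute(pdm: PDM, query_type_id: int, shell_delta: float = 1.0,
                  scale: float = 1.0) -> float:
    """Contact-shell density mass of a PDM, rescaled to [0, 1].

    The shell is [r_q + r_t - delta, r_q + r_t + delta] around the query
    atom, with radii from the packaged type table; ``scale`` is the
    corpus-level normalizing constant for this attribute.
    """
    if pdm.normalization == 0.0 or pdm.grid.sum() == 0.0:
        return 0.0
    r_shell = vdw_radius(query_type_id) + vdw_radius(pdm.interacting_type)
    n = pdm.grid.shape[0]
    half = (n - 1) * pdm.spacing / 2.0
    rr = _grid_radii(half, pdm.spacing)
    mask = (rr >= r_shell - shell_delta) & (rr <= r_shell + shell_delta)
    raw = float(pdm.grid[mask].sum() * pdm.spacing**3)
    return float(np.clip(raw / scale if scale > 0 else raw, 0.0, 1.0))


@lru_cache(maxsize=4)
def _geometry_lattice(radius: float, spacing: float):
    half = int(np.floor(radius / spacing))
    g = spacing * np.arange(-half, half + 1)
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1)
    inside = np.sqrt((pts**2).sum(axis=-1)) <= radius
    return g, pts, inside


def geometry_attribute(s: Structure, atom_index: int, radius: float = 10.0,
                       spacing: float = 0.5, frame: np.ndarray | None = None) -> float:
    """Free-volume fraction of the sphere around an atom.

    Deterministic estimate on a fixed cubic lattice of sample points
    (default 0.5 Å) inside the ``radius`` sphere: a point counts as occupied
    when it falls strictly inside any protein atom's van der Waals sphere
    (including the query atom's own volume).  Passing the atom's local
    ``frame`` aligns the lattice with it, which makes the estimate exactly
    invariant under rigid motion of the structure.
    """
    g, pts, inside = _geometry_lattice(radius, spacing)
    center = s.atoms[atom_index].coord
    coords = s.coords
    radii = s.radii
    occupied = np.zeros(pts.shape[:3], bool)
    m = len(g)
    for j in s.kdtree().query_ball_point(center, radius + radii.max()):
        d = coords[j] - center
        if frame is not None:
            d = frame.T @ d
        r = radii[j]
        lo = np.searchsorted(g, d - r)
        hi = np.searchsorted(g, d + r, side="right")
        sl = tuple(slice(max(0, int(lo[k])), min(m, int(hi[k]))) for k in range(3))
        if any(sli.start >= sli.stop for sli in sl):
            continue
        sub = pts[sl] - d
        occupied[sl] |= (sub**2).sum(axis=-1) < r * r
    n_inside = int(inside.sum())
    n_occ = int((occupied & inside).sum())
    return 1.0 - n_occ / n_inside


class AttributeNormalizer:
    """Corpus-level rescaling of the 53 raw PDM attributes.

    The scale for each attribute is a high percentile (default 99th) of its
    raw values over a training corpus, which is robust to outliers; applied
    values are clipped to [0, 1].  The geometry attribute is already a
    fraction and passes through unchanged.
    """

    def __init__(self, scales: np.ndarray):
        scales = np.asarray(scales, float)
        if scales.shape != (N_PDM_ATTRIBUTES,):
            raise ValueError("need one scale per PDM attribute")
        self.scales = np.where(scales > 0, scales, 1.0)

    @classmethod
    def fit(cls, raw_attributes: np.ndarray, percentile: float = 99.0) -> "AttributeNormalizer":
        raw = np.asarray(raw_attributes, float)
        if raw.ndim != 2 or raw.shape[1] not in (N_PDM_ATTRIBUTES, N_ATTRIBUTES):
            raise ValueError("raw attribute table must have 53 or 54 columns")
        scales = np.percentile(raw[:, :N_PDM_ATTRIBUTES], percentile, axis=0)
        return cls(scales)

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, float)
        out = raw.copy().astype(float)
        out[..., :N_PDM_ATTRIBUTES] = np.clip(
            raw[..., :N_PDM_ATTRIBUTES] / self.scales, 0.0, 1.0)
        return out

    def save(self, path) -> None:
        np.savez(path, scales=self.scales)

    @classmethod
    def load(cls, path) -> "AttributeNormalizer":
        return cls(np.load(path)["scales"])


def attribute_vector(s: Structure, atom_index: int, db: InteractionDatabase,
                     params: PdmParams = PdmParams(),
                     normalizer: AttributeNormalizer | None = None,
                     _context=None) -> np.ndarray:
    """The 54-attribute input vector for one surface atom.

    Attributes 1..53 follow the type-table order; attribute 54 is the
    geometry attribute.  Without a normalizer the PDM attributes are raw
    shell masses (still in [0, 1] because each PDM has unit total mass).
    """
    atom = s.atoms[atom_index]
    if not atom.is_surface:
        raise ValueError(f"atom {atom.serial} is buried (SASA = 0)")
    if _context is None:
        frame = atom_frame(s, atom_index)
        conf = residue_conformations(s)[atom.residue_key]
    else:
        adj, confs = _context
        frame = atom_frame(s, atom_index, adj)
        conf = confs[atom.residue_key]
    key = ContextKey(atom.type_id, atom.resname, conf)
    groups, _ = db.query(key)
    values = np.zeros(N_ATTRIBUTES)
    if groups:
        free = _free_space_mask(s, atom_index, frame, params)
        half = (free.shape[0] - 1) * params.spacing / 2.0
        rr = _grid_radii(half, params.spacing)
        r_q = vdw_radius(atom.type_id)
        for t, pts in groups.items():
            pts = _cap_records(
                pts[np.linalg.norm(pts, axis=1) <= params.radius * np.sqrt(3)],
                params.max_records)
            if len(pts) == 0:
                continue
            grid = _splat(pts, params)
            grid[~free] = 0.0
            mass = grid.sum()
            if mass <= 0:
                continue
            r_shell = r_q + vdw_radius(t)
            mask = (rr >= r_shell - params.shell_delta) & (rr <= r_shell + params.shell_delta)
            values[t - 1] = grid[mask].sum() / mass
    values[N_ATTRIBUTES - 1] = geometry_attribute(s, atom_index, frame=frame)
    if normalizer is not None:
        values = normalizer.apply(values)
    return values


_META_COLUMNS = ["atom_index", "chain", "resseq", "icode", "resname",
                 "atom_name", "type_id"]


def attribute_columns() -> list[str]:
    return [f"a{i:02d}" for i in range(1, 54)] + ["geom"]


def featurize_structure(s: Structure, db: InteractionDatabase,
                        params: PdmParams = PdmParams(),
                        normalizer: AttributeNormalizer | None = None) -> pd.DataFrame:
    """Attribute table for all surface atoms of a structure.

    Returns a DataFrame with atom metadata columns followed by the 54
    attribute columns ``a01..a53, geom``.
    """
    import warnings

    adj = covalent_bond_graph(s)
    confs = residue_conformations(s)
    rows = []
    for i in s.surface_indices():
        if not adj[int(i)]:  # no covalent neighbor -> no local frame
            warnings.warn(
                f"atom {s.atoms[int(i)].serial} has no covalent neighbor; skipped",
                stacklevel=2)
            continue
        v = attribute_vector(s, int(i), db, params, normalizer, _context=(adj, confs))
        a = s.atoms[int(i)]
        rows.append([int(i), a.chain, a.resseq, a.icode, a.resname, a.name,
                     a.type_id, *v])
    return pd.DataFrame(rows, columns=_META_COLUMNS + attribute_columns())
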