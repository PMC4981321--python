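"""PDM reconstruction, contact-shell attributes and the geometry attribute."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pdmsite.features import (
    AttributeNormalizer,
    PdmParams,
    attribute_vector,
    build_pdms,
    featurize_structure,
    geometry_attribute,
    pdm_attribute,
)
from pdmsite.interaction_db import (
    ContextKey,
    InteractionDatabase,
    InteractionRecord,
    atom_frame,
    residue_conformations,
)
from pdmsite.structure import LigandInstance

from conftest import make_structure


@pytest.fixture()
def pair_structure():
    """Two bonded atoms far from everything: surface, frame well-defined."""
    return make_structure([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]],
                          type_ids=[8, 8], resseqs=[1, 1])


def _key_for(s, i):
    conf = residue_conformations(s)[s.atoms[i].residue_key]
    return ContextKey(s.atoms[i].type_id, s.atoms[i].resname, conf)


def test_empty_db_gives_53_zero_pdms(pair_structure):
    pdms = build_pdms(pair_structure, 0, InteractionDatabase())
    assert len(pdms) == 53
    assert [p.interacting_type for p in pdms] == list(range(1, 54))
    assert all(p.grid.sum() == 0 for p in pdms)
    n = pdms[0].grid.shape[0]
    assert n % 2 == 1  # query atom on a grid node


def test_single_record_reconstruction(pair_structure):
    s = pair_structure
    db = InteractionDatabase()
    db.add(_key_for(s, 0), InteractionRecord(35, np.array([3.0, 0.0, 0.0]), "ligand"))
    pdms = build_pdms(s, 0, db)
    p35 = pdms[34]
    assert p35.total_mass() == pytest.approx(1.0, abs=1e-9)
    others = [p for p in pdms if p.interacting_type != 35]
    assert all(p.grid.sum() == 0 for p in others)
    # mode within one grid spacing of the world-mapped point
    frame = atom_frame(s, 0)
    world_target = s.atoms[0].coord + frame @ np.array([3.0, 0.0, 0.0])
    idx = np.unravel_index(np.argmax(p35.grid), p35.grid.shape)
    mode_world = p35.world_points().reshape(*p35.grid.shape, 3)[idx]
    assert np.linalg.norm(mode_world - world_target) <= p35.spacing + 1e-9


def test_density_masked_inside_protein(pair_structure):
    s = pair_structure
    db = InteractionDatabase()
    # record placed inside the bonded neighbor's vdW sphere
    db.add(_key_for(s, 0), InteractionRecord(35, np.array([1.5, 0.0, 0.0]), "ligand"))
    pdms = build_pdms(s, 0, db)
    p35 = pdms[34]
    pts = p35.world_points()
    inside0 = np.linalg.norm(pts - s.atoms[0].coord, axis=1) < 1.87
    inside1 = np.linalg.norm(pts - s.atoms[1].coord, axis=1) < 1.87
    dens = p35.grid.reshape(-1)
    assert np.all(dens[inside0] == 0.0)
    assert np.all(dens[inside1] == 0.0)


def test_buried_atom_rejected():
    from pdmsite.geometry import fibonacci_sphere

    shell = 3.0 * fibonacci_sphere(120)
    s = make_structure(np.vstack([[0.0, 0.0, 0.0], shell]))
    with pytest.raises(ValueError, match="buried"):
        build_pdms(s, 0, InteractionDatabase())


def test_pdm_attribute_zero_and_shell_mass(pair_structure):
    s = pair_structure
    empty = build_pdms(s, 0, InteractionDatabase())[0]
    assert pdm_attribute(empty, 8) == 0.0
    db = InteractionDatabase()
    # delta-like distribution exactly at contact distance r_8 + r_35
    r_shell = 1.87 + 1.91
    db.add(_key_for(s, 0), InteractionRecord(35, np.array([0.0, 0.0, r_shell]), "ligand"))
    pdm = build_pdms(s, 0, db)[34]
    raw = pdm_attribute(pdm, 8)
    # the unit mass sits at the shell center; the smoothing kernel leaks a
    # predictable fraction out of the +-1 A shell
    assert raw > 0.7
    # doubling multiplicity leaves the normalized attribute unchanged
    db.add(_key_for(s, 0), InteractionRecord(35, np.array([0.0, 0.0, r_shell]), "ligand"))
    pdm2 = build_pdms(s, 0, db)[34]
    assert pdm_attribute(pdm2, 8) == pytest.approx(raw, abs=1e-9)


def test_geometry_attribute_single_sphere_analytic():
    s = make_structure([[0.0, 0.0, 0.0]], type_ids=[8])
    got = geometry_attribute(s, 0, radius=10.0, spacing=0.5)
    assert got == pytest.approx(1.0 - (1.87 / 10.0) ** 3, abs=0.002)


def test_geometry_attribute_dense_block_below_convex():
    g = np.arange(-3, 4) * 2.0
    block = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
    s = make_structure(block)
    center_idx = int(np.argmin(np.linalg.norm(block, axis=1)))
    corner_idx = int(np.argmax(np.linalg.norm(block, axis=1)))
    g_center = geometry_attribute(s, center_idx)
    g_corner = geometry_attribute(s, corner_idx)
    assert g_center < g_corner


def test_geometry_pocket_below_ridge(fixture_complex):
    from pdmsite.structure import ligand_contact_atoms

    s, ligs, _ = fixture_complex
    contacts = ligand_contact_atoms(s, ligs[0], 4.5)
    surf = s.surface_indices()
    pocket = [int(i) for i in surf if i in contacts]
    r = np.linalg.norm(s.coords - s.coords.mean(0), axis=1)
    ridge = [int(i) for i in surf
             if i not in contacts and r[i] > np.percentile(r[surf], 85)]
    g_pocket = np.mean([geometry_attribute(s, i) for i in pocket])
    g_ridge = np.mean([geometry_attribute(s, i) for i in ridge[:40]])
    assert g_pocket < g_ridge


def test_attribute_vector_shape_and_empty_db(pair_structure):
    v = attribute_vector(pair_structure, 0, InteractionDatabase())
    assert v.shape == (54,)
    assert np.all(v[:53] == 0.0)
    assert v[53] > 0.0
    assert np.all(np.isfinite(v))


def test_attribute_vector_rigid_invariance(fixture_complex, fixture_db):
    s = fixture_complex[0]
    i = int(s.surface_indices()[10])
    v = attribute_vector(s, i, fixture_db)
    R = Rotation.from_euler("zyx", [15.0, 71.0, -40.0], degrees=True).as_matrix()
    s2 = s.transformed(R, np.array([3.0, -8.0, 12.0]))
    from pdmsite.structure import compute_sasa

    compute_sasa(s2)
    v2 = attribute_vector(s2, i, fixture_db)
    assert np.allclose(v, v2, atol=1e-6)


def test_attribute_monotone_in_shell_records(pair_structure):
    s = pair_structure
    r_shell = 1.87 + 1.91
    db = InteractionDatabase()
    key = _key_for(s, 0)
    rng = np.random.default_rng(9)
    # background records away from the shell
    for _ in range(5):
        db.add(key, InteractionRecord(35, np.array([0.0, 0.0, 1.0]), "ligand"))
    prev = attribute_vector(s, 0, db)[34]
    for _ in range(4):
        u = rng.normal(size=3)
        u = u / np.linalg.norm(u) * r_shell
        if u @ np.array([1.0, 0, 0]) > 0:  # keep it outside the bonded neighbor
            u = -u
        db.add(key, InteractionRecord(35, u, "ligand"))
        cur = attribute_vector(s, 0, db)[34]
        assert cur >= prev - 1e-9
        prev = cur


def test_normalizer_rescaling_and_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    raw = rng.uniform(0, 0.2, (200, 54))
    norm = AttributeNormalizer.fit(raw)
    out = norm.apply(raw)
    assert out[:, :53].max() <= 1.0
    assert np.all(out[:, :53] >= 0.0)
    assert np.allclose(out[:, 53], raw[:, 53])  # geometry passes through
    path = tmp_path / "norm.npz"
    norm.save(path)
    again = AttributeNormalizer.load(path)
    assert np.array_equal(norm.scales, again.scales)


def test_featurize_structure_columns(fixture_complex, fixture_db):
    s = fixture_complex[0]
    table = featurize_structure(s, fixture_db)
    assert len(table) == len(s.surface_indices())
    cols = [f"a{i:02d}" for i in range(1, 54)] + ["geom"]
    assert all(c in table.columns for c in cols)
    vals = table[cols].to_numpy(float)
    assert vals.shape[1] == 54
    assert np.all(np.isfinite(vals))
    assert vals[:, 53].min() > 0  # geometry attribute is never zero on a surface atom
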