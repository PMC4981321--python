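"""Complex filtering, conformational classes, local frames and harvesting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pdmsite.geometry import local_frame
from pdmsite.interaction_db import (
    ComplexMetadata,
    ContextKey,
    InteractionDatabase,
    InteractionRecord,
    conformation_class,
    covalent_bond_graph,
    filter_complexes,
    harvest,
    residue_conformations,
    sequence_identity,
)


def meta(**overrides) -> ComplexMetadata:
    base = dict(pdb_id="GOOD", method="X-RAY DIFFRACTION", resolution=2.0,
                has_nucleic_in_atom=False, ca_only=False, covalent_ligand=False,
                n_ligand_atoms=12, n_interacting_atoms=20,
                seq="ACDEFGHIKLMNPQRSTVWY", ligand_code="ATP")
    base.update(overrides)
    return ComplexMetadata(**base)


@pytest.mark.parametrize("bad", [
    dict(pdb_id="NMR", method="SOLUTION NMR"),
    dict(pdb_id="LOWRES", resolution=3.2),
    dict(pdb_id="NUC", has_nucleic_in_atom=True),
    dict(pdb_id="CAONLY", ca_only=True),
    dict(pdb_id="COV", covalent_ligand=True),
    dict(pdb_id="SMALL", n_ligand_atoms=9),
    dict(pdb_id="FEWINT", n_interacting_atoms=14),
])
def test_filter_removes_each_criterion(bad):
    report = {}
    kept = filter_complexes([meta(), meta(**bad)], report=report)
    assert [m.pdb_id for m in kept] == ["GOOD"]
    assert bad["pdb_id"] in report


def test_filter_accepts_clean_entry():
    assert [m.pdb_id for m in filter_complexes([meta()])] == ["GOOD"]


def test_filter_missing_field_lists_it():
    with pytest.raises(ValueError, match="resolution"):
        filter_complexes([meta(resolution=None)])


def test_redundancy_removed_same_ligand():
    a = meta(pdb_id="A", resolution=1.5, seq="ACDEFGHIKLMNPQRSTVWY" * 3)
    b = meta(pdb_id="B", resolution=2.5,
             seq=("ACDEFGHIKLMNPQRSTVWY" * 3)[:-3] + "AAA")  # ~95% identical
    kept = filter_complexes([a, b])
    assert [m.pdb_id for m in kept] == ["A"]  # best resolution retained
    # different ligand codes: both survive
    kept2 = filter_complexes([a, meta(pdb_id="B", resolution=2.5,
                                      seq=a.seq, ligand_code="GTP")])
    assert {m.pdb_id for m in kept2} == {"A", "B"}


def test_filter_idempotent():
    candidates = [meta(pdb_id=f"S{i}", seq="ACDEFG" * 10, resolution=1.0 + i / 10)
                  for i in range(3)] + [meta(pdb_id="OK", seq="WYWYWY" * 10)]
    once = filter_complexes(candidates)
    twice = filter_complexes(once)
    assert [m.pdb_id for m in once] == [m.pdb_id for m in twice]


def test_sequence_identity_bounds():
    assert sequence_identity("ACDEF", "ACDEF") == pytest.approx(1.0)
    assert sequence_identity("AAAA", "WWWW") == pytest.approx(0.0)


@pytest.mark.parametrize("phi,psi,chi1,expected", [
    (-60.0, -45.0, -60.0, "H/g-"),
    (-120.0, 130.0, 65.0, "E/g+"),
    (-120.0, 130.0, 175.0, "E/t"),
    (60.0, 60.0, None, "O/none"),
    (None, -45.0, -60.0, "other"),
    (-60.0, None, None, "other"),
])
def test_conformation_class_bins(phi, psi, chi1, expected):
    assert conformation_class(phi, psi, chi1) == expected


def test_residue_conformations_deterministic(fixture_complex):
    s = fixture_complex[0]
    confs = residue_conformations(s)
    assert set(confs) == set(s.residues)
    assert confs == residue_conformations(s)


def test_local_frame_orthonormal_and_right_handed():
    F = local_frame([0, 0, 0], [[1.5, 0, 0], [0, 1.5, 0]])
    assert np.allclose(F.T @ F, np.eye(3), atol=1e-12)
    assert np.linalg.det(F) == pytest.approx(1.0)


def test_local_frame_rotates_with_molecule():
    rng = np.random.default_rng(5)
    central = np.array([1.0, 2.0, 3.0])
    bonded = [central + rng.normal(0, 1, 3) for _ in range(3)]
    F = local_frame(central, bonded)
    for _ in range(5):
        R = Rotation.random(random_state=rng.integers(1 << 16)).as_matrix()
        F2 = local_frame(R @ central, [R @ b for b in bonded])
        assert np.allclose(F2, R @ F, atol=1e-9)


def test_local_frame_collinear_falls_back_orthonormal():
    F = local_frame([0, 0, 0], [[1.5, 0, 0], [-1.5, 0, 0]])
    assert np.allclose(F.T @ F, np.eye(3), atol=1e-12)
    with pytest.raises(ValueError):
        local_frame([0, 0, 0], [])


def test_harvest_matches_brute_force_count(fixture_complex):
    s, ligs, waters = fixture_complex
    records = harvest(s, ligs, waters, cutoff=4.5)
    # brute-force oracle over all pairs
    coords = s.coords
    surface = set(int(i) for i in s.surface_indices())
    adj = covalent_bond_graph(s)
    framable = {i for i in surface if adj[i]}
    expected = 0
    for i in framable:
        ai = s.atoms[i]
        for j in range(len(s)):
            if j == i:
                continue
            aj = s.atoms[j]
            if aj.chain == ai.chain and abs(aj.resseq - ai.resseq) < 2:
                continue
            if np.linalg.norm(coords[j] - coords[i]) <= 4.5:
                expected += 1
        for lig in ligs:
            expected += int(np.sum(
                np.linalg.norm(lig.coords - coords[i], axis=1) <= 4.5))
    assert len(records) == expected


def test_harvest_decoy_has_no_ligand_records(fixture_spec):
    from pdmsite.pipeline import load_complex
    from pdmsite.synthetic import make_decoy_complex

    s, ligs, waters = load_complex(make_decoy_complex(fixture_spec))
    records = harvest(s, ligs, waters)
    assert all(r.source_class != "ligand" for _, r in records)


def test_harvest_pose_invariant(fixture_complex):
    s, ligs, waters = fixture_complex
    base = harvest(s, ligs, waters)
    R = Rotation.from_euler("xyz", [31.0, -54.0, 77.0], degrees=True).as_matrix()
    t = np.array([11.0, -7.0, 3.0])
    s2 = s.transformed(R, t)
    from pdmsite.structure import LigandInstance

    ligs2 = [LigandInstance(l.het_code, l.elements, l.type_ids,
                            l.coords @ R.T + t) for l in ligs]
    rot = harvest(s2, ligs2, waters @ R.T + t if len(waters) else waters)
    assert len(base) == len(rot)
    a = np.sort(np.array([r.local_coord for _, r in base]), axis=0)
    b = np.sort(np.array([r.local_coord for _, r in rot]), axis=0)
    assert np.allclose(a, b, atol=1e-6)


def test_database_query_fallback_levels():
    db = InteractionDatabase()
    key = ContextKey(3, "ALA", "H/none")
    db.add(key, InteractionRecord(35, np.array([1.0, 2.0, 3.0]), "ligand"))
    groups, level = db.query(key)
    assert level == 0 and 35 in groups
    groups, level = db.query(ContextKey(3, "ALA", "E/t"))
    assert level == 1 and len(groups[35]) == 1
    groups, level = db.query(ContextKey(3, "GLY", "E/t"))
    assert level == 2 and 35 in groups
    groups, level = db.query(ContextKey(9, "GLY", "E/t"))
    assert level == 2 and groups == {}


def test_database_round_trip_exact(tmp_path, fixture_complex):
    s, ligs, waters = fixture_complex
    db = InteractionDatabase()
    db.extend(harvest(s, ligs, waters))
    path = tmp_path / "db.npz"
    db.save(path)
    again = InteractionDatabase.load(path)
    assert len(again) == len(db)
    assert again.source_counts() == db.source_counts()
    for key in db.keys:
        g1, _ = db.query(key)
        g2, _ = again.query(key)
        assert set(g1) == set(g2)
        for t in g1:
            assert np.array_equal(np.sort(g1[t], axis=0), np.sort(g2[t], axis=0))
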