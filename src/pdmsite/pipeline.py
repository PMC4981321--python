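"""End-to-end orchestration: corpus -> database -> features -> models -> sites.

These functions glue the pipeline stages together for the command-line
tools, the test suite and reproduction scripts.  Structures travel as
parsed :class:`~pdmsite.structure.Structure` objects with SASA computed
ligand-free; examples travel as pandas feature tables with one row per
surface atom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import (
    AttributeNormalizer,
    PdmParams,
    attribute_columns,
    featurize_structure,
)
from .interaction_db import InteractionDatabase, harvest
from .metrics import Confusion, bdt_score, confusion_metrics
from .predictor import TypedPredictor, crossvalidate_10fold
from .sites import (
    actual_residues_fractional,
    actual_residues_vdw,
    assemble_patches,
    residue_predictions,
    success_top1,
)
from .structure import (
    Structure,
    compute_sasa,
    extract_ligands,
    extract_waters,
    ligand_contact_atoms,
    parse_structure,
    superpose_and_center_distance,
)

__all__ = [
    "load_complex",
    "build_database",
    "featurize_corpus",
    "label_examples",
    "predict_sites",
    "evaluate_structure",
    "run_corpus_crossvalidation",
]

CONTACT_CUTOFF = 4.5


def load_complex(pdb_text: str, chain: str | None = None):
    """Parse a holo complex: (structure with SASA, ligands, waters)."""
    s = parse_structure(pdb_text, chain)
    compute_sasa(s)
    ligands = extract_ligands(pdb_text)
    waters = extract_waters(pdb_text)
    return s, ligands, waters


def build_database(complexes, cutoff: float = CONTACT_CUTOFF) -> InteractionDatabase:
    """Harvest interaction records from parsed complexes into one database.

    ``complexes`` iterates over (structure, ligands, waters) triples as
    produced by :func:`load_complex`.
    """
    db = InteractionDatabase()
    for s, ligands, waters in complexes:
        db.extend(harvest(s, ligands, waters, cutoff=cutoff))
    return db


def label_examples(s: Structure, ligands, cutoff: float = CONTACT_CUTOFF) -> dict[int, int]:
    """Binary labels for surface atoms: 1 iff within cutoff of a ligand atom."""
    positive: set[int] = set()
    for lig in ligands:
        positive |= ligand_contact_atoms(s, lig, cutoff)
    return {int(i): int(i in positive) for i in s.surface_indices()}


def featurize_corpus(corpus_complexes, db: InteractionDatabase,
                     params: PdmParams = PdmParams(),
                     normalizer_percentile: float = 99.0):
    """Feature table + fitted normalizer for a corpus.

    ``corpus_complexes`` iterates over (structure_id, structure, ligands)
    with SASA precomputed.  Raw attributes are computed for every surface
    atom, the corpus-level normalizer is fit on them, and normalized
    attributes are returned along with contact labels.
    """
    frames = []
    for sid, s, ligands in corpus_complexes:
        table = featurize_structure(s, db, params)
        labels = label_examples(s, ligands)
        table.insert(0, "structure_id", sid)
        table["label"] = [labels[int(i)] for i in table["atom_index"]]
        frames.append(table)
    examples = pd.concat(frames, ignore_index=True)
    cols = attribute_columns()
    normalizer = AttributeNormalizer.fit(
        examples[cols].to_numpy(float), normalizer_percentile)
    examples[cols] = normalizer.apply(examples[cols].to_numpy(float))
    return examples, normalizer


def predict_sites(s: Structure, db: InteractionDatabase,
                  predictor: TypedPredictor,
                  normalizer: AttributeNormalizer | None = None,
                  params: PdmParams = PdmParams(),
                  seed_threshold: float = 0.50,
                  member_threshold: float = 0.10,
                  member_radius: float = 5.0,
                  merge_distance: float = 10.0):
    """Predict binding sites on one structure.

    Returns ``(table, confidences, patches)``: the per-surface-atom feature/
    prediction table, a dense per-atom confidence array (zero for buried
    atoms), and the ranked patches.
    """
    table = featurize_structure(s, db, params, normalizer)
    table.insert(0, "structure_id", "query")
    pred = predictor.predict(table)
    conf = np.zeros(len(s))
    conf[pred["atom_index"].to_numpy(int)] = pred["confidence"].to_numpy(float)
    patches = assemble_patches(s, conf, seed_threshold, member_threshold,
                               member_radius, merge_distance)
    return pred, conf, patches


def evaluate_structure(s: Structure, lig, patches,
                       vdw_tolerance: float = 0.5,
                       d0: float = 5.0) -> dict:
    """Per-structure benchmark of the top-ranked predicted site.

    Residue-level confusion metrics are computed under both actual-site
    definitions (fractional-contact and van der Waals), plus the BDT score
    and the top-1 center success flag.
    """
    actual_frac = actual_residues_fractional(s, lig)
    actual_vdw = actual_residues_vdw(s, lig, vdw_tolerance)
    report: dict = {"n_sites": len(patches),
                    "success_top1": success_top1(patches, lig)}
    all_res = list(s.residues)
    if patches:
        preds = residue_predictions(s, patches[0])
        predicted = {p.residue_key for p in preds if p.predicted}
    else:
        predicted = set()
    ca = s.ca_coords()
    for tag, actual in (("frac", actual_frac), ("vdw", actual_vdw)):
        conf = Confusion.from_labels(
            [k in predicted for k in all_res],
            [k in actual for k in all_res],
        )
        metrics = confusion_metrics(conf)
        report.update({f"{m}_{tag}": v for m, v in metrics.items()})
    if predicted and actual_frac:
        report["BDT"] = bdt_score(
            np.array([ca[k] for k in predicted if k in ca]),
            np.array([ca[k] for k in actual_frac if k in ca]),
            d0=d0,
        )
    else:
        report["BDT"] = float("nan")
    return report


def run_corpus_crossvalidation(examples: pd.DataFrame, seed: int = 0,
                               feature_indices=None, config=None, n_folds: int = 10):
    """Structure-level cross-validation (thin wrapper, see predictor module)."""
    from .predictor import PredictorConfig

    return crossvalidate_10fold(examples, seed=seed,
                                config=config or PredictorConfig(),
                                feature_indices=feature_indices,
                                n_folds=n_folds)


def residue_level_results(examples_pred: pd.DataFrame, structures: dict,
                          ligands: dict,
                          seed_threshold: float = 0.50,
                          member_threshold: float = 0.10,
                          member_radius: float = 5.0,
                          merge_distance: float = 10.0) -> pd.DataFrame:
    """Residue-level per-structure evaluation of cross-validation predictions.

    ``examples_pred`` is the prediction table from cross-validation
    (columns structure_id, atom_index, confidence); ``structures`` and
    ``ligands`` map structure ids to parsed objects.
    """
    rows = []
    for sid, sub in examples_pred.groupby("structure_id"):
        s = structures[sid]
        conf = np.zeros(len(s))
        conf[sub["atom_index"].to_numpy(int)] = sub["confidence"].to_numpy(float)
        patches = assemble_patches(s, conf, seed_threshold, member_threshold,
                                   member_radius, merge_distance)
        report = evaluate_structure(s, ligands[sid], patches)
        report["structure_id"] = sid
        rows.append(report)
    return pd.DataFrame(rows)


def apo_holo_center_distance(holo: Structure, apo: Structure,
                             holo_patches, apo_patches) -> float:
    """Distance between top-1 patch centers of holo and apo predictions.

    The apo structure is superposed onto the holo structure through the
    corresponding C-alpha atoms before the distance is measured.  Returns
    ``inf`` when either prediction is empty.
    """
    if not holo_patches or not apo_patches:
        return float("inf")
    return superpose_and_center_distance(
        apo, holo, apo_patches[0].center, holo_patches[0].center)
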