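# pdmsite

Prediction of ligand binding sites (LBSs) on protein surfaces from
3-dimensional probability density maps (PDMs) of interacting atoms.

Structure-based function annotation and structure-based drug design both
start from the question: *where on this protein would a small molecule
bind?* Template-based predictors answer it well when a homologous
protein–ligand complex is known, but fail on novel folds and degrade on
computationally modeled structures. `pdmsite` implements a
template-independent, machine-learning approach: the statistics of
non-covalent atomistic contacts harvested from complexes of known
structure are remapped onto the query surface as 3D probability densities,
summarized into per-atom attributes, and scored by per-atom-type neural
ensembles whose calibrated confidences are assembled into ranked
binding-site patches.

## The model

- Every protein heavy atom gets one of **30 protein atom types**; water
  oxygen is type 31; ligand atoms get one of **22 Sybyl types** (C.3, C.ar,
  O.co2, ...), each type with a van der Waals radius.
- An **interaction database** stores, for every surface atom of every
  curated complex, the displacement (in the atom's local covalent frame)
  and type of each non-covalent contact within 4.5 Å, keyed by atom type ×
  residue type × backbone/rotamer conformational class.
- For a query surface atom *q*, the records retrieved by its context key
  are accumulated into **53 PDMs** (one per interacting type *t*), masked
  against the protein's van der Waals volume and normalized to unit mass.
  Attribute *t* is the PDM mass in the contact shell
  `[r_q + r_t − 1 Å, r_q + r_t + 1 Å]`; attribute 54 is the fraction of
  the 10 Å sphere around *q* free of protein volume. The **54-attribute
  vector** feeds a bagged network ensemble (one per protein atom type);
  outputs are calibrated to comparable confidence levels.
- Surface atoms with confidence > 0.5 seed patches, neighbors within 5 Å
  with confidence > 0.1 join, seeds closer than 10 Å merge; patches are
  ranked by summed confidence. Residues with more than 30% of their
  surface atoms in a patch form the residue-level prediction.
- Evaluation: accuracy, precision, sensitivity, specificity, F-score and
  MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); the binding-site
  distance test BDT = Σᵢ maxⱼ Sᵢⱼ / max(Np, No) with
  Sᵢⱼ = 1/(1+(dᵢⱼ/d₀)²), d₀ = 5 Å; and the top-1 success criterion
  (top patch center within 4 Å of the ligand).

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Everything below runs offline on synthetic complexes (a designed concave
pocket holding a 13-atom aromatic ligand) produced by the package's own
generator:

```bash
pdmsite make-fixtures --n 10 --seed 5 --out work/fixtures
pdmsite build-db --input work/fixtures --out work/db.npz --seed 5
pdmsite train --input work/fixtures --db work/db.npz --out work/model --seed 5
pdmsite predict --pdb work/fixtures/SYN000.pdb --db work/db.npz \
    --model work/model --out work/pred/syn000 --seed 5
pdmsite evaluate --pdb work/fixtures/SYN000.pdb \
    --predictions work/pred/syn000_atoms.tsv --out work/eval.tsv --seed 5
```

The run prints:

```
wrote 11 files to work/fixtures
10 complexes accepted, 0 rejected; 14017 records ({'protein': 13326, 'water': 0, 'ligand': 691})
trained 14 atom-type models -> work/model
3 patch(es) predicted; outputs at work/pred/syn000_*
ligand LIG: MCC(frac) 0.802 BDT 0.667 top-1 success True
```

Reading the output: the database harvested ~14k interacting-atom records
from the 10 complexes; 14 atom-type predictors had enough examples to
train; on the first complex the method predicts three ranked patches, and
the top-ranked one reaches residue-level MCC 0.802 against the actual
pocket residues, with a BDT of 0.667 and its geometry center within 4 Å of
the ligand (a top-1 success). `predict` also writes a PDB whose B-factor
column holds the per-atom confidence × 100 for structure viewers, plus
patch and residue tables.

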