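# Methods

`pdmsite` predicts ligand binding sites (LBSs) on protein surfaces from the
statistics of non-covalent atomistic contacts observed in complexes of known
structure. This note documents the model, its parameters, the synthetic
study system, and the numerical and design choices a maintainer should know
about.

## Model overview

Every protein heavy atom is assigned one of 30 protein atom types (a
chemical-environment partition of the heavy atoms of the 20 standard amino
acids); water oxygen is type 31 and ligand heavy atoms receive one of 22
Sybyl-style types (C.3, C.ar, O.co2, ...), each type carrying a van der
Waals radius. The pipeline has five stages:

1. **Interaction database.** For each surface atom (SASA > 0) of each
   curated complex, every non-covalently contacting heavy atom within
   4.5 Å — protein atoms of sequence-non-adjacent residues, water oxygens,
   ligand atoms — is recorded as a displacement vector in the central
   atom's local covalent frame, keyed by the central atom's *context*:
   atom type × parent residue type × parent-residue conformational class.
   Complexes enter the database only after filtering (X-ray, resolution
   ≤ 3 Å, no nucleic acids in ATOM records, not Cα-only, no protein–ligand
   covalent link, ≥ 10 ligand atoms, ≥ 15 interacting atoms) and 30%
   sequence-identity deduplication among complexes binding the same ligand.

2. **Probability density maps (PDMs).** For a query surface atom, the
   records retrieved by its context key are accumulated per interacting
   type on a cubic grid with a Gaussian kernel, masked to remove density
   inside the protein's van der Waals volume, and normalized to unit mass —
   a 3D probability density of where atoms of that type sit around atoms
   like the query.

3. **Attributes.** Attribute *t* (t = 1..53) is the PDM-*t* mass inside
   the contact shell `[r_q + r_t − δ, r_q + r_t + δ]` around the query
   atom, rescaled by a corpus-level normalizer (99th percentile of raw
   values) and clipped to [0, 1]. Attribute 54 is the local-geometry
   descriptor: the fraction of the 10 Å sphere around the atom not occupied
   by protein van der Waals volume, estimated on a fixed 0.5 Å lattice.
   Pocket-lining atoms have lower values than convex ridge atoms.

4. **Predictors.** One bagged ensemble of feed-forward networks
   (54 → 10 logistic units → 1 sigmoid) per protein atom type, trained on
   stratified bootstrap resamples with negatives downsampled to ≤ 5:1.
   Raw ensemble outputs ("activities") are normalized to confidence levels
   with a monotone calibration map (equal-count binning of validation
   activities to positive precision, isotonic smoothing), making the 30
   models comparable; per-type decision thresholds maximize validation MCC
   over a 0.01 grid (ties go to the lower threshold).

5. **Patches.** Surface atoms with confidence > 0.50 seed patches; surface
   atoms within 5 Å of a seed with confidence > 0.10 join; seed pairs
   closer than 10 Å merge transitively. Patches are ranked by summed member
   confidence; the patch center is the unweighted mean of member
   coordinates. A residue is a positive call when strictly more than 30%
   of its surface atoms belong to the patch.

Evaluation uses the confusion metrics (accuracy/precision/sensitivity/
specificity on the ×100 scale, F-score, MCC with the MCC = 0 convention for
zero denominators), the binding-site distance test
`BDT = Σᵢ maxⱼ 1/(1+(dᵢⱼ/d₀)²) / max(Np, No)` on Cα distances with
d₀ = 5 Å, and the top-1 success criterion (top patch center within 4 Å of
the nearest ligand heavy atom — the nearest-atom reading was chosen over
ligand-centroid as the conventional one). Actual binding residues are
labeled under two definitions: fractional (> 30% of surface atoms within
4.5 Å of the ligand) and van der Waals (any heavy-atom pair within
r_p + r_l + 0.5 Å). Residue-level benchmark numbers are computed from the
top-ranked patch.

## Parameters

| parameter | default | role |
|---|---|---|
| contact cutoff | 4.5 Å | labeling, harvesting, actual-site definition |
| SASA probe | 1.4 Å (960 sphere points) | surface-atom definition (Shrake–Rupley) |
| PDM grid | half-edge 6 Å, spacing 0.5 Å | density reconstruction volume |
| kernel σ | 0.75 Å | Gaussian smoothing of records |
| shell half-width δ | 1.0 Å | contact-shell integration |
| normalizer percentile | 99 | corpus rescaling, robust to outliers |
| geometry sphere / lattice | 10 Å / 0.5 Å | free-volume fraction |
| hidden units / bags | 10 / 10 | network ensemble (solver lbfgs, max_iter 200) |
| seed / member confidence | 0.50 / 0.10 | patch thresholds (strict) |
| member radius / merge | 5 Å (inclusive) / 10 Å (strict) | patch geometry |
| residue fraction | 0.30 (strict) | residue-level conversion |
| BDT d₀ / success radius | 5 Å / 4 Å | evaluation |

All inequalities follow the wording they implement: "greater than 50%",
"more than 30%", "smaller than 10 Å" are strict; "within 4.5 Å"/"within
4 Å" are inclusive.

## Conformational classes

The published conformational typing of the original database is not
available, so a documented stand-in is used: three backbone classes
(helix-like φ∈[−180,0), ψ∈[−120,45); strand-like φ∈[−180,0), ψ∈[45,225)
mod 360; other) crossed with a χ1 rotamer bin {g+, t, g−, none}. Chain
termini and residues with missing backbone atoms collapse to a single
"other" class. Query keys unseen in the database back off first to
any-conformation, then to any-residue aggregates.

## Frames and rigid invariance

The local frame of an atom is built from its covalent bond directions
(x = mean bond direction, z = normal of the first two independent
directions). With a single bonded neighbor the plane is completed from
second-shell covalent neighbors so the frame — and therefore all harvested
displacements, the PDM grid and the geometry lattice, which are all
expressed in frame coordinates — co-rotates exactly with the molecule.
Only an isolated bonded pair with no second shell falls back to a fixed
global-axis convention. The full 54-attribute vector is invariant under
rigid motion of the structure to 1e-6.

## Synthetic study system

Real training corpora (thousands of curated PDB complexes) are outside the
scope of a test suite, so the generator builds complexes that emulate the
statistical structure the method assumes: a globular protein (ball of real
residue templates on a jittered 5.7 Å lattice, hard-sphere packing, ten
residue types covering 15 protein atom types) with a designed concave
pocket holding a 13-atom organic ligand (benzene core, aminoethyl tail,
aldehyde, hydroxymethyl → C.ar, C.3, C.2, N.3, O.2, O.3). A lining pass
guarantees every ligand atom sits within 4.5 Å of the protein; a mouth
channel keeps the pocket open. Apo counterparts strip the ligand and move
every residue as a rigid body (random ~4° rotation about its centroid plus
a σ = 0.3 Å translation), emulating the side-chain repacking and small
backbone shifts between independently solved apo and holo structures while
preserving covalent geometry — independent per-atom noise would stretch
bonds unphysically and destroy the covalent frames the features are built
on. All randomness flows through the spec seed; outputs are
byte-identical per seed, and corpus metadata passes every database filter
by construction.

What the fixtures do **not** emulate: real secondary structure and chain
connectivity (residues are spatially packed, not covalently linked, so
backbone dihedrals are arbitrary-but-deterministic), realistic residue
composition, water-mediated contacts (no waters are generated), binding-site
chemistry beyond hard spheres, and the diversity of real ligand scaffolds.
Passing corpus-level tests therefore shows the pipeline is wired correctly
and can learn a real geometric/chemical contact signal over a permuted-label
null — not that it reaches the accuracy a model trained on thousands of
real complexes attains.

## Study sizes and observed behavior

Corpus-level checks use a 30-complex study (≈ 11,800 surface-atom
examples, ≈ 860 positives) for the test suite and a 20-complex study in the
reproduction script; 10-fold cross-validation splits at the structure
level (8/1/1 train/validation/test) — atom-level splitting would leak
near-duplicate neighbors of one pocket across splits. On this system the
full 54-attribute set gives a mean atom-level test MCC in the 0.15–0.20
range, beats the label-permuted null in every fold, and outperforms the P
(protein-only), L (ligand-only), LW and LG attribute subsets on average,
with the
ligand-carbon attributes (C.3, C.ar, C.2) the strongest single correlates
of actual contact — the same qualitative ordering the method is built
around. Absolute MCCs are far below what real corpora support, as expected
at this corpus size and chemistry.

## Numerical choices and degenerate inputs

- Alternate locations resolve to the highest occupancy (first on tie);
  hydrogens, waters and hetero groups are excluded from the protein model;
  Cα-only chains are rejected.
- Nonstandard residues with a documented parent (MSE, SEC, HIS protonation
  variants) are remapped with a warning; others are skipped.
- Terminal OXT is typed as backbone carbonyl oxygen (chemically an
  equivalent carboxyl oxygen).
- Ligand bond perception runs through the OpenBabel CLI (connectivity and
  bond orders from 3D coordinates) followed by RDKit aromaticity
  perception; if perception fails, atoms fall back to the sp3 default of
  their element with a warning.
- Covalent bonds are inferred at < 1.9 Å within the same or adjacent
  residues; a protein–ligand pair below 1.9 Å marks the complex covalent.
- Per-type record retrieval is capped at 4000 records by even subsampling
  (deterministic) to bound the density-reconstruction cost.
- Surface atoms without any covalent neighbor (possible in perturbed
  synthetic structures) are skipped by the featurizer with a warning and
  receive confidence 0.
- Atom types absent from training (or single-class) get no model; their
  atoms score activity and confidence 0.
- Atom types whose validation slice is degenerate (single-class) are
  calibrated and thresholded with the pooled cross-type validation set:
  raw activities of different models are not comparable, so leaving them
  uncalibrated would inject unleveled scores into patch assembly.
- An all-zero confusion matrix raises; a zero MCC denominator returns 0.
- Patch-member inclusion is single-shot from seeds (members within 5 Å of
  members do not recruit further); patches may share member atoms when two
  unmerged seed groups both reach an atom.

## Known limitations

- The attribute formulas and network topology of the original server are
  not public; this implementation's variants are documented above and
  parameterized, so exact numeric parity with the original predictions is
  not claimed — the package reproduces the method's structure, decision
  rules and evaluation suite.
- The conformational-class scheme is a stand-in (swappable via the database
  key construction).
- Multi-chain training structures are supported at harvest time, but the
  synthetic corpus is single-chain.
- No mmCIF input, assembly generation, or hydrogen handling.
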