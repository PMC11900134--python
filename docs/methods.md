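# Methods

This note documents the models, the numerical and design choices behind
them, what the synthetic benchmark does and does not establish, and the
known limitations.

## Problem setting

Given a query compound (a small molecule as SMILES, or a peptide as a
one-letter sequence), the system predicts which GPCR in a configured
panel the compound most plausibly targets, how active it is likely to
be, and how confident that call is. Three independent predictors are
trained or run per (receptor, binding-site mode) pair and then vote:

- a multiclass neural classifier over activity ranges,
- a gradient-boosted regression of the pChEMBL value,
- a structure-based docking score.

The legs are deliberately heterogeneous (ligand-based vs target-based,
classification vs regression, neural vs tree ensemble) so their errors
are largely uncorrelated and a k-of-3 agreement rule is meaningful.

## Peptide truncation and assembly

Peptide agonists of opioid, chemokine and secretin-family receptors
activate through a short N-terminal "message" fragment; the remaining
"address" region contributes binding orientation and stability. The
package therefore truncates peptides to their six N-terminal residues
(a C-terminal rule is available for receptor families, such as apelin
or endothelin receptors, whose message is C-terminal) and assembles the
fragment into a molecule by amide condensation of residue building
blocks.

Choices the data did not dictate, exposed as options:

- **C-terminus created by truncation**: free carboxylic acid by default
  (the natural product of residue-dictionary condensation); amide
  capping available (`cterm="amide"`).
- **Stereochemistry**: L-configuration α-carbons encoded by default;
  a flat (achiral) assembly is available. Note the default fingerprint
  ignores chirality, so this only matters when `use_chirality` is on.
- **Protonation**: residues are built neutral. Fingerprints are
  topological, and physiological charge states would fragment the
  feature space without adding signal.

The assembly is validated residue-by-residue and on multimers against
the toolkit's independent peptide parser, and by molecular-formula
arithmetic (a chain of n residues must equal the residue-formula sum
minus n−1 waters).

## Features

ECFP4 — Morgan circular fingerprints of radius 2 (bond diameter 4) —
folded to 2048 bits by default. 2048 is the de-facto standard length;
the tests and the acceptance script use 512 bits to keep matrices small,
which raises the folding-collision rate but does not change any
contract. Chirality is off by default (classic ECFP4 definition);
both settings are explicit configuration, not claims about any
reference system. Folding collisions are logged and reported, not
resolved: a folded bit is allowed to carry several atom environments,
and the fragment decoder reports the first and notes the collision.

Every on bit can be decoded back to its atom environment: the center
atom plus all bonds within the radius, with bonds leaving the
environment replaced by `*` attachment points. This is what makes the
regressor's gain importances chemically readable.

## Models

One classifier and one regressor are trained per (receptor, site-mode)
pair, never a pooled multi-receptor model: per-receptor training sets
differ in chemistry and size, and the decision logic needs per-receptor
scores.

**Classifier.** A feed-forward network over the fingerprint bits with a
softmax readout over six activity classes. Hyperparameters are drawn by
seeded random search: 5–20 hidden layers, per-layer widths drawn
log-uniformly from 16–2048 units, activation from {relu, tanh,
sigmoid}, Adam learning rate log-uniform in [1e−4, 1e−2]; the loss is
multiclass cross-entropy. Each trial is scored by mean 10-fold
cross-validated accuracy and the winner is refit on all data. The
backend is scikit-learn's `MLPClassifier`; the predictor contract
(bit vector in, probability 6-vector out) is backend-agnostic by
design. The training budget is a fixed iteration cap with
plateau-based early stopping; budget, trial count (default 25) and the
selection metric are recorded in the bundle metadata to keep runs
auditable.

**Regressor.** LightGBM gradient-boosted trees. Random search draws the
tree count log-uniformly within the hard bound [50, 50000], learning
rate in [0.01, 0.3], leaf count in [8, 256] and row subsampling in
[0.5, 1]; selection is by mean 10-fold cross-validated RMSE. Runs are
single-threaded with `deterministic=true` so a seed fixes the model
exactly. Feature importance uses total split gain; zero-gain bits are
excluded and ties break by bit index.

**Activity classes.** pChEMBL is binned as {0} (inactive / negative
data point), (0, 5], (5, 6], (6, 7], (7, 8], (8, ∞). The six-bin
structure with a dedicated inactive class is fixed; the interior edges
are a package choice (unit-width bins over the pharmacologically
standard 5–8 range) and fully overridable. Bins are lower-exclusive /
upper-inclusive so that boundary values such as pChEMBL = 5 have one
defined home.

**Splits.** Records are split 80/20 at random (by record, not by
scaffold; a scaffold split is a stricter generalization test but is not
the default contract), with `floor(0.8 n)` training records and ten
shuffled CV folds over the training side whose sizes differ by at most
one. All splits are seeded and serialized.

## Docking leg

The package owns the docking *protocol* — box construction, ligand
preparation, batch orchestration, score parsing — and treats the engine
as a pluggable third party. The search volume is a cube (default edge
30 Å) centered on the arithmetic centroid of the site's
reference-ligand coordinates; orthosteric and allosteric sites
(including separate PAM/NAM sites) are independent tasks. Ligands are
prepared from SMILES by seeded distance-geometry 3D embedding,
force-field relaxation and Gasteiger charges, written as PDBQT with the
rotatable-bond count annotated; per-compound embedding failures are
recorded, not fatal, since 3D generation is the step most compounds
fail in practice.

Two backends:

- `vina`: shells out to an external AutoDock Vina binary (config:
  exhaustiveness 8, seed 42 by default — local choices, documented as
  such) and parses its score table.
- `stub` (default): a deterministic hash of (canonical SMILES,
  receptor, site) mapped into [−12, −2] kcal/mol. It preserves every
  structural property of the leg (determinism, per-site independence,
  ranking semantics) while being uninformed about chemistry, which
  makes it the honest null predictor for tests: the ML legs must beat
  it.

Receptor preparation (homology modelling, loop building, refinement) is
out of scope; receptors are consumed as ready PDBQT files.

## Consensus and evaluation

Per leg, a receptor's orthosteric and allosteric entries are collapsed
to whichever looks more active for that leg, then: the classifier leg
nominates the receptor with the highest predicted class (ties broken by
probability mass above the inactive class, then lexicographically), the
regressor leg the highest predicted pChEMBL, the docking leg the lowest
score. If no docking score exists the leg is a "no call" and agreement
is computed over two legs. All ties break lexicographically for
determinism.

Evaluation counts a compound as TP under rule `all3` / `atleast2` /
`atleast1` when 3 / ≥2 / ≥1 legs name the truth, at two levels: the
exact receptor, or its GPCR class (A vs B) from a shipped
receptor-class registry (chemokine receptors class A, secretin family
class B; extendable via JSON). Precision = TP/(TP+FP), NaN-flagged when
a stratum is empty. TP counts are nested by construction
(all3 ≤ atleast2 ≤ atleast1); precisions need not be.

Query compounds can additionally be ranked against precomputed profiles
of known actives per receptor (percentile and z-score of the predicted
pChEMBL), mirroring how a practitioner reads a prediction relative to
known chemistry. There is no probabilistic calibration or score fusion
across legs — the legs only vote.

## Synthetic benchmark: what it shows and what it does not

The generator plants a known structure–activity relationship: carrier
molecules get a receptor-specific pharmacophore grafted onto one of 20
drug-like scaffolds (decorated with small substituents for diversity;
decoration happens before grafting so the pharmacophore's interior
atom environments are identical across carriers), and
`pChEMBL = baseline + effect·carrier + N(0, σ)`, clipped to [0, 14].
Defaults: baseline 5, effect 3, σ = 0.2, 100 actives and 100 inactives
per receptor. The multi-receptor benchmark adds cross-receptor
negatives (each receptor's actives enter the other receptor's table at
pChEMBL 0, mirroring negative data points in real tables) and
dual-pharmacophore compounds that are genuinely non-selective.
A substructure oracle verifies during generation that every carrier
contains its pharmacophore and no non-carrier does.

Passing on this benchmark establishes that the pipeline recovers a
signal that is actually in the data: near-Bayes regression error,
carrier-indicative bits at the top of the gain ranking, consensus
precision far above the uninformed docking null. It does **not**
establish performance on real ChEMBL chemistry: real activity cliffs,
assay noise structure, scaffold imbalance and series effects are all
absent, and the planted signal is far cleaner than any real SAR.

Problem sizes in the test suite and acceptance script (512-bit
fingerprints, 60–500 actives per receptor, 2–5 search trials with
narrowed ranges) are the package's own scaled-down defaults for a
single-CPU run; every range stays inside the contractual bounds and the
full defaults remain available through configuration.

## Numerical choices and degenerate inputs

- Seeds: every stochastic step (generation, splitting, search, NN and
  GBM fits, docking engine) takes an explicit seed that is serialized
  with the output.
- Single-class training labels raise a degenerate-label error rather
  than fitting a vacuous classifier; constant features warn and fit the
  mean; constant targets yield an empty importance list.
- Receptors with fewer than 10 curated records are skipped with a
  warning (10-fold CV is undefined below that).
- Duplicate activity records (same molecule, receptor, site) keep the
  first occurrence; conflicting potencies are logged, not averaged.
- Salts/mixtures (SMILES with `.`) are kept verbatim and flagged, never
  silently stripped.
- The classifier always emits a probability vector over all six
  classes, with zero mass on classes absent from training, so consensus
  logic sees a fixed-width output.

## Known limitations

- The stub docking backend is chemistry-blind by design; docking-leg
  precision in offline runs reflects chance, not AutoDock Vina.
- The vina backend wrapper is exercised against synthetic engine logs
  only; it has not been run against a live engine in this repository.
- No count fingerprints, no other descriptor families, no InChI, no
  D-amino acids, PTMs or cyclic peptides; out-of-alphabet residues are
  an error, never a silent skip.
- Gain importance inherits folding collisions: a top bit can carry more
  than one environment, and the decoder reports the first with a
  collision note.
- Whether real curation pipelines strip salts before fingerprinting is
  unknowable from the data contract; records are kept verbatim and
  flagged instead of guessing.
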