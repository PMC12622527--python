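# Methods

## Scope and model

`ibvs` implements an interaction-based rescoring pipeline for structure-based
virtual screening.  A docked pose is summarised by a fixed, named feature
vector; a gradient-boosted tree classifier maps that vector to a binding
confidence in [0, 1]; compound-level scores come from pose aggregation and a
fixed-weight two-model consensus; screening power is read off the ranked,
labelled library.  The sections below record the concrete definitions,
defaults and design decisions, in the order the pipeline runs.

## Featurization

**Interaction features** are functions of receptor–ligand geometry only:

* *Typed close contacts.*  For each unordered AutoDock-type pair, the number
  of receptor–ligand atom pairs within 2.5 Å and within 4.0 Å.  Names are
  canonical-alphabetical, e.g. `2.5(HD, OA)`, never `2.5(OA, HD)`, so a pair
  has exactly one feature.
* *Electrostatic sums.*  Per type pair, `V(a,b) = Σ q_a·q_b / r` over
  receptor–ligand pairs within the 4.0 Å contact cutoff, in charge²/Å units
  with sign preserved.  Charges are always the ones carried by the PDBQT
  file; a missing charge column is a hard error, because this term is
  meaningless without the charges the docking engine actually used.
  Coincident distinct atoms (r = 0) raise a degenerate-geometry error rather
  than returning ±inf.
* *Hydrogen bonds.*  A polar hydrogen (type HD) on either side within
  4.0 Å of an acceptor-typed heavy atom (OA/NA/SA) on the other, with
  donor–H–acceptor angle ≥ 120° whenever a donor heavy atom is identifiable
  (nearest heavy atom within 1.6 Å of the H).  The distance is measured
  H···acceptor.  When no covalently plausible donor exists the angle test is
  waived rather than silently failing the bond.
* *Salt bridges.*  Receptor–ligand atom pairs with opposite-sign charges,
  both |q| ≥ 0.5 e, within 5.5 Å.  The charge floor keeps ordinary polar
  atoms (|q| ≈ 0.2–0.4) from registering as ionic contacts.
* *π–π stacking.*  Ring centroids and normals; face-to-face when centroids
  ≤ 7.0 Å apart with interplanar angle ≤ 30°, edge-to-face at ≤ 5.0 Å with
  angle ≥ 60°.  Receptor rings are detected by distance-clustering
  aromatic-typed atoms (PDBQT has no bond table); ligand rings can be passed
  explicitly or detected the same way.
* *ECIF-style pair counts.*  Counts of (protein extended type, ligand
  extended type) pairs within 6.0 Å, hydrogens excluded.  The canonical ECIF
  method types protein atoms from PDB residue templates; since PDBQT carries
  no residue-level bond information, this implementation uses a simplified
  extended type — element; heavy-atom degree; aromatic flag — with protein
  connectivity inferred from covalent distance (≤ 1.9 Å heavy–heavy) and
  ligand typing taken from the supplied SDF/SMILES topology.  Ligand heavy
  atoms must appear in the same order in topology and docked structure.

All geometric thresholds live in one frozen `InteractionConfig` and are
loadable from YAML/JSON, so the defaults are auditable and overridable.

**Ligand descriptors** are pure graph functions: 59 RDKit 2D descriptors
(connectivity Chi indices, kappa shape indices, BalabanJ, BertzCT, counts,
molecular weights, TPSA, LogP, VSA bins, EState extrema, QED) plus the Kier
flexibility index Φ = ¹κα·²κα/A.  The kappa formulas and path counts are
implemented here from first principles (with the Hall–Kier α taken from
RDKit); the test suite cross-checks against RDKit's independent kappa
implementation.  Φ uses the α-modified indices by default
(`use_alpha=False` gives the plain ones).  Degenerate graphs — a single
heavy atom, or no two-bond path — return Φ = 0 with a warning instead of
NaN.  Because every descriptor is conformation-invariant, a badly docked
pose of an active still carries the active's molecular identity; this is the
mechanism that lets the model separate pose quality from compound identity.

**Schemas.**  A `FeatureSchema` fixes feature identity and order.  The
default PB schema enumerates contact and electrostatic pairs over the 13
common AutoDock types, the three named interaction counts, a 128-token ECIF
pair block, the 59 ligand descriptors and Φ.  The PS schema is PB minus
exactly one named feature; which feature is excluded is declared in the
schema object (default: `kier_flexibility`, a documented placeholder — the
schema is data, not code, and swaps without touching the pipeline).
Schema features unobserved in a pose are 0; observed pairs outside the
schema are dropped; a schema name no producer recognises is an error.

## Curation

Heavy-atom RMSD between two poses of the same molecule uses canonical atom
correspondence and **no superposition** — docked poses share the receptor
frame, so alignment would hide real displacement.  Hydrogens, polar or not,
are ignored.

Pose labelling is a three-way partition: RMSD ≤ pos_cutoff (2.0, 2.5 or
3.0 Å tolerance profiles) → positive; ≥ 4.0 Å → low-quality negative;
strictly between → discarded.  The gray zone is dropped rather than
negatively labelled because such poses are neither near-native nor clearly
wrong.  The crystal reference itself is always a positive.  Topology-decoy
negatives are capped at 150 per target by seeded sampling (default seed 42,
recorded).

Max-abs scaling divides each feature by its maximum absolute training value,
mapping training data into [−1, 1] while preserving sign and skew;
all-zero columns scale by 1 so the transform is always invertible.  Unseen
values may legitimately scale outside [−1, 1].

## Training

XGBoost binary classifier (`binary:logistic`, `tree_method=hist`, single
thread for determinism), trained directly on the imbalanced table.  The
positive class is up-weighted by `scale_pos_weight = (len(y) − Σy)/Σy`,
which makes total positive weight equal total negative weight exactly; the
loss is the weighted binary cross-entropy
`−(1/N) Σ wᵢ[yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)]` with probabilities clipped at
ε = 1e-15.  Model selection maximises validation AUCPR — the metric that
tracks minority-class retrieval — under a seeded random search over bounded
ranges (depth 3–10, learning rate 0.01–0.3 log-uniform, subsample 0.6–1,
colsample 0.5–1, min_child_weight 1–10, γ 0–5, λ 0.01–10 log-uniform,
α 0–5); every trial is logged in the model metadata.  The reference-scale
schedule is 100 trials × 2000 rounds with early stop 50, then a refit up to
50 000 rounds with early stop 100.  `TrainingConfig.desk()` (20 trials,
500 rounds) is the profile the examples and tests run; the problem sizes
throughout this package (1240-compound screens, 100 features) are chosen so
a full train–screen–evaluate cycle completes in seconds on one core.
Validation is a stratified 10% split by default, or an external set when
supplied.  Two runs with identical data, config and seed produce identical
models.

## Scoring and consensus

Aggregation collapses a compound's pose scores by `max` (best rescored pose
regardless of docking rank — the recommended default), `top1` (docking
engine's rank-1 pose) or `average`.  Consensus is a fixed convex combination
of the two models' aggregated scores: balanced (0.5, 0.5) or imbalanced
(0.3, 0.7) with the PS-role scorer at 70%.  Aggregation happens **per model
before consensus** — each model independently picks its own best pose —
which differs from consensus-then-aggregate when the strategy is `max`; the
per-pose alternative is available by consensus-scoring a per-pose table.
Score ties across compounds are broken by compound id, so tie-sensitive
early-enrichment values are reproducible run to run.

## Evaluation

* EF at fraction x uses a top set of ⌈x·N⌉ compounds (ceiling), so EF 0.5%
  of a 1240-compound library ranks 7 compounds rather than an empty set.
* BEDROC uses the Truchon–Bayly closed form with α = 80.5 by default; the
  suite cross-checks it against both a loop-arithmetic oracle and RDKit's
  implementation, and verifies the α → 0 limit tracks AUROC.
* AUROC is the Mann–Whitney probability (ties ½), computed via
  scikit-learn and checked against exhaustive pair counting.
* Spearman uses average ranks on ties (SciPy), checked against a hand-rolled
  rank-Pearson oracle.

## Attribution

Per-feature contributions come from the exact TreeSHAP values the XGBoost
booster computes natively, on the margin (log-odds) scale where the
additivity identity `base + Σ φᵢ = margin` is exact; probability-scale
numbers shown anywhere are a labelled sigmoid transform of the margin, not
an additive decomposition.  Global importance is mean |contribution| over a
dataset, with the per-feature value-vs-contribution correlation retained so
"higher value ⇒ higher score" patterns are visible; local attribution
orders one example's contributions by magnitude into a waterfall.

## Synthetic data: what it does and does not show

The generators are pure functions of (spec, seed).  Toy complexes realise
exact distances and angles, so expected feature values are computable by
hand.  Screening libraries copy the DEKOIS 2.0 class geometry — 40 actives
: 1200 decoys — with a planted mean shift (default 2 SD on 5 of 100
features) on independent Gaussian features; pose sets realise requested
RMSDs exactly by rigid translation along seeded random directions.

These synthetics validate the *machinery*: labelling arithmetic, loss and
weight identities, metric values, recovery of planted signal, and the
complementarity of two models trained on disjoint signal blocks.  In the
two-pattern consensus scenario, "balanced" is operationalised as: each
consensus weighting enriches the mixed screen at least as well as the worse
single model and reaches at least 75% of the better one's EF 1%.  They do
not emulate correlated chemical feature distributions, target-family
structure, assay noise, or decoy-selection bias, so passing tests here say
nothing about screening performance on real targets — that requires real
docking data and benchmark libraries, which are deliberately out of scope.

## Numerical choices and edge cases

* Probability clipping ε = 1e-15 in the loss; contact counts are exact
  integer comparisons on Euclidean distance (≤, closed boundary).
* RMSD-boundary poses: a pose whose RMSD is within floating-point error of
  a cutoff classifies by the exact ≤/≥ comparison; the pose generators used
  in tests avoid placing targets exactly on cutoffs.
* Empty pocket after truncation, zero positives, single-class training
  tables, constant vectors in Spearman, and empty pose lists all raise
  typed errors rather than returning sentinel values.
* All sampling — decoy truncation, library generation, train/validation
  splits, hyperparameter draws — flows from explicit integer seeds.

## Known limitations

* Protein ECIF types are connectivity-inferred, not residue-template based;
  they are coarser than the published ECIF protein typing.
* Receptor ring detection by aromatic-atom clustering lumps fused ring
  systems into one plane estimate.
* The PDBQT parser reads the standard fixed columns and tolerates torsion
  tree records, but does not validate AutoDock type tokens against a
  dictionary; metal ions and cofactors are treated as ordinary typed atoms.
* The feature universe is configurable rather than canonical: the default
  PB schema targets the same families and scale as established interaction
  fingerprints, but exact membership is declared in the schema, not
  hard-coded.
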