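# Methods

## Problem and model

Natural disulfide bonds impose a tight, well-conserved local geometry on
the two cysteines they join.  `ssbondnet` treats engineered-site
prediction as binary classification of residue-pair geometry: does the
backbone+Cβ arrangement of a candidate pair look like that of a natural
bridge?

The representation is purely internal: the 45 pairwise Euclidean
distances among the ten heavy atoms (N, Cα, C, O, Cβ) × 2 of a pair.
Distances make the feature exactly invariant under rigid-body motion of
the input coordinates.  They are also invariant under mirror reflection —
a known blind spot of any distance-only featurization, documented and
tested rather than hidden.  Sulfur atoms are excluded by design: at a
proposed mutation site no Sγ exists, and in natural bonds the S–S
distance would dominate the classifier and make it trivial (and useless
for engineering).  No scaling or standardisation is applied; the network
consumes raw Å distances, which keeps the first-layer weights directly
interpretable as distance sensitivities.

## Data derivation

Positives are the cysteine pairs declared by SSBOND records whose two
residues have complete (N, Cα, C, O, Cβ) blocks.  Each bond yields one
negative: of the four crossing pairs of the bonded residues' sequence
neighbours, the one with the shortest Cα–Cα distance.  This choice
produces negatives that are spatially close but unbonded — hard
negatives that carve out the decision boundary tightly around true bond
geometry.  Candidates that are themselves declared disulfide pairs are
excluded (adjacent disulfide bridges exist but are vanishingly rare);
ties are broken by a fixed candidate order, and a bond whose candidates
are all unusable simply yields no negative (logged as dataset
imbalance).

Conventions where the inputs are ambiguous, all configurable or logged:

* multi-model (NMR) files: first model only;
* alternate conformations collapsed to the blank/'A' altloc;
* insertion codes are part of residue identity;
* common modified residues (MSE, SEC, CSO, …) mapped to their standard
  parent, others dropped;
* residues missing any backbone atom are dropped with a warning; a
  missing Cβ drops the residue unless it is glycine;
* sequence neighbours are defined by adjacency in the chain's ordered
  residue list, so numbering gaps still count as neighbours;
* inter-chain bonds are retained, with neighbours taken within each
  residue's own chain;
* dataset curation thresholds ("resolution better than 2.0 Å, R-factor
  below 0.25") are read as strict inequalities, and entries lacking the
  metadata are excluded.

## Cβ reconstruction

Glycine's Cβ is placed analytically from (N, Cα, C): 1.53 Å from Cα, at
110.5° to both the Cα→N and Cα→C directions, on the L-amino-acid side of
the backbone plane.  This is equivalent (to within thermal noise) to
superposing an ideal alanine onto the backbone and reading off its Cβ,
which is exactly the independent oracle the tests use: a frozen
MMFF-optimised L-alanine conformer, superposed by least squares,
reproduces the analytic placement to < 0.05 Å (tested at 0.25 Å to
accommodate the conformer's own non-ideality).  The construction is
exactly equivariant under rigid motions (tested to 1e-9 Å) and raises on
degenerate (collinear) backbones.

## Classifier

Architecture 45→128→32→1, ReLU hidden activations, logistic output,
threshold 0.5 (boundary convention: score = threshold → bonded).
Training: 10 epochs of plain SGD at learning rate 0.01, batch size 100.
The loss is binary cross-entropy and initialisation is seeded He-style
uniform — canonical choices for a logistic-output classifier of this
size; with them, training is bit-reproducible for a fixed seed.  The
implementation is a transparent numpy forward/backward pass wrapped in a
scikit-learn estimator (`fit` / `predict` / `predict_proba`,
`get_params`/`set_params`, underscored fitted attributes), so it
composes with sklearn pipelines and model selection.

Residue-pair order is a genuine ambiguity of the representation (which
cysteine occupies rows 0–4?).  It is resolved twice over: samples are
stored under a canonical order (lexicographic by chain, number,
insertion code), every training sample is presented in both orientations
(the induced permutation of the 45 features), and prediction averages
the two orientation scores.  Score symmetry under swap is therefore
exact, not approximate.

Weights serialise to JSON via repr round-tripping, so a reloaded model
scores bit-identically; files are validated against the declared
architecture on load.

## Prediction and ranking

All n(n−1)/2 unordered residue pairs are enumerated, then prescreened by
the Cα–Cα window 3.0–7.5 Å (inclusive), the range in which natural
bridges overwhelmingly fall.  Two defaults extend the window filter:
within-chain pairs closer than 2 positions in sequence are excluded
(adjacent bridges are vanishingly rare; set `min_sequence_separation=0`
to apply the distance window alone), and pairs involving native cysteines
are kept (a single mutation can pair with an existing cysteine).
Records are sorted by descending score with ties broken by residue
identity, and ranked: `abs_rank` from 0, `rel_rank = abs_rank/(N−1)`
(0 when N = 1).

## Evaluation

ROC curves group tied scores (standard step construction,
`drop_intermediate=False`) so the trapezoidal AUC equals the
Mann–Whitney concordance probability; the tests verify this against an
exhaustive O(n²) concordance oracle including ties.  Feature relevance
uses a seeded random-forest *regressor* on the binary label (impurity
importances normalised to sum 1) — regression mode keeps the analysis
threshold-free.  Average distance maps are plain element-wise means of
the per-label distance matrices.

## Synthetic data

The generator produces ideal-geometry residues (standard bond lengths
and angles, L-chirality, built by internal-coordinate placement — a code
path independent of the Cβ reconstruction it is tested against) in two
pair-geometry regimes:

| regime | Cα–Cα | Cβ–Cβ | Cβ orientation |
|---|---|---|---|
| positive (bonded-like) | uniform 4.0–6.5 Å | 3.8 Å | facing |
| negative (non-bonded) | uniform 3.0–7.5 Å | forced > 5.5 Å | pointing apart |

with per-atom Gaussian jitter σ = 0.15 Å (redrawn in the rare case it
would break the 0.8–2.2 Å bonded-distance sanity window).  The positive
regime mirrors the observed geometry of natural bridges (Cα–Cα centred
in the prescreen window, Cβ contact distance ~3.8 Å); the negative
Cβ–Cβ floor is set above the positive value so the two supports are
disjoint *by construction*.  That is deliberate: it gives model tests a
provable floor (a single Cβ–Cβ threshold at 5.0 Å already classifies
the clouds perfectly, so both that oracle and the trained network can
saturate AUC at 1.0), at the price of realism.  Passing these tests
demonstrates pipeline correctness, not performance on real proteins,
where the two classes genuinely overlap and accuracy is necessarily
lower.  Real-data features the generator does not emulate: side chains
beyond Cβ, rotamer states, secondary-structure context, crystallographic
noise and missing atoms.

Synthetic structures place residues on a line at 12 Å spacing — far
enough that no accidental pair enters the prescreen window — and embed
planted bonded pairs (declared via SSBOND) and optional non-bonded
decoy pairs perpendicular to the line.  Each structure ships with a
truth table listing, for every planted bond, the crossing-pair negative
it should yield, computed inside the generator by direct distance
comparison so it can serve as an independent oracle for the sampling
module.

## Problem sizes

The benchmark used by the tests and the acceptance script is 5,000
pairs per class with a 25 % held-out split; training the network on it
takes a few seconds on one CPU.  Structure-level checks use fixtures of
12–106 residues.  These sizes give stable statistics (the held-out AUC
and accuracy saturate well before this scale) while keeping the whole
suite fast.

## Known limitations

* Distance features cannot distinguish mirror images.
* The classifier models geometry only; it knows nothing about sequence
  context, conformational strain released by mutation, or expression
  effects.
* Wild-type structures are used as-is: no relaxation of the mutant is
  performed, so pairs whose geometry would only become compatible after
  backbone adjustment score low.
* No pretrained weights are distributed; performance depends entirely
  on the structure collection (or synthetic benchmark) a user trains on.
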