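# ssbondnet

Structure-based prediction of **disulfide-bond engineering sites**.

Engineered disulfide bonds — introduced by mutating a pair of residues to
cysteine at structurally compatible positions — are a standard way to
stabilise proteins for crystallography, therapeutics and industrial use.
Given a protein structure, `ssbondnet` ranks every candidate residue pair
by how much its local backbone geometry resembles that of natural
disulfide bridges, so that experimentalists can shortlist mutations worth
testing.

## Method

A residue pair is represented by the ten heavy atoms
(N, Cα, C, O, Cβ, N′, Cα′, C′, O′, Cβ′) of its two residues.  Sulfur atoms
are deliberately excluded: at a candidate mutation site the cysteine side
chain does not exist yet.  The 10×3 coordinate block is converted to the
10×10 Euclidean distance matrix — removing all translation/rotation
dependence — and flattened to its strict upper triangle, a 45-dimensional
vector **d** in Å.  Glycine, which lacks Cβ, is handled by placing an
ideal alanine Cβ from its backbone (N, Cα, C), i.e. the in-silico
glycine→alanine mutation.

The classifier is a small fully connected network

```
d (45) → ReLU(128) → ReLU(32) → σ → score ∈ (0, 1)
```

trained with plain SGD on binary cross-entropy for 10 epochs at learning
rate 0.01 with mini-batches of 100; score ≥ 0.5 calls a pair "bonded".
Because a pair has no intrinsic residue order, every sample is trained in
both orientations and prediction averages the two orientation scores,
making the score exactly swap-symmetric.

Training data come from structures with annotated disulfide bonds
(SSBOND records): each bonded cysteine pair (Cᵢ, Cⱼ) is a positive
sample, and its negative counterpart is the crossing neighbour pair among
(Xᵢ₋₁, Xⱼ₋₁), (Xᵢ₋₁, Xⱼ₊₁), (Xᵢ₊₁, Xⱼ₋₁), (Xᵢ₊₁, Xⱼ₊₁) with the shortest
Cα–Cα distance — spatially close yet unbonded, exactly the boundary the
classifier must learn.

For prediction, the n(n−1)/2 residue pairs of a target are prescreened by
the Cα–Cα window **3.0–7.5 Å** (where natural disulfide bonds
overwhelmingly fall), scored, and ranked.  Reports use the conventions of
engineered-bond benchmarks: absolute rank from 0 down the score-sorted
list, relative rank = abs_rank / (total − 1).

## Worked example

No pretrained weights ship with the package; models are trained from your
own structure collection or from the built-in synthetic geometric
benchmark.  The snippet below plants one true disulfide pair and three
non-bonded decoys in a synthetic structure and ranks them:

```python
from ssbondnet import (make_feature_clouds, make_structure, predict_sites,
                       train)

clouds = make_feature_clouds(2000, seed=0)   # geometric benchmark
clf = train(clouds)                          # 45-128-32-1 net, 10 epochs
target, _ = make_structure(25, 1, seed=13, decoys=3)
for r in predict_sites(target, clf):
    print(r.abs_rank, f"{r.score:.3f}", str(r.a), "--", str(r.b), r.predicted)
```

```
0 0.997 CYS A:2 -- CYS A:4 bonded
1 0.000 ALA A:17 -- ALA A:19 nonbonded
2 0.000 ALA A:12 -- ALA A:14 nonbonded
```

The planted cysteine pair is ranked 0 with a saturated score; the decoys,
whose Cβ atoms point apart, score near 0.  (One decoy fell just outside
the Cα prescreen window here, so three records are reported.)

The same workflow is available from the shell:

```
ssbondnet synth --n-res 20 --bonds 2 --seed 1 --out fixture.pdb
ssbondnet dataset --pdb-dir pdbs/ --out dataset.csv
ssbondnet train --dataset dataset.csv --seed 3 --out weights.json
ssbondnet predict --pdb target.pdb --model weights.json --out report.csv
```

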