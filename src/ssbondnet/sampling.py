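"""Labelled dataset construction.

Positive samples are the disulfide-bonded cysteine pairs declared by a
structure's SSBOND records.  Each bond also yields one negative sample: of
the four "crossing" pairs formed by the sequence neighbours of the two
bonded cysteines — (i-1, j-1), (i-1, j+1), (i+1, j-1), (i+1, j+1) — the one
with the shortest CA-CA distance.  These negatives are spatially close but
unbonded, which is exactly the decision boundary the classifier has to
learn; free (unbonded) cysteines are deliberately not used.

The resulting dataset is balanced up to bonds whose negative could not be
derived, and is split into train/test by seeded uniform sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, distance_matrix, flatten
from .structure_io import ResidueRef, SSBondRecord, StructureModel, pair_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "ResiduePairSample",
    "LabelledDataset",
    "extract_positives",
    "derive_negative",
    "assemble_dataset",
    "curate_filter",
]

_META_COLUMNS = [
    "structure_id",
    "chain_a", "resnum_a", "icode_a", "aa_a",
    "chain_b", "resnum_b", "icode_b", "aa_b",
    "label", "origin", "split",
]


@dataclass
class ResiduePairSample:
    """One labelled residue pair: its 10-atom coordinate block (rows 0-4 the
    canonically-first residue) and its bonded (1) / non-bonded (0) label."""

    structure_id: str
    a: ResidueRef
    b: ResidueRef
    coords: np.ndarray | None  # (10, 3); None when restored from a feature CSV
    label: int
    origin: str = ""

    def feature(self) -> np.ndarray:
        if self.coords is None:
            raise ValueError("sample restored without coordinates")
        return flatten(distance_matrix(self.coords)).values


@dataclass
class LabelledDataset:
    """Samples plus their 45-d features, labels and a train/test split."""

    samples: list
    features: np.ndarray  # (n, 45)
    labels: np.ndarray  # (n,) of {0, 1}
    split: np.ndarray  # (n,) of {"train", "test"}

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def X(self) -> np.ndarray:
        return self.features

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def _mask(self, part: str) -> np.ndarray:
        return self.split == part

    @property
    def X_train(self):
        return self.features[self._mask("train")]

    @property
    def y_train(self):
        return self.labels[self._mask("train")]

    @property
    def X_test(self):
        return self.features[self._mask("test")]

    @property
    def y_test(self):
        return self.labels[self._mask("test")]

    def subset(self, part: str) -> "LabelledDataset":
        m = self._mask(part)
        return LabelledDataset(
            [s for s, keep in zip(self.samples, m) if keep],
            self.features[m], self.labels[m], self.split[m])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append({
                "structure_id": s.structure_id,
                "chain_a": s.a.chain_id, "resnum_a": s.a.residue_number,
                "icode_a": s.a.insertion_code, "aa_a": s.a.amino_acid,
                "chain_b": s.b.chain_id, "resnum_b": s.b.residue_number,
                "icode_b": s.b.insertion_code, "aa_b": s.b.amino_acid,
                "label": s.label, "origin": s.origin,
            })
        df = pd.DataFrame(rows)
        df["split"] = self.split
        feat = pd.DataFrame(self.features, columns=list(FEATURE_NAMES))
        return pd.concat([df[_META_COLUMNS], feat], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabelledDataset":
        missing = [c for c in list(FEATURE_NAMES) + ["label", "split"]
                   if c not in df.columns]
        if missing:
            raise ValueError(f"dataset table missing columns: {missing[:5]}")
        samples = []
        for row in df.itertuples(index=False):
            samples.append(ResiduePairSample(
                structure_id=str(row.structure_id),
                a=ResidueRef(str(row.chain_a), int(row.resnum_a),
                             str(row.icode_a or "") if not pd.isna(row.icode_a) else "",
                             str(row.aa_a)),
                b=ResidueRef(str(row.chain_b), int(row.resnum_b),
                             str(row.icode_b or "") if not pd.isna(row.icode_b) else "",
                             str(row.aa_b)),
                coords=None,
                label=int(row.label),
                origin=str(getattr(row, "origin", "")),
            ))
        return cls(samples,
                   df[list(FEATURE_NAMES)].to_numpy(dtype=float),
                   df["label"].to_numpy(dtype=int),
                   df["split"].to_numpy(dtype=object))

    @classmethod
    def from_csv(cls, path) -> "LabelledDataset":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False,
                                          na_values=[""]))


def _make_sample(s: StructureModel, a: ResidueRef, b: ResidueRef,
                 label: int, origin: str) -> ResiduePairSample:
    if b.key < a.key:
        a, b = b, a
    return ResiduePairSample(s.id, a, b, pair_atoms(s, a, b), label, origin)


def extract_positives(s: StructureModel) -> list:
    """One positive sample per SSBOND whose residues are usable."""
    out = []
    for bond in s.ssbonds:
        if bond.first not in s or bond.second not in s:
            logger.warning("%s: skipping bond %s (unusable residue)", s.id, bond)
            continue
        out.append(_make_sample(s, bond.first, bond.second, 1, f"ssbond:{bond}"))
    return out


def derive_negative(s: StructureModel, bond: SSBondRecord):
    """Negative sample for one disulfide bond, or None.

    Candidates, in fixed tie-break order, are the four crossing pairs of the
    bonded residues' sequence neighbours; the usable candidate with the
    smallest CA-CA distance wins.  A candidate is unusable if a neighbour is
    missing, if its two residues coincide, or if it is itself a declared
    disulfide pair of the structure.
    """
    prev_i, next_i = s.neighbors(bond.first)
    prev_j, next_j = s.neighbors(bond.second)
    candidates = [(prev_i, prev_j), (prev_i, next_j),
                  (next_i, prev_j), (next_i, next_j)]
    best = None
    best_d = np.inf
    for a, b in candidates:
        if a is None or b is None or a.key == b.key:
            continue
        if s.is_bonded_pair(a, b):
            continue
        d = float(np.linalg.norm(s.get(a).ca - s.get(b).ca))
        if d < best_d:
            best, best_d = (a, b), d
    if best is None:
        logger.warning("%s: no usable negative for bond %s", s.id, bond)
        return None
    return _make_sample(s, best[0], best[1], 0, f"neg-of:{bond}")


def assemble_dataset(structures, test_fraction: float = 0.25,
                     seed: int = 0) -> LabelledDataset:
    """Balanced positive/negative dataset over a list of structures with a
    seeded uniform train/test split at the sample level."""
    if not structures:
        raise ValueError("no structures supplied")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    samples = []
    n_pos = n_neg = 0
    for s in structures:
        for pos in extract_positives(s):
            samples.append(pos)
            n_pos += 1
            neg = derive_negative(s, SSBondRecord.make(pos.a, pos.b))
            if neg is not None:
                samples.append(neg)
                n_neg += 1
    if not samples:
        raise ValueError("no usable disulfide bonds in the supplied structures")
    if n_pos != n_neg:
        logger.warning("dataset imbalance: %d positives vs %d negatives",
                       n_pos, n_neg)
    features = np.stack([s.feature() for s in samples])
    labels = np.array([s.label for s in samples], dtype=int)
    rng = np.random.default_rng(seed)
    n = len(samples)
    n_test = int(round(test_fraction * n))
    split = np.full(n, "train", dtype=object)
    split[rng.permutation(n)[:n_test]] = "test"
    return LabelledDataset(samples, features, labels, split)


def curate_filter(entries, max_resolution: float = 2.0,
                  max_rfactor: float = 0.25) -> list:
    """Keep entries with resolution strictly better than ``max_resolution``
    and R-factor strictly below ``max_rfactor``; entries lacking either
    value are excluded."""
    kept = []
    for e in entries:
        resolution = getattr(e, "resolution", None)
        r_factor = getattr(e, "r_factor", None)
        if resolution is None or r_factor is None:
            continue
        if resolution < max_resolution and r_factor < max_rfactor:
            kept.append(e)
    return kept
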