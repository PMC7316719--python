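"""Distance-matrix featurization of residue pairs.

A candidate pair is described by the 10 heavy atoms (N, CA, C, O, CB) of its
two residues.  The 10x3 coordinate block is turned into the 10x10 Euclidean
distance matrix, which removes all dependence on translation and rotation
(and, as a known blind spot, on mirror reflection), and then flattened to
its strict upper triangle: a 45-dimensional vector in Angstrom.  No scaling
or standardisation is applied; downstream models see raw distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .structure_io import ResidueRef, StructureModel, pair_atoms

__all__ = [
    "ATOM_LABELS",
    "N_FEATURES",
    "FEATURE_INDEX_PAIRS",
    "FEATURE_NAMES",
    "SWAP_PERMUTATION",
    "DistanceFeature",
    "distance_matrix",
    "flatten",
    "unflatten",
    "swap_pair_order",
    "featurize_pair",
    "canonical_pair",
    "PairDistanceFeaturizer",
]

#: labels of the 10 atoms in block order; primes mark the second residue
ATOM_LABELS = ("N", "CA", "C", "O", "CB", "Np", "CAp", "Cp", "Op", "CBp")

_TRIU_ROWS, _TRIU_COLS = np.triu_indices(10, k=1)
#: the 45 (row, col) atom-index pairs, strict upper triangle in row-major order
FEATURE_INDEX_PAIRS = tuple(zip(_TRIU_ROWS.tolist(), _TRIU_COLS.tolist()))
N_FEATURES = len(FEATURE_INDEX_PAIRS)  # 45

#: serialization column names, e.g. d_N_CA ... d_CB_CBp
FEATURE_NAMES = tuple(
    f"d_{ATOM_LABELS[i]}_{ATOM_LABELS[j]}" for i, j in FEATURE_INDEX_PAIRS
)

_pair_to_pos = {pair: k for k, pair in enumerate(FEATURE_INDEX_PAIRS)}
#: index permutation of the 45-vector induced by swapping the two residues
SWAP_PERMUTATION = np.array(
    [
        _pair_to_pos[tuple(sorted(((i + 5) % 10, (j + 5) % 10)))]
        for i, j in FEATURE_INDEX_PAIRS
    ],
    dtype=int,
)


@dataclass(frozen=True)
class DistanceFeature:
    """45 pairwise atomic distances (Angstrom) for one residue pair."""

    values: np.ndarray  # (45,)

    #: shared flattening map: feature k is the distance between atom pair
    #: FEATURE_INDEX_PAIRS[k] of the 10-atom block
    index_map = FEATURE_INDEX_PAIRS

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} distances, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def as_feature_array(f) -> np.ndarray:
    """Accept a DistanceFeature or a plain length-45 array."""
    v = np.asarray(getattr(f, "values", f), dtype=float)
    if v.shape != (N_FEATURES,):
        raise ValueError(f"expected a length-{N_FEATURES} feature, got shape {v.shape}")
    return v


def distance_matrix(coords) -> np.ndarray:
    """10x10 symmetric Euclidean distance matrix of a coordinate block."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (10, 3):
        raise ValueError(f"expected a 10x3 coordinate block, got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return cdist(coords, coords)


def flatten(m, atol: float = 1e-9) -> DistanceFeature:
    """Strict upper triangle of a symmetric zero-diagonal 10x10 matrix,
    row-major, as a DistanceFeature."""
    m = np.asarray(m, dtype=float)
    if m.shape != (10, 10):
        raise ValueError(f"expected a 10x10 matrix, got {m.shape}")
    if np.max(np.abs(m - m.T)) > atol:
        raise ValueError("matrix is not symmetric")
    return DistanceFeature(m[_TRIU_ROWS, _TRIU_COLS].copy())


def unflatten(f) -> np.ndarray:
    """Inverse of :func:`flatten`: rebuild the symmetric 10x10 matrix."""
    v = as_feature_array(f)
    m = np.zeros((10, 10))
    m[_TRIU_ROWS, _TRIU_COLS] = v
    return m + m.T


def swap_pair_order(X):
    """Features of the same pairs with the two residues' roles exchanged.

    Works on a single 45-vector or an (n, 45) matrix.
    """
    X = np.asarray(X, dtype=float)
    return X[..., SWAP_PERMUTATION]


def canonical_pair(a: ResidueRef, b: ResidueRef):
    """Fixed pair ordering: lexicographically smaller (chain, number,
    insertion code) first."""
    return (a, b) if a.key <= b.key else (b, a)


def featurize_pair(s: StructureModel, a: ResidueRef, b: ResidueRef) -> DistanceFeature:
    """Distance feature of a residue pair under the canonical ordering."""
    a, b = canonical_pair(a, b)
    return flatten(distance_matrix(pair_atoms(s, a, b)))


class PairDistanceFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: (n, 10, 3) coordinate blocks -> (n, 45)
    distance features.  Fits into sklearn pipelines ahead of the classifier."""

    def fit(self, X, y=None):
        self._check(X)
        self.n_features_in_ = 30  # 10 atoms x 3 coordinates
        return self

    @staticmethod
    def _check(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (10, 3):
            raise ValueError(f"expected (n, 10, 3) coordinate blocks, got {X.shape}")
        return X

    def transform(self, X):
        X = self._check(X)
        diff = X[:, :, None, :] - X[:, None, :, :]
        d = np.sqrt(np.einsum("nijk,nijk->nij", diff, diff))
        return d[:, _TRIU_ROWS, _TRIU_COLS]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
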