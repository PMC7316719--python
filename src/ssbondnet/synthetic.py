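"""Synthetic structures and feature clouds for testing and benchmarking.

Everything here is generated geometry, not real protein data.  Residues are
ideal-geometry five-atom units (N, CA, C, O, CB built from standard bond
lengths and angles with L-chirality).  Two regimes of pair geometry are
produced:

* positive ("bonded-like"): CA-CA distance in 4.0-6.5 Angstrom with the two
  CB atoms facing each other at ~3.8 Angstrom — the compact geometry of
  natural disulfide bridges;
* negative ("non-bonded"): CA-CA in 3.0-7.5 Angstrom but with the CB atoms
  pointing apart, forced beyond 5.5 Angstrom.

The two regimes have disjoint CB-CB supports *by construction*, so a
trained classifier has a provable performance floor (a single CB-CB
threshold already separates them).  That deliberately sacrifices realism
for testability: real engineered-site prediction is harder than these
clouds, and passing on them shows correctness of the pipeline, not
field performance.

Synthetic structures place such pairs (bonded pairs become SSBOND-declared
cysteines, "decoy" pairs get the non-bonded geometry) on a widely spaced
backbone line so that no accidental pair enters the prescreen window, and
return a truth table with the planted bonds and the crossing-pair negative
each bond should yield — computed here, independently of the sampling
module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import PairDistanceFeaturizer
from .sampling import LabelledDataset, ResiduePairSample
from .structure_io import (ResidueAtoms, ResidueRef, SSBondRecord,
                           StructureModel, write_structure)

logger = logging.getLogger(__name__)

__all__ = [
    "GeometrySpec",
    "IDEAL_TEMPLATE",
    "make_residue",
    "make_structure",
    "make_feature_clouds",
    "write_fixture",
]


@dataclass
class GeometrySpec:
    """Geometry regimes of the synthetic positive and negative clouds.

    All lengths in Angstrom.  ``jitter`` is the per-atom isotropic Gaussian
    noise applied after placement.
    """

    pos_cb_cb: float = 3.8
    pos_ca_range: tuple = (4.0, 6.5)
    neg_ca_range: tuple = (3.0, 7.5)
    neg_cb_min: float = 5.5
    jitter: float = 0.15


# ----------------------------------------------------- ideal residue template

def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Internal-coordinate (NeRF) placement: new atom bonded to ``c`` with
    the given bond length, angle new-c-b, and dihedral new-c-b-a."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(dih),
                  bond * math.sin(ang) * math.sin(dih)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_template() -> np.ndarray:
    """Ideal residue coordinates (N, CA, C, O, CB), CA at the origin."""
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])  # N-CA bond
    # C with N-CA-C angle 111.0 deg, in the xy-plane
    theta = math.radians(111.0)
    c = 1.525 * np.array([math.cos(theta), math.sin(theta), 0.0])
    # carbonyl O: C-O 1.231, CA-C-O 120.5 deg, dihedral N-CA-C-O 135 deg
    o = _place_atom(n, ca, c, 1.231, 120.5, 135.0)
    # CB: CA-CB 1.53, N-CA-CB 110.5 deg, dihedral C-N-CA-CB picked for
    # L-chirality (CB on the same side as in natural residues)
    cb = _place_atom(c, n, ca, 1.53, 110.5, -122.55)
    coords = np.stack([n, ca, c, o, cb])
    return coords - coords.mean(axis=0) * 0  # CA stays at origin


IDEAL_TEMPLATE = _build_template()
_CB_AXIS = IDEAL_TEMPLATE[4] / np.linalg.norm(IDEAL_TEMPLATE[4])  # CA at origin
CB_LEN = float(np.linalg.norm(IDEAL_TEMPLATE[4]))


def _rotation_between(u, v) -> np.ndarray:
    """Rotation matrix sending unit vector u to unit vector v (Rodrigues)."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(u @ v)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, math.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _axis_rotation(axis, math.atan2(s, c))


def _axis_rotation(axis, angle) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _jitter_residue(rng, coords5, sigma, max_tries: int = 100) -> np.ndarray:
    """Per-atom Gaussian jitter, redrawn (rarely) if it would push a bonded
    N-CA / CA-C / C-O distance outside the 0.8-2.2 Angstrom sanity window."""
    if sigma <= 0:
        return coords5
    for _ in range(max_tries):
        out = coords5 + rng.normal(scale=sigma, size=coords5.shape)
        ok = all(0.8 <= np.linalg.norm(out[i] - out[j]) <= 2.2
                 for i, j in ((0, 1), (1, 2), (2, 3)))
        if ok:
            return out
    return coords5


def _jitter_block(rng, block, sigma) -> np.ndarray:
    return np.vstack([_jitter_residue(rng, block[:5], sigma),
                      _jitter_residue(rng, block[5:], sigma)])


def make_residue(ref: ResidueRef | None = None, rotation=None, translation=None,
                 jitter: float = 0.0, rng=None) -> ResidueAtoms:
    """An ideal-geometry residue rigidly placed (rotation then translation),
    optionally with per-atom Gaussian jitter."""
    coords = IDEAL_TEMPLATE.copy()
    if rotation is not None:
        coords = coords @ np.asarray(rotation, dtype=float).T
    if translation is not None:
        coords = coords + np.asarray(translation, dtype=float)
    if jitter > 0:
        if rng is None:
            raise ValueError("jitter requires an rng")
        coords = _jitter_residue(rng, coords, jitter)
    if ref is None:
        ref = ResidueRef("A", 1, "", "ALA")
    return ResidueAtoms(ref, coords, cb_source="observed")


# ------------------------------------------------------------ pair geometry

def _oriented_residue(cb_direction, roll_angle) -> np.ndarray:
    """Template coordinates rotated so the CA->CB axis points along
    ``cb_direction``, after a roll about the original CB axis."""
    roll = _axis_rotation(_CB_AXIS, roll_angle)
    align = _rotation_between(_CB_AXIS, cb_direction)
    return IDEAL_TEMPLATE @ roll.T @ align.T


def sample_pair_geometry(rng, spec: GeometrySpec, label: int) -> np.ndarray:
    """One 10x3 coordinate block from the positive (label 1) or negative
    (label 0) geometry regime, in a random global pose."""
    r = CB_LEN
    if label == 1:
        a = rng.uniform(*spec.pos_ca_range)
        dcb = spec.pos_cb_cb
        # residue A's CB points at B (+x); CB_A = (r, 0, 0)
        e_a = np.array([1.0, 0.0, 0.0])
        cos_phi = (dcb * dcb - (a - r) ** 2 - r * r) / (2 * r * (a - r))
    else:
        a = rng.uniform(*spec.neg_ca_range)
        lo = max(a, spec.neg_cb_min + 0.1)
        hi = a + 2 * r - 0.05
        dcb = rng.uniform(lo, hi)
        # residue A's CB points away from B (-x); CB_A = (-r, 0, 0)
        e_a = np.array([-1.0, 0.0, 0.0])
        cos_phi = (dcb * dcb - (a + r) ** 2 - r * r) / (2 * r * (a + r))
    cos_phi = float(np.clip(cos_phi, -1.0, 1.0))
    phi = math.acos(cos_phi)
    e_b = np.array([math.cos(phi), math.sin(phi), 0.0])

    res_a = _oriented_residue(e_a, rng.uniform(0, 2 * math.pi))
    res_b = _oriented_residue(e_b, rng.uniform(0, 2 * math.pi))
    res_b = res_b + np.array([a, 0.0, 0.0])
    # spin residue B about the CA_A-CA_B axis (x); CB_A lies on that axis,
    # so both the CA-CA and CB-CB distances are preserved
    spin = _axis_rotation([1.0, 0.0, 0.0], rng.uniform(0, 2 * math.pi))
    res_b = res_b @ spin.T
    block = np.vstack([res_a, res_b])
    # random global pose + jitter
    block = block @ _random_rotation(rng).T + rng.normal(scale=10.0, size=3)
    return _jitter_block(rng, block, spec.jitter)


# ------------------------------------------------------------ feature clouds

def make_feature_clouds(n_per_class: int, spec: GeometrySpec | None = None,
                        seed: int = 0, test_fraction: float = 0.25) -> LabelledDataset:
    """Balanced labelled dataset of distance features from the two geometry
    regimes, with a seeded uniform train/test split."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    spec = spec or GeometrySpec()
    rng = np.random.default_rng(seed)
    blocks = []
    labels = []
    samples = []
    n_neg_outside = 0
    for label in (1, 0):
        for k in range(n_per_class):
            block = sample_pair_geometry(rng, spec, label)
            blocks.append(block)
            labels.append(label)
            d_ca = float(np.linalg.norm(block[1] - block[6]))
            if label == 0 and not 3.0 <= d_ca <= 7.5:
                n_neg_outside += 1
            samples.append(ResiduePairSample(
                structure_id=f"cloud-{label}-{k}",
                a=ResidueRef("A", 1, "", "CYS" if label else "ALA"),
                b=ResidueRef("A", 5, "", "CYS" if label else "ALA"),
                coords=block, label=label, origin="synthetic-cloud"))
    if n_neg_outside:
        logger.info("feature clouds: %d/%d negatives fall outside the "
                    "3.0-7.5 A prescreen window after jitter",
                    n_neg_outside, n_per_class)
    features = PairDistanceFeaturizer().fit_transform(np.stack(blocks))
    labels = np.array(labels, dtype=int)
    n = len(labels)
    n_test = int(round(test_fraction * n))
    split = np.full(n, "train", dtype=object)
    split[rng.permutation(n)[:n_test]] = "test"
    return LabelledDataset(samples, features, labels, split)


# --------------------------------------------------------------- structures

_SPACING = 12.0  # backbone-line spacing; keeps unplanted pairs out of the
                 # 3.0-7.5 A prescreen window
_SLOT = 5        # residues consumed per planted pair (pair + flanks)


def make_structure(n_residues: int, planted_bonds: int,
                   spec: GeometrySpec | None = None, seed: int = 0,
                   decoys: int = 0, gly_fraction: float = 0.0,
                   n_chains: int = 1, pdb_path=None):
    """Synthetic structure with planted disulfide pairs.

    Residues sit on a line at 12 Angstrom spacing; each planted bond (and
    each non-bonded decoy pair) occupies a 5-residue slot whose middle pair
    is re-placed in the bonded (resp. non-bonded) geometry regime,
    perpendicular to the line so no accidental pair enters the prescreen
    window.  Planted bonds become CYS residues with SSBOND records.

    Returns ``(model, truth)`` where ``truth`` is a DataFrame listing every
    planted bond and the crossing-pair negative it should yield (computed
    here by direct distance comparison).  If ``pdb_path`` is given the
    structure is also written as a PDB file.
    """
    spec = spec or GeometrySpec()
    n_pairs = planted_bonds + decoys
    if n_residues < 2 * planted_bonds + 2:
        raise ValueError("need n_residues >= 2 * planted_bonds + 2")
    if n_pairs * _SLOT > n_residues:
        raise ValueError(
            f"{n_residues} residues cannot host {n_pairs} planted pairs "
            f"({_SLOT} residues per pair)")
    if n_chains not in (1, 2):
        raise ValueError("n_chains must be 1 or 2")
    rng = np.random.default_rng(seed)

    # chain assignment and per-chain author numbering
    split_at = n_residues // 2 if n_chains == 2 else n_residues
    chain_of = ["A" if k < split_at else "B" for k in range(n_residues)]
    number_of = [k + 1 if k < split_at else k - split_at + 1
                 for k in range(n_residues)]

    # base placement: ideal residues along x, random orientation
    coords = [None] * n_residues
    for k in range(n_residues):
        base = np.array([_SPACING * k, 0.0, 0.0])
        coords[k] = (IDEAL_TEMPLATE @ _random_rotation(rng).T) + base

    # planted pairs occupy slots [5m, 5m+4]; the pair is (5m+1, 5m+3)
    pair_kinds = [1] * planted_bonds + [0] * decoys
    pair_members = {}
    bonds_idx = []
    for m, kind in enumerate(pair_kinds):
        i, j = _SLOT * m + 1, _SLOT * m + 3
        block = sample_pair_geometry(rng, GeometrySpec(
            pos_cb_cb=spec.pos_cb_cb, pos_ca_range=spec.pos_ca_range,
            neg_ca_range=spec.neg_ca_range, neg_cb_min=spec.neg_cb_min,
            jitter=0.0), kind)
        # re-pose: CA_A at residue i's base position, pair axis along +y
        # (perpendicular to the backbone line), random roll about that axis
        axis = block[6] - block[1]
        axis_len = np.linalg.norm(axis)
        align = _rotation_between(axis / axis_len, [0.0, 1.0, 0.0])
        roll = _axis_rotation([0.0, 1.0, 0.0], rng.uniform(0, 2 * math.pi))
        block = (block - block[1]) @ align.T @ roll.T
        block = block + np.array([_SPACING * i, 0.0, 0.0])
        block = _jitter_block(rng, block, spec.jitter)
        coords[i] = block[:5]
        coords[j] = block[5:]
        pair_members[i] = kind
        pair_members[j] = kind
        if kind == 1:
            bonds_idx.append((i, j))

    # residue names
    names = []
    for k in range(n_residues):
        if pair_members.get(k) == 1:
            names.append("CYS")
        elif gly_fraction > 0 and rng.uniform() < gly_fraction and k not in pair_members:
            names.append("GLY")
        else:
            names.append("ALA")

    chains: dict[str, list] = {}
    refs = []
    for k in range(n_residues):
        ref = ResidueRef(chain_of[k], number_of[k], "", names[k])
        refs.append(ref)
        chains.setdefault(chain_of[k], []).append(
            ResidueAtoms(ref, np.asarray(coords[k]), cb_source="observed"))
    ssbonds = [SSBondRecord.make(refs[i], refs[j]) for i, j in bonds_idx]
    model = StructureModel(id=f"SYN{seed}", chains=chains, ssbonds=ssbonds)

    # truth table: expected crossing-pair negative per bond, by direct
    # CA-distance comparison over the sequence neighbours (within-chain
    # adjacency), independent of the sampling module
    rows = []
    for i, j in bonds_idx:
        cands = []
        for di in (-1, +1):
            for dj in (-1, +1):
                ii, jj = i + di, j + dj
                if not (0 <= ii < n_residues and 0 <= jj < n_residues):
                    continue
                if chain_of[ii] != chain_of[i] or chain_of[jj] != chain_of[j]:
                    continue
                if ii == jj:
                    continue
                d = float(np.linalg.norm(coords[ii][1] - coords[jj][1]))
                cands.append((d, ii, jj))
        if not cands:
            continue
        _, ni, nj = min(cands, key=lambda t: t[0])
        rows.append({
            "bond_chain_a": chain_of[i], "bond_resnum_a": number_of[i],
            "bond_chain_b": chain_of[j], "bond_resnum_b": number_of[j],
            "neg_chain_a": chain_of[ni], "neg_resnum_a": number_of[ni],
            "neg_chain_b": chain_of[nj], "neg_resnum_b": number_of[nj],
        })
    truth = pd.DataFrame(rows, columns=[
        "bond_chain_a", "bond_resnum_a", "bond_chain_b", "bond_resnum_b",
        "neg_chain_a", "neg_resnum_a", "neg_chain_b", "neg_resnum_b"])

    if pdb_path is not None:
        write_structure(model, pdb_path)
    return model, truth


def write_fixture(model: StructureModel, truth: pd.DataFrame,
                  pdb_path, truth_path) -> None:
    """Write a generated structure and its truth table to disk."""
    write_structure(model, pdb_path)
    truth.to_csv(truth_path, index=False)
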