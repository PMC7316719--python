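"""Candidate enumeration, prescreening, scoring and ranking.

For a target structure with n usable residues there are n(n-1)/2 unordered
residue pairs that could in principle be mutated to a cystine bridge.  A
cheap geometric prescreen — the CA-CA distance window 3.0-7.5 Angstrom in
which natural disulfide bonds overwhelmingly fall — cuts this to a short
list, which is then scored by the trained classifier and ranked by
descending score.  Ranks follow the reporting convention of engineered-bond
benchmarks: absolute rank counts from 0 down the score-sorted list, and
relative rank is abs_rank / (total - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, canonical_pair, featurize_pair
from .model import DisulfideBondClassifier
from .structure_io import ResidueRef, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "PrescreenConfig",
    "PredictionRecord",
    "enumerate_pairs",
    "prescreen",
    "predict_sites",
    "write_report",
    "read_report",
]


@dataclass
class PrescreenConfig:
    """Geometric pre-filter ahead of classifier scoring.

    ca_min/ca_max bound the CA-CA distance (inclusive).  Pairs within one
    chain must be at least ``min_sequence_separation`` apart in the chain's
    residue list (adjacent-residue bridges are vanishingly rare); set it to
    0 to disable.  ``include_native_cys`` keeps pairs involving an existing
    cysteine, which lets a single mutation pair with a native one.
    """

    ca_min: float = 3.0
    ca_max: float = 7.5
    min_sequence_separation: int = 2
    include_native_cys: bool = True

    def __post_init__(self):
        if not 0.0 < self.ca_min < self.ca_max:
            raise ValueError("require 0 < ca_min < ca_max")


@dataclass
class PredictionRecord:
    """A scored candidate pair with its provenance and rank."""

    a: ResidueRef
    b: ResidueRef
    ca_distance: float
    score: float
    abs_rank: int = -1
    rel_rank: float = 0.0
    predicted: str = "nonbonded"  # "bonded" | "nonbonded"

    @property
    def wild_types(self) -> tuple:
        return (self.a.amino_acid, self.b.amino_acid)


def enumerate_pairs(s: StructureModel) -> list:
    """All n(n-1)/2 unordered pairs of usable residues, across all chains,
    each in canonical order."""
    refs = [r.ref for r in s.residues()]
    return [(refs[i], refs[j])
            for i in range(len(refs)) for j in range(i + 1, len(refs))]


def prescreen(pairs, s: StructureModel, cfg: PrescreenConfig | None = None) -> list:
    """Filter pairs by the CA-CA window and sequence separation."""
    cfg = cfg or PrescreenConfig()
    kept = []
    for a, b in pairs:
        ra, rb = s.get(a), s.get(b)
        if not cfg.include_native_cys and "CYS" in (a.amino_acid, b.amino_acid):
            continue
        d = float(np.linalg.norm(ra.ca - rb.ca))
        if not cfg.ca_min <= d <= cfg.ca_max:
            continue
        if a.chain_id == b.chain_id:
            sep = abs(s.chain_position(a) - s.chain_position(b))
            if sep < cfg.min_sequence_separation:
                continue
        kept.append((a, b))
    return kept


def predict_sites(s: StructureModel, model: DisulfideBondClassifier,
                  cfg: PrescreenConfig | None = None) -> list:
    """Score the prescreened candidate pairs of a structure.

    Returns PredictionRecords sorted by descending score (ties broken by
    the identity of the first residue), with ranks assigned and the hard
    bonded/nonbonded call made at the model threshold.
    """
    cfg = cfg or PrescreenConfig()
    pairs = prescreen(enumerate_pairs(s), s, cfg)
    if not pairs:
        return []
    records = []
    X = np.empty((len(pairs), len(FEATURE_NAMES)))
    for k, (a, b) in enumerate(pairs):
        a, b = canonical_pair(a, b)
        X[k] = featurize_pair(s, a, b).values
        d = float(np.linalg.norm(s.get(a).ca - s.get(b).ca))
        records.append(PredictionRecord(a, b, ca_distance=d, score=np.nan))
    scores = model.predict_proba(X)[:, 1]
    for rec, sc in zip(records, scores):
        rec.score = float(sc)
        rec.predicted = "bonded" if sc >= model.threshold else "nonbonded"
    records.sort(key=lambda r: (-r.score, r.a.key, r.b.key))
    total = len(records)
    for rank, rec in enumerate(records):
        rec.abs_rank = rank
        rec.rel_rank = rank / (total - 1) if total > 1 else 0.0
    return records


_REPORT_COLUMNS = [
    "abs_rank", "rel_rank", "score", "predicted",
    "chain_a", "resnum_a", "icode_a", "aa_a",
    "chain_b", "resnum_b", "icode_b", "aa_b",
    "ca_distance",
]


def write_report(records, path) -> None:
    """Write PredictionRecords as CSV, one row per record in rank order."""
    rows = [{
        "abs_rank": r.abs_rank,
        "rel_rank": round(r.rel_rank, 6),
        "score": round(r.score, 6),
        "predicted": r.predicted,
        "chain_a": r.a.chain_id, "resnum_a": r.a.residue_number,
        "icode_a": r.a.insertion_code, "aa_a": r.a.amino_acid,
        "chain_b": r.b.chain_id, "resnum_b": r.b.residue_number,
        "icode_b": r.b.insertion_code, "aa_b": r.b.amino_acid,
        "ca_distance": round(r.ca_distance, 3),
    } for r in sorted(records, key=lambda r: r.abs_rank)]
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    return pd.read_csv(path, keep_default_na=False, na_values=[""])
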