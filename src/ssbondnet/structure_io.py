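"""Protein structure input/output.

Reads PDB files into a light-weight per-residue representation holding the
five heavy atoms this package works with (N, CA, C, O, CB), extracts
disulfide-bond declarations (SSBOND records), and reconstructs an ideal CB
position for glycine from its backbone.  Sulfur atoms are never read or
used: the featurization is designed for candidate sites where the cysteine
side chain does not exist yet.

Parsing and writing are delegated to :mod:`gemmi`; this module only decides
which residues are usable and normalises identifiers.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueRef",
    "ResidueAtoms",
    "SSBondRecord",
    "StructureModel",
    "StructureMeta",
    "StructureParseError",
    "ResidueLookupError",
    "read_structure",
    "write_structure",
    "read_metadata",
    "build_cb",
    "pair_atoms",
]

#: atom names stored per residue, in storage order
ATOM_ORDER = ("N", "CA", "C", "O", "CB")
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: ideal CA-CB bond length in Angstrom
CB_BOND_LENGTH = 1.53
#: ideal N-CA-CB (and C-CA-CB) tetrahedral-like angle in degrees
CB_ANGLE_DEG = 110.5

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# common chemically-modified residues mapped to their parent standard residue;
# anything not listed here and not standard is dropped
NONSTANDARD_PARENT = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "CSO": "CYS",  # S-hydroxycysteine
    "CME": "CYS",
    "OCS": "CYS",
    "HYP": "PRO",
    "MLY": "LYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

# bonded-atom sanity window (Angstrom) for N-CA, CA-C, C-O
BOND_SANITY = (0.8, 2.2)


class StructureParseError(ValueError):
    """Raised when a structure file cannot be turned into a usable model."""


class ResidueLookupError(KeyError):
    """Raised when a referenced residue is absent from a model."""


@dataclass(frozen=True)
class ResidueRef:
    """Identity of one residue: chain, author residue number, insertion code,
    and 3-letter amino-acid code."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    amino_acid: str = ""

    @property
    def key(self) -> tuple:
        """Identity key (amino-acid name excluded): chain, number, icode."""
        return (self.chain_id, self.residue_number, self.insertion_code)

    def __str__(self) -> str:
        ic = self.insertion_code or ""
        aa = self.amino_acid or "???"
        return f"{aa} {self.chain_id}:{self.residue_number}{ic}"


@dataclass
class ResidueAtoms:
    """One residue's (N, CA, C, O, CB) coordinates, in Angstrom.

    ``cb_source`` records whether CB was observed in the file or rebuilt
    from the backbone (always the case for glycine).
    """

    ref: ResidueRef
    coords: np.ndarray  # (5, 3) float64, rows follow ATOM_ORDER
    cb_source: str = "observed"  # "observed" | "reconstructed"

    @property
    def ca(self) -> np.ndarray:
        return self.coords[1]


@dataclass(frozen=True)
class SSBondRecord:
    """A disulfide bond declared in a structure file (unordered residue pair,
    stored with the lexicographically smaller (chain, number, icode) first)."""

    first: ResidueRef
    second: ResidueRef

    @staticmethod
    def make(a: ResidueRef, b: ResidueRef) -> "SSBondRecord":
        if b.key < a.key:
            a, b = b, a
        return SSBondRecord(a, b)

    @property
    def key_pair(self) -> tuple:
        return (self.first.key, self.second.key)

    def __str__(self) -> str:
        return f"{self.first}--{self.second}"


@dataclass
class StructureMeta:
    """Experimental metadata used for dataset curation."""

    id: str
    resolution: float | None = None
    r_factor: float | None = None


@dataclass
class StructureModel:
    """Parsed structure: per-chain ordered residue lists plus SSBOND pairs."""

    id: str
    chains: dict = field(default_factory=dict)  # chain_id -> list[ResidueAtoms]
    ssbonds: list = field(default_factory=list)  # list[SSBondRecord]

    def __post_init__(self):
        self._reindex()

    def _reindex(self) -> None:
        self._index = {}
        self._position = {}
        for chain_id, residues in self.chains.items():
            residues.sort(key=lambda r: (r.ref.residue_number, r.ref.insertion_code))
            for i, res in enumerate(residues):
                if res.ref.key in self._index:
                    raise StructureParseError(f"duplicate residue {res.ref} in {self.id}")
                self._index[res.ref.key] = res
                self._position[res.ref.key] = (chain_id, i)

    def residues(self):
        """Iterate residues chain by chain, in residue order."""
        for chain_id in self.chains:
            yield from self.chains[chain_id]

    @property
    def n_residues(self) -> int:
        return len(self._index)

    def __contains__(self, ref: ResidueRef) -> bool:
        return ref.key in self._index

    def get(self, ref: ResidueRef) -> ResidueAtoms:
        try:
            return self._index[ref.key]
        except KeyError:
            raise ResidueLookupError(f"residue {ref} not in structure {self.id}") from None

    def chain_position(self, ref: ResidueRef) -> int:
        """0-based position of a residue within its chain's ordered list."""
        self.get(ref)  # raises ResidueLookupError if absent
        return self._position[ref.key][1]

    def neighbors(self, ref: ResidueRef):
        """Sequence neighbours (previous, next) of a residue within its own
        chain, by adjacency in the ordered residue list.  Either may be None
        at a chain terminus."""
        chain_id, i = self._position[self.get(ref).ref.key]
        residues = self.chains[chain_id]
        prev_res = residues[i - 1].ref if i > 0 else None
        next_res = residues[i + 1].ref if i + 1 < len(residues) else None
        return prev_res, next_res

    def is_bonded_pair(self, a: ResidueRef, b: ResidueRef) -> bool:
        pair = SSBondRecord.make(a, b).key_pair
        return any(bond.key_pair == pair for bond in self.ssbonds)


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
             length: float = CB_BOND_LENGTH) -> np.ndarray:
    """Ideal CB position from backbone N, CA, C.

    Places CB at `length` from CA with ~110.5 degree angles to both the
    CA->N and CA->C directions and the chirality of an L-amino acid (the
    placement a standard alanine template would give after superposing its
    backbone onto the inputs).

    Raises ValueError on a degenerate (collinear or overlapping) backbone.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    nv = n - ca
    cv = c - ca
    norm_n = np.linalg.norm(nv)
    norm_c = np.linalg.norm(cv)
    if norm_n < 1e-6 or norm_c < 1e-6:
        raise ValueError("degenerate backbone: overlapping atoms")
    nv /= norm_n
    cv /= norm_c
    perp = np.cross(nv, cv)  # sign encodes L-chirality
    norm_p = np.linalg.norm(perp)
    if norm_p < 1e-6:
        raise ValueError("degenerate backbone: collinear N, CA, C")
    perp /= norm_p
    bis = nv + cv
    bis /= np.linalg.norm(bis)
    # direction d = -alpha * bisector + beta * perp with |d| = 1 so that
    # angle(d, nv) = angle(d, cv) = CB_ANGLE_DEG
    alpha = -math.cos(math.radians(CB_ANGLE_DEG)) / float(nv @ bis)
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    d = -alpha * bis + beta * perp
    d /= np.linalg.norm(d)
    return ca + length * d


def pair_atoms(s: StructureModel, a: ResidueRef, b: ResidueRef) -> np.ndarray:
    """10x3 coordinate block for a residue pair: rows 0-4 are residue ``a``
    (N, CA, C, O, CB), rows 5-9 residue ``b`` in the same atom order."""
    ra = s.get(a)
    rb = s.get(b)
    return np.vstack([ra.coords, rb.coords])


def _residue_name(raw: str) -> str | None:
    name = raw.strip().upper()
    if name in STANDARD_AA:
        return name
    return NONSTANDARD_PARENT.get(name)


def _bond_lengths_ok(coords: np.ndarray) -> bool:
    lo, hi = BOND_SANITY
    for i, j in ((0, 1), (1, 2), (2, 3)):  # N-CA, CA-C, C-O
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if not (lo <= d <= hi):
            return False
    return True


def read_structure(path, model_index: int = 0) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    Only the first model is used unless ``model_index`` says otherwise
    (relevant for NMR entries).  Alternate conformations are collapsed to
    the one gemmi keeps (altloc '' or 'A').  Residues missing any of
    N, CA, C, O are dropped with a warning; a missing CB drops the residue
    too unless it is glycine, whose CB is reconstructed from the backbone.
    SSBOND records whose residues did not survive are dropped, never
    returned dangling.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.remove_hydrogens()
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models / empty coordinate section")
    if model_index >= len(st):
        raise StructureParseError(
            f"{path}: model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    chains: dict[str, list[ResidueAtoms]] = {}
    seen: set[tuple] = set()
    for chain in model:
        for res in chain:
            name = _residue_name(res.name)
            if name is None:
                continue  # water, ligands, unmapped modified residues
            atoms = {}
            for atom in res:
                if atom.name in ATOM_ORDER and atom.name not in atoms:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            ref = ResidueRef(chain.name, res.seqid.num,
                             res.seqid.icode.strip(), name)
            if ref.key in seen:
                logger.warning("%s: duplicate residue %s, keeping first", path.name, ref)
                continue
            missing_bb = [a for a in BACKBONE_ATOMS if a not in atoms]
            if missing_bb:
                logger.warning("%s: dropping %s (missing %s)",
                               path.name, ref, ",".join(missing_bb))
                continue
            cb_source = "observed"
            if "CB" not in atoms:
                if name != "GLY":
                    logger.warning("%s: dropping %s (missing CB)", path.name, ref)
                    continue
                try:
                    atoms["CB"] = build_cb(atoms["N"], atoms["CA"], atoms["C"])
                except ValueError as exc:
                    logger.warning("%s: dropping %s (%s)", path.name, ref, exc)
                    continue
                cb_source = "reconstructed"
            coords = np.stack([atoms[a] for a in ATOM_ORDER])
            if not np.all(np.isfinite(coords)):
                logger.warning("%s: dropping %s (non-finite coordinates)", path.name, ref)
                continue
            if not _bond_lengths_ok(coords):
                logger.warning("%s: dropping %s (implausible bond lengths)", path.name, ref)
                continue
            seen.add(ref.key)
            chains.setdefault(chain.name, []).append(
                ResidueAtoms(ref, coords, cb_source))

    if not chains:
        raise StructureParseError(f"{path}: no usable residues")

    sm = StructureModel(id=st.name or path.stem, chains=chains)

    ssbonds: list[SSBondRecord] = []
    seen_bonds: set[tuple] = set()
    for conn in st.connections:
        if conn.type != gemmi.ConnectionType.Disulf:
            continue
        refs = []
        for partner in (conn.partner1, conn.partner2):
            name = _residue_name(partner.res_id.name) or partner.res_id.name
            refs.append(ResidueRef(partner.chain_name, partner.res_id.seqid.num,
                                   partner.res_id.seqid.icode.strip(), name))
        a, b = refs
        if a not in sm or b not in sm:
            logger.warning("%s: dropping dangling SSBOND %s--%s", path.name, a, b)
            continue
        # normalise amino-acid codes to the ones stored in the model
        a = sm.get(a).ref
        b = sm.get(b).ref
        bond = SSBondRecord.make(a, b)
        if bond.key_pair in seen_bonds:
            continue
        seen_bonds.add(bond.key_pair)
        ssbonds.append(bond)
    sm.ssbonds = ssbonds
    return sm


def _ssbond_line(serial: int, bond: SSBondRecord) -> str:
    def half(ref: ResidueRef) -> str:
        ic = ref.insertion_code or " "
        return f"CYS {ref.chain_id[:1]:1s} {ref.residue_number:4d}{ic:1s}"
    return f"SSBOND {serial:3d} {half(bond.first)}   {half(bond.second)}"


def write_structure(s: StructureModel, path) -> None:
    """Write a StructureModel as a PDB file (ATOM records + SSBOND lines).

    Glycine residues are written without their (reconstructed) CB so the
    file stays chemically truthful; re-reading reconstructs it again.
    """
    path = Path(path)
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for chain_id, residues in s.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.ref.amino_acid
            gr.seqid = gemmi.SeqId(res.ref.residue_number,
                                   res.ref.insertion_code or " ")
            for row, atom_name in enumerate(ATOM_ORDER):
                if atom_name == "CB" and res.ref.amino_acid == "GLY":
                    continue
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(elements[atom_name])
                x, y, z = (float(v) for v in res.coords[row])
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = 0.0
                gr.add_atom(atom)
            chain.add_residue(gr)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    if s.ssbonds:
        # gemmi only emits SSBOND when SG atoms exist; prepend the records
        body = path.read_text()
        lines = "".join(_ssbond_line(i + 1, b) + "\n"
                        for i, b in enumerate(s.ssbonds))
        path.write_text(lines + body)


_RFACTOR_RE = re.compile(
    r"REMARK   3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)")


def read_metadata(path) -> StructureMeta:
    """Resolution and working-set R-factor of a PDB entry, where recorded."""
    path = Path(path)
    st = gemmi.read_structure(str(path))
    resolution = st.resolution if st.resolution > 0 else None
    r_factor = None
    try:
        for line in path.read_text(errors="replace").splitlines():
            m = _RFACTOR_RE.match(line)
            if m:
                r_factor = float(m.group(1))
                break
    except OSError:
        pass
    return StructureMeta(id=st.name or path.stem,
                         resolution=resolution, r_factor=r_factor)
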