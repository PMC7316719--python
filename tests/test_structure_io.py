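"""Structure parsing, CB reconstruction and coordinate round-trips."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ssbondnet import (ResidueRef, StructureModel, build_cb, make_residue,
                       make_structure, pair_atoms, read_structure,
                       write_structure)
from ssbondnet.sampling import curate_filter
from ssbondnet.structure_io import (StructureMeta, StructureParseError,
                                    ResidueLookupError, read_metadata)
from conftest import rigid_motion

# Ideal L-alanine heavy-atom geometry (MMFF-optimised small-molecule
# conformer); serves as an independent template for CB placement checks.
L_ALANINE = {
    "N": np.array([-0.824, 1.106, -0.742]),
    "CA": np.array([-0.351, 0.233, 0.358]),
    "CB": np.array([-1.094, -1.094, 0.302]),
    "C": np.array([1.165, 0.008, 0.276]),
}


def _superpose_cb(n, ca, c):
    """Oracle: least-squares superpose the alanine template's (N, CA, C)
    onto the target backbone and read off where its CB lands."""
    src = np.stack([L_ALANINE[a] for a in ("N", "CA", "C")])
    dst = np.stack([n, ca, c])
    src_c, dst_c = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - dst_c, src - src_c)
    return rot.apply(L_ALANINE["CB"] - src_c) + dst_c


class TestBuildCb:
    def test_matches_superposed_alanine_template(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            rot, t = rigid_motion(rng)
            n, ca, c = (rot @ L_ALANINE[a] + t for a in ("N", "CA", "C"))
            cb = build_cb(n, ca, c)
            assert np.linalg.norm(cb - _superpose_cb(n, ca, c)) < 0.25

    def test_bond_length_and_translation_equivariance(self):
        n, ca, c = L_ALANINE["N"], L_ALANINE["CA"], L_ALANINE["C"]
        cb = build_cb(n, ca, c)
        assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=1e-9)
        shift = np.array([3.0, -7.0, 11.0])
        assert np.allclose(build_cb(n + shift, ca + shift, c + shift),
                           cb + shift, atol=1e-9)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        n, ca, c = L_ALANINE["N"], L_ALANINE["CA"], L_ALANINE["C"]
        cb = build_cb(n, ca, c)
        worst = 0.0
        for _ in range(100):
            rot, _ = rigid_motion(rng)
            err = np.linalg.norm(build_cb(rot @ n, rot @ ca, rot @ c) - rot @ cb)
            worst = max(worst, err)
        assert worst < 1e-9

    def test_degenerate_backbone_raises(self):
        with pytest.raises(ValueError):
            build_cb([0, 0, 0], [1, 0, 0], [2, 0, 0])  # collinear
        with pytest.raises(ValueError):
            build_cb([0, 0, 0], [0, 0, 0], [1, 1, 0])  # overlapping


class TestReadWrite:
    def test_round_trip_coordinates_within_pdb_precision(self, tmp_path):
        model, _ = make_structure(12, 1, seed=5)
        path = tmp_path / "fixture.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.n_residues == model.n_residues
        for res in model.residues():
            err = np.abs(back.get(res.ref).coords - res.coords).max()
            assert err <= 1e-3 + 1e-9

    def test_ssbond_records_survive_round_trip(self, tmp_path, line_fixture):
        model, _ = line_fixture
        path = tmp_path / "bonds.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert {b.key_pair for b in back.ssbonds} == \
            {b.key_pair for b in model.ssbonds}

    def test_no_ssbond_lines_gives_empty_bond_list(self, tmp_path):
        model, _ = make_structure(8, 0, seed=2)
        path = tmp_path / "nobonds.pdb"
        write_structure(model, path)
        assert "SSBOND" not in path.read_text()
        assert read_structure(path).ssbonds == []

    def test_dangling_ssbond_dropped_with_warning(self, tmp_path, caplog):
        model, _ = make_structure(8, 1, seed=2)
        path = tmp_path / "dangling.pdb"
        write_structure(model, path)
        text = path.read_text()
        text = "SSBOND   2 CYS A   99    CYS A   98\n" + text
        path.write_text(text)
        with caplog.at_level("WARNING"):
            back = read_structure(path)
        assert len(back.ssbonds) == 1
        assert any("dangling" in r.message for r in caplog.records)

    def test_glycine_cb_reconstructed_not_written(self, tmp_path):
        model, _ = make_structure(15, 1, seed=9, gly_fraction=0.8)
        gly = [r for r in model.residues() if r.ref.amino_acid == "GLY"]
        assert gly, "fixture should contain glycines"
        path = tmp_path / "gly.pdb"
        write_structure(model, path)
        assert not any(" CB  GLY" in line for line in path.read_text().splitlines())
        back = read_structure(path)
        for res in gly:
            back_res = back.get(res.ref)
            assert back_res.cb_source == "reconstructed"
            # generator CB and reconstructed CB both follow ideal geometry
            assert np.linalg.norm(back_res.coords[4] - res.coords[4]) < 0.35

    def test_residue_missing_backbone_atom_is_dropped(self, tmp_path, caplog):
        model, _ = make_structure(8, 0, seed=4)
        path = tmp_path / "partial.pdb"
        write_structure(model, path)
        lines = [l for l in path.read_text().splitlines(keepends=True)
                 if not (l.startswith("ATOM") and " O   " in l and " A   3 " in l)]
        path.write_text("".join(lines))
        with caplog.at_level("WARNING"):
            back = read_structure(path)
        assert back.n_residues == model.n_residues - 1
        assert ResidueRef("A", 3, "", "ALA") not in back

    def test_unreadable_and_empty_inputs_are_fatal(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(StructureParseError):
            read_structure(empty)
        model, _ = make_structure(6, 0, seed=1)
        path = tmp_path / "one_model.pdb"
        write_structure(model, path)
        with pytest.raises(StructureParseError):
            read_structure(path, model_index=3)


class TestPairAtoms:
    def test_row_blocks_follow_argument_order(self, line_fixture):
        model, _ = line_fixture
        bond = model.ssbonds[0]
        ab = pair_atoms(model, bond.first, bond.second)
        ba = pair_atoms(model, bond.second, bond.first)
        assert ab.shape == (10, 3)
        assert np.all(np.isfinite(ab))
        assert np.array_equal(ab[:5], ba[5:])
        assert np.array_equal(ab[5:], ba[:5])

    def test_matches_hand_assembled_block(self, line_fixture):
        model, _ = line_fixture
        bond = model.ssbonds[0]
        expected = np.vstack([model.get(bond.first).coords,
                              model.get(bond.second).coords])
        assert np.array_equal(pair_atoms(model, bond.first, bond.second), expected)

    def test_missing_residue_raises_lookup_error(self, line_fixture):
        model, _ = line_fixture
        ghost = ResidueRef("Z", 999, "", "ALA")
        with pytest.raises(ResidueLookupError, match="Z:999"):
            pair_atoms(model, model.ssbonds[0].first, ghost)


class TestMetadataCuration:
    def test_resolution_and_rfactor_parsed(self, tmp_path):
        model, _ = make_structure(6, 0, seed=1)
        path = tmp_path / "meta.pdb"
        write_structure(model, path)
        header = ("REMARK   2 RESOLUTION.    1.80 ANGSTROMS.\n"
                  "REMARK   3   R VALUE            (WORKING SET) : 0.197\n")
        path.write_text(header + path.read_text())
        meta = read_metadata(path)
        assert meta.resolution == pytest.approx(1.80)
        assert meta.r_factor == pytest.approx(0.197)

    def test_curate_filter_strict_thresholds(self):
        entries = [
            StructureMeta("good", 1.8, 0.20),
            StructureMeta("at_resolution_boundary", 2.0, 0.20),
            StructureMeta("at_rfactor_boundary", 1.5, 0.25),
            StructureMeta("missing", None, 0.20),
        ]
        kept = curate_filter(entries, max_resolution=2.0, max_rfactor=0.25)
        assert [e.id for e in kept] == ["good"]

    def test_all_missing_metadata_gives_empty(self):
        entries = [StructureMeta("a"), StructureMeta("b")]
        assert curate_filter(entries) == []
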