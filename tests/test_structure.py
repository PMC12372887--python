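"""Structure parsing and geometric measurements."""

import gemmi
import numpy as np
import pytest

from kinprof.structure import (
    MissingAtomError,
    StructureFormatError,
    apply_transform,
    atom_distance,
    backbone_dihedrals,
    detect_disulfides,
    dihedral_angle,
    read_structure,
    spine_contacts,
    superpose,
    write_structure,
)
from kinprof.synth import build_backbone, make_structure

from conftest import random_rigid_motion, transform_model


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, occ=1.0, altloc=" ", element=None):
    element = element or name[0]
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5} {name_field}{altloc}{resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2}"
    )


class TestReadStructure:
    def test_minimal_one_residue_pdb(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(
            "\n".join(
                [
                    _pdb_atom(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
                    _pdb_atom(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0),
                    _pdb_atom(3, "C", "ALA", "A", 1, 2.0, 1.4, 0.0),
                    "END",
                ]
            )
            + "\n"
        )
        model = read_structure(path)
        assert len(list(model.model)) == 1
        np.testing.assert_allclose(model.atom_pos("A", 1, "CA"), [1.458, 0.0, 0.0])

    def test_pdb_and_mmcif_give_identical_coordinates(self, tmp_path):
        synth, _ = make_structure(0, n_residues=4)
        pdb, cif = tmp_path / "m.pdb", tmp_path / "m.cif"
        write_structure(synth, pdb)
        write_structure(synth, cif)
        a, b = read_structure(pdb), read_structure(cif)
        for num in a.protein_residue_numbers("A"):
            for atom in ("N", "CA", "C"):
                np.testing.assert_allclose(
                    a.atom_pos("A", num, atom), b.atom_pos("A", num, atom), atol=1e-3
                )

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "\n".join(
                [
                    _pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.40, altloc="A"),
                    _pdb_atom(2, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0, occ=0.60, altloc="B"),
                    "END",
                ]
            )
            + "\n"
        )
        model = read_structure(path)
        np.testing.assert_allclose(model.atom_pos("A", 1, "CA"), [9.0, 0.0, 0.0])

    def test_altloc_tie_prefers_conformer_a(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "\n".join(
                [
                    _pdb_atom(1, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0, occ=0.50, altloc="A"),
                    _pdb_atom(2, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0, occ=0.50, altloc="B"),
                    "END",
                ]
            )
            + "\n"
        )
        model = read_structure(path)
        np.testing.assert_allclose(model.atom_pos("A", 1, "CA"), [1.0, 0.0, 0.0])

    def test_missing_file_and_bad_model_index(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")
        synth, _ = make_structure(0, n_residues=3)
        path = tmp_path / "m.pdb"
        write_structure(synth, path)
        with pytest.raises(StructureFormatError, match="model 5"):
            read_structure(path, model_index=5)


class TestAtomDistance:
    def test_three_four_five_triangle(self, tmp_path):
        path = tmp_path / "tri.pdb"
        path.write_text(
            "\n".join(
                [
                    _pdb_atom(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
                    _pdb_atom(2, "CA", "GLY", "A", 2, 3.0, 4.0, 0.0),
                    "END",
                ]
            )
            + "\n"
        )
        model = read_structure(path)
        assert atom_distance(model, ("A", 1, "CA"), ("A", 2, "CA")) == pytest.approx(5.0)

    def test_missing_atom_error_names_residue_and_atom(self, dfg_backbone):
        model, _ = dfg_backbone
        with pytest.raises(MissingAtomError, match="158.*CZ"):
            atom_distance(model, ("A", 156, "CA"), ("A", 158, "CZ"))

    def test_invariant_under_rigid_motion(self, dfg_backbone):
        model, _ = dfg_backbone
        before = atom_distance(model, ("A", 155, "CA"), ("A", 160, "CA"))
        rot, trans = random_rigid_motion(np.random.default_rng(1))
        transform_model(model, rot, trans)
        after = atom_distance(model, ("A", 155, "CA"), ("A", 160, "CA"))
        assert after == pytest.approx(before, abs=1e-9)


class TestDihedrals:
    def test_construct_then_measure_roundtrip_many_angles(self):
        """Backbones built to 1000 random torsion targets measure back exactly."""
        rng = np.random.default_rng(99)
        targets = rng.uniform(-179.9, 179.9, size=(250, 4))
        for phi1, psi1, phi2, psi2 in targets:
            torsions = {11: (None, psi1), 12: (phi1, psi2), 13: (phi2, None)}
            coords = build_backbone(range(10, 15), torsions)
            # measure with the same primitive used on real structures
            phi_12 = dihedral_angle(coords[11]["C"], coords[12]["N"], coords[12]["CA"], coords[12]["C"])
            psi_11 = dihedral_angle(coords[11]["N"], coords[11]["CA"], coords[11]["C"], coords[12]["N"])
            psi_12 = dihedral_angle(coords[12]["N"], coords[12]["CA"], coords[12]["C"], coords[13]["N"])
            phi_13 = dihedral_angle(coords[12]["C"], coords[13]["N"], coords[13]["CA"], coords[13]["C"])
            assert psi_11 == pytest.approx(psi1, abs=1e-6)
            assert phi_12 == pytest.approx(phi1, abs=1e-6)
            assert psi_12 == pytest.approx(psi2, abs=1e-6)
            assert phi_13 == pytest.approx(phi2, abs=1e-6)

    def test_trans_planar_backbone_has_psi_180(self):
        coords = build_backbone(range(1, 4), {1: (None, 180.0), 2: (180.0, 180.0)})
        psi = dihedral_angle(coords[1]["N"], coords[1]["CA"], coords[1]["C"], coords[2]["N"])
        assert psi == pytest.approx(180.0, abs=1e-6)

    def test_matches_gemmi_dihedral(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 5
            mine = dihedral_angle(*pts)
            ref = np.degrees(gemmi.calculate_dihedral(*(gemmi.Position(*p) for p in pts)))
            assert mine == pytest.approx(ref, abs=1e-9) or abs(abs(mine) - 180.0) < 1e-9

    def test_sign_flips_under_mirror(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 4
            a = dihedral_angle(*pts)
            mirrored = pts * np.array([-1.0, 1.0, 1.0])
            b = dihedral_angle(*mirrored)
            assert b == pytest.approx(-a, abs=1e-9)

    def test_backbone_dihedrals_on_planted_window(self, dfg_backbone):
        model, torsions = dfg_backbone
        records = backbone_dihedrals(model, "A", range(156, 161))
        for rec in records:
            phi, psi = torsions[rec.residue_number]
            assert rec.phi == pytest.approx(phi, abs=1e-6)
            assert rec.psi == pytest.approx(psi, abs=1e-6)

    def test_termini_yield_missing_markers(self, dfg_backbone):
        model, _ = dfg_backbone
        recs = backbone_dihedrals(model, "A", [154, 162])
        assert recs[0].phi is None and recs[0].psi is not None
        assert recs[1].psi is None and recs[1].phi is not None

    def test_chain_break_marks_dihedral_missing(self, tmp_path):
        model, _ = make_structure(0, first_residue=1, n_residues=4)
        # pull residues 3-4 far away: peptide bond 2-3 becomes > 2.5 A
        shift = np.array([50.0, 0.0, 0.0])
        for res in model.chain("A"):
            if res.seqid.num >= 3:
                for atom in res:
                    p = np.array([atom.pos.x, atom.pos.y, atom.pos.z]) + shift
                    atom.pos = gemmi.Position(*p)
        with pytest.warns(UserWarning, match="chain break"):
            recs = backbone_dihedrals(model, "A", [2, 3])
        assert recs[0].psi is None  # across the break
        assert recs[1].phi is None

    def test_invariant_under_rigid_motion(self, dfg_backbone):
        model, torsions = dfg_backbone
        rot, trans = random_rigid_motion(np.random.default_rng(11))
        transform_model(model, rot, trans)
        for rec in backbone_dihedrals(model, "A", range(156, 161)):
            phi, psi = torsions[rec.residue_number]
            assert rec.phi == pytest.approx(phi, abs=1e-6)
            assert rec.psi == pytest.approx(psi, abs=1e-6)


class TestDisulfides:
    def test_planted_bond_detected(self):
        model, truth = make_structure(0, disulfide=(106, 174, 2.05))
        (bond,) = detect_disulfides(model)
        assert {bond.residue_a, bond.residue_b} == {106, 174}
        assert bond.sg_distance == pytest.approx(2.05, abs=1e-9)

    def test_distant_cysteines_not_reported(self):
        model, _ = make_structure(0, disulfide=(106, 174, 5.0))
        assert detect_disulfides(model) == []

    def test_monotone_in_cutoff_and_each_cys_used_once(self):
        model, _ = make_structure(0, disulfide=(10, 20, 2.0))
        shorter = detect_disulfides(model, max_sg_distance=1.0)
        longer = detect_disulfides(model, max_sg_distance=3.0)
        assert len(shorter) <= len(longer)
        seen = [b.residue_a for b in longer] + [b.residue_b for b in longer]
        assert len(seen) == len(set(seen))

    def test_cysteine_without_sg_skipped_with_warning(self, tmp_path):
        path = tmp_path / "cys.pdb"
        path.write_text(_pdb_atom(1, "CA", "CYS", "A", 1, 0, 0, 0) + "\nEND\n")
        model = read_structure(path)
        with pytest.warns(UserWarning, match="no SG"):
            assert detect_disulfides(model) == []


class TestSpine:
    def test_intact_stack(self):
        model, _ = make_structure(0, spine=((68, 158, 137, 196), (3.8, 3.8, 3.8)))
        report = spine_contacts(model, (68, 158, 137, 196))
        assert report.status == "intact" and report.breaking_pairs == []

    def test_displaced_residue_breaks_named_link(self):
        model, _ = make_structure(0, spine=((68, 158, 137, 196), (3.8, 8.0, 3.8)))
        report = spine_contacts(model, (68, 158, 137, 196))
        assert report.status == "broken"
        assert report.breaking_pairs == [(158, 137)]

    def test_pair_distances_match_bruteforce_all_atom_minimum(self, dfg_backbone):
        model, _ = make_structure(0, spine=((1, 2, 3), (3.0, 4.4)))
        report = spine_contacts(model, (1, 2, 3))
        for a, b, d in report.pair_distances:
            ra = model.residue("A", a)
            rb = model.residue("A", b)
            backbone = {"N", "CA", "C", "O", "OXT"}
            best = min(
                np.linalg.norm(
                    np.array([x.pos.x, x.pos.y, x.pos.z]) - np.array([y.pos.x, y.pos.y, y.pos.z])
                )
                for x in ra if x.name not in backbone
                for y in rb if y.name not in backbone
            )
            assert d == pytest.approx(best, abs=1e-12)

    def test_residue_without_sidechain_breaks_spine(self, tmp_path):
        path = tmp_path / "s.pdb"
        path.write_text(
            "\n".join(
                [
                    _pdb_atom(1, "CB", "ALA", "A", 1, 0, 0, 0, element="C"),
                    _pdb_atom(2, "CA", "GLY", "A", 2, 2, 0, 0),  # backbone only
                    "END",
                ]
            )
            + "\n"
        )
        model = read_structure(path)
        with pytest.warns(UserWarning, match="side-chain"):
            report = spine_contacts(model, (1, 2))
        assert report.status == "broken"


class TestSuperpose:
    def test_structure_onto_itself(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3)) * 8
        transform, rmsd = superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_random_rigid_motion(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(25, 3)) * 10
        rot, trans = random_rigid_motion(rng)
        moved = coords @ rot.T + trans
        transform, rmsd = superpose(coords, moved)
        assert rmsd <= 1e-9
        np.testing.assert_allclose(transform.rotation, rot, atol=1e-9)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            transform.rotation @ transform.rotation.T, np.eye(3), atol=1e-12
        )

    def test_rmsd_invariant_under_common_prerotation(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(12, 3)) * 6
        b = a + rng.normal(scale=0.5, size=a.shape)
        _, rmsd0 = superpose(a, b)
        rot, trans = random_rigid_motion(rng)
        _, rmsd1 = superpose(a @ rot.T + trans, b @ rot.T + trans)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_matches_scipy_rotation_alignment(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(8)
        a = rng.normal(size=(15, 3)) * 5
        b = rng.normal(size=(15, 3)) * 5
        transform, rmsd = superpose(a, b)
        ref, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        np.testing.assert_allclose(transform.rotation, ref.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line + 1.0)
        with pytest.raises(ValueError, match="3 atom pairs"):
            superpose(line[:2], line[:2])
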