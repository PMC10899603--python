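"""Structure screens: PDB I/O, internal-coordinate geometry, disulfide scan,
B-factor segments, Kabsch superposition, and loop grafting."""

import numpy as np
import pytest

from helpers import (
    ca_only_structure,
    oracle_disulfide_accept,
    random_pair_frames,
)
from indikit import structure_screen as ss
from indikit.errors import (
    DegenerateBFactorError,
    DegenerateGeometryError,
    EmptyStructureError,
    StructureParseError,
)
from indikit.synthetic_data import gen_structure, ideal_disulfide_residues

PDB_TWO_RESIDUES = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 21.00           C
ATOM      3  C   ALA A   1      12.321   7.375  -4.742  1.00 22.00           C
ATOM      4  N   GLY A   2      12.120   7.762  -3.484  1.00 23.00           N
ATOM      5  CA  GLY A   2      12.731   8.992  -2.983  1.00 24.00           C
ATOM      6  C   GLY A   2      14.251   8.900  -2.935  1.00 25.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  N   SER A   1      10.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA ASER A   1      11.000   0.000   0.000  0.40 20.00           C
ATOM      3  CA BSER A   1      11.500   0.000   0.000  0.60 20.00           C
ATOM      4  C   SER A   1      12.000   1.000   0.000  1.00 20.00           C
END
"""


class TestReadStructure:
    def test_two_residue_parse(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(PDB_TWO_RESIDUES)
        model = ss.read_structure(p)
        residues = model.residues()
        assert [r.res_name for r in residues] == ["ALA", "GLY"]
        assert list(model.atom_name[:3]) == ["N", "CA", "C"]
        assert model.b_factor[0] == pytest.approx(20.0)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        model = ss.read_structure(p)
        cas = model.coord[model.atom_name == "CA"]
        assert len(cas) == 1
        assert cas[0][0] == pytest.approx(11.5)

    def test_no_atom_records_is_empty_structure(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(EmptyStructureError):
            ss.read_structure(p)

    def test_malformed_coordinates_report_line(self, tmp_path):
        bad = PDB_TWO_RESIDUES.replace("11.639", "xx.639")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(StructureParseError, match="line 2"):
            ss.read_structure(p)

    def test_generator_roundtrip_to_pdb_precision(self, tmp_path,
                                                  synthetic_model):
        model, _ = synthetic_model
        p = tmp_path / "model.pdb"
        ss.write_structure(model, p)
        back = ss.read_structure(p)
        assert len(back) == len(model)
        assert np.allclose(back.coord, model.coord, atol=1.5e-3)


class TestGeometryPrimitives:
    def test_place_atom_reproduces_internal_coordinates(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 3)) * 4
            bond = rng.uniform(1.0, 2.0)
            angle = rng.uniform(60, 170)
            dih = rng.uniform(-180, 180)
            d = ss.place_atom(a, b, c, bond, angle, dih)
            assert np.linalg.norm(d - c) == pytest.approx(bond)
            assert ss.bond_angle(b, c, d) == pytest.approx(angle)
            assert ss.dihedral_angle(a, b, c, d) == pytest.approx(dih)

    def test_reconstructed_cb_geometry(self):
        n = np.array([1.458, 0.0, 0.0])
        ca = np.zeros(3)
        c = ss.place_atom(np.array([0.0, 1.0, 0.0]), n, ca, 1.525, 111.0, -60.0)
        cb = ss.reconstruct_cb(n, ca, c)
        assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=0.02)
        assert ss.bond_angle(n, ca, cb) == pytest.approx(109.5, abs=3.0)
        assert ss.bond_angle(c, ca, cb) == pytest.approx(109.5, abs=3.0)


class TestDisulfideScan:
    def test_strain_zero_at_ideal_and_monotone(self):
        assert ss.disulfide_strain(2.05, 87.0) == 0.0
        assert ss.disulfide_strain(2.05, -87.0) == 0.0
        d_values = [2.05, 2.15, 2.25, 2.35]
        strains = [ss.disulfide_strain(d, 87.0) for d in d_values]
        assert strains == sorted(strains) and len(set(strains)) == 4
        chi_values = [87.0, 95.0, 105.0, 115.0]
        strains = [ss.disulfide_strain(2.05, c) for c in chi_values]
        assert strains == sorted(strains) and len(set(strains)) == 4

    def test_ideal_pair_accepted_with_negligible_strain(self):
        res_a, res_b = ideal_disulfide_residues()
        best = ss.evaluate_pair((res_a["N"], res_a["CA"], res_a["CB"]),
                                (res_b["N"], res_b["CA"], res_b["CB"]))
        assert best is not None
        assert best["strain"] < 1e-6
        assert best["d"] == pytest.approx(2.05, abs=1e-3)

    def test_planted_pair_found_in_generated_model(self, synthetic_model):
        model, truth = synthetic_model
        cands = ss.scan_disulfides(model)
        planted = {tuple(p) for p in truth["planted_ss_pairs"]}
        found = {(c.res_a[1], c.res_b[1]) for c in cands}
        assert planted <= found
        best = min(c.strain_score for c in cands
                   if (c.res_a[1], c.res_b[1]) in planted)
        assert best < 0.05

    def test_distant_cb_pair_prefiltered(self):
        res_a, res_b = ideal_disulfide_residues()
        shift = np.array([8.0, 0.0, 0.0])
        residues = [("A", 1, "CYS", res_a, 20.0),
                    ("A", 10, "CYS", {k: v + shift for k, v in res_b.items()},
                     21.0)]
        from indikit.synthetic_data import _assemble_structure

        model = _assemble_structure(residues)
        assert ss.scan_disulfides(model) == []

    def test_sequence_separation_enforced(self):
        res_a, res_b = ideal_disulfide_residues()
        from indikit.synthetic_data import _assemble_structure

        close = _assemble_structure([("A", 1, "CYS", res_a, 20.0),
                                     ("A", 2, "CYS", res_b, 21.0)])
        assert ss.scan_disulfides(close) == []

    def test_interchain_pair_flagged(self):
        res_a, res_b = ideal_disulfide_residues()
        from indikit.synthetic_data import _assemble_structure

        model = _assemble_structure([("A", 1, "CYS", res_a, 20.0),
                                     ("B", 1, "CYS", res_b, 21.0)])
        cands = ss.scan_disulfides(model)
        assert len(cands) == 1 and cands[0].interchain

    def test_result_independent_of_residue_order(self):
        res_a, res_b = ideal_disulfide_residues()
        from indikit.synthetic_data import _assemble_structure

        fwd = _assemble_structure([("A", 1, "CYS", res_a, 20.0),
                                   ("A", 10, "CYS", res_b, 21.0)])
        rev = _assemble_structure([("A", 10, "CYS", res_b, 21.0),
                                   ("A", 1, "CYS", res_a, 20.0)])
        c1, c2 = ss.scan_disulfides(fwd), ss.scan_disulfides(rev)
        assert [(c.res_a, c.res_b) for c in c1] == [(c.res_a, c.res_b)
                                                    for c in c2]
        assert c1[0].strain_score == pytest.approx(c2[0].strain_score)

    def test_proline_excluded(self):
        res_a, res_b = ideal_disulfide_residues()
        from indikit.synthetic_data import _assemble_structure

        model = _assemble_structure([("A", 1, "PRO", res_a, 20.0),
                                     ("A", 10, "CYS", res_b, 21.0)])
        assert ss.scan_disulfides(model) == []

    def test_decisions_match_fine_grid_oracle(self):
        rng = np.random.default_rng(42)
        geom = ss.DisulfideGeometry()
        for _ in range(20):
            frame_a, frame_b = random_pair_frames(rng)
            mine = ss.evaluate_pair(frame_a, frame_b, geom) is not None
            assert mine == oracle_disulfide_accept(frame_a, frame_b, geom)


class TestFlexibleSegments:
    def test_subthreshold_perturbation_gives_empty(self):
        # short-period ripple plus a bump too small to push any smoothed
        # window past one standard deviation
        n = 50
        k = np.arange(n)
        b = 20.0 + 2.0 * np.sin(2 * np.pi * k / 7.0)
        b[25] += 0.5
        structure = ca_only_structure(np.arange(1, n + 1),
                                      np.c_[k * 3.8, np.zeros(n), np.zeros(n)],
                                      b_factors=b)
        assert ss.flexible_segments(structure) == []

    def test_generator_hotspots_detected(self, synthetic_model):
        model, truth = synthetic_model
        segs = ss.flexible_segments(model, window=5, z_threshold=1.0)
        slack = 5
        for lo, hi in truth["b_hotspots"]:
            assert any(s.start >= lo - slack and s.end <= hi + slack
                       and s.start <= hi and s.end >= lo for s in segs)

    def test_segments_sorted_and_disjoint(self, synthetic_model):
        model, _ = synthetic_model
        segs = ss.flexible_segments(model)
        for earlier, later in zip(segs, segs[1:]):
            assert earlier.end < later.start

    def test_affine_b_rescaling_invariance(self, synthetic_model):
        model, _ = synthetic_model
        segs = ss.flexible_segments(model)
        import copy

        scaled = copy.deepcopy(model)
        scaled.b_factor = scaled.b_factor * 7.3 + 11.0
        segs2 = ss.flexible_segments(scaled)
        assert [(s.start, s.end) for s in segs] == [(s.start, s.end)
                                                    for s in segs2]

    def test_uniform_b_is_degenerate(self):
        structure = ca_only_structure([1, 2, 3, 4, 5],
                                      np.c_[np.arange(5), np.zeros(5),
                                            np.zeros(5)],
                                      b_factors=np.full(5, 20.0))
        with pytest.raises(DegenerateBFactorError):
            ss.flexible_segments(structure)


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(8, 3))
        rot, trans, rmsd = ss.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3))
        assert np.allclose(trans, 0.0)

    def test_recovers_applied_rotation(self, rng):
        pts = rng.normal(size=(10, 3))
        theta = np.radians(90.0)
        applied = np.array([[np.cos(theta), -np.sin(theta), 0],
                            [np.sin(theta), np.cos(theta), 0],
                            [0, 0, 1.0]])
        moved = pts @ applied.T + np.array([1.0, -2.0, 3.0])
        rot, trans, rmsd = ss.kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, applied)

    def test_transform_self_consistency(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        rot, trans, rmsd = ss.kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        direct = np.sqrt(np.mean(np.sum((a @ rot.T + trans - b) ** 2, axis=1)))
        assert rmsd == pytest.approx(direct)

    def test_rmsd_symmetric_and_rigid_invariant(self, rng):
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        r_ab = ss.kabsch_superpose(a, b)[2]
        r_ba = ss.kabsch_superpose(b, a)[2]
        assert r_ab == pytest.approx(r_ba)
        theta = np.radians(37.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        shift = np.array([5.0, -1.0, 2.0])
        r2 = ss.kabsch_superpose(a @ rot.T + shift, b @ rot.T + shift)[2]
        assert r2 == pytest.approx(r_ab)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ss.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]
        with pytest.raises(DegenerateGeometryError):
            ss.kabsch_superpose(line, line)


def _graft_fixture():
    """Target with a 10-residue loop and a donor whose loop is 4 shorter,
    built so the donor anchors coincide exactly with the target's."""
    rng = np.random.default_rng(3)
    t_coords = rng.normal(size=(30, 3)) * 2 + \
        np.c_[np.arange(30) * 3.8, np.zeros(30), np.zeros(30)]
    target = ca_only_structure(np.arange(1, 31), t_coords)
    # donor: residues 1-9 flank, 10-15 loop (6 residues), 16-26 = target 20-30
    d_coords = np.vstack([
        t_coords[:9],
        rng.normal(size=(6, 3)) + np.array([40.0, 0, 0]),
        t_coords[19:],
    ])
    donor = ca_only_structure(np.arange(1, 27), d_coords)
    return target, donor


class TestLoopGraft:
    def test_self_donor_excluded_for_equal_length(self):
        target, _ = _graft_fixture()
        cands = ss.loop_graft_candidates(target, ("A", 10, 19),
                                         [("self", target, ("A", 10, 19))])
        assert cands == []

    def test_shorter_donor_reported(self):
        target, donor = _graft_fixture()
        cands = ss.loop_graft_candidates(target, ("A", 10, 19),
                                         [("donor", donor, ("A", 10, 15))])
        assert len(cands) == 1
        c = cands[0]
        assert c.length_delta == -4
        assert c.anchor_rmsd == pytest.approx(0.0, abs=1e-10)

    def test_displaced_anchor_excluded(self):
        target, donor = _graft_fixture()
        import copy

        bad = copy.deepcopy(donor)
        # shear: move only the C-terminal anchor block, breaking rigidity
        # (a rigid fit absorbs part of the shear, so displace generously)
        mask = bad.res_id >= 16
        bad.coord = bad.coord.copy()
        bad.coord[mask] += np.array([0.0, 15.0, 0.0])
        cands = ss.loop_graft_candidates(target, ("A", 10, 19),
                                         [("bad", bad, ("A", 10, 15))])
        assert cands == []

    def test_missing_flank_skips_donor_with_warning(self):
        target, donor = _graft_fixture()
        with pytest.warns(UserWarning, match="skipped"):
            cands = ss.loop_graft_candidates(
                target, ("A", 10, 19), [("edge", donor, ("A", 2, 15))])
        assert cands == []
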