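"""Kabsch superposition, structure loading, and steric-clash detection."""

import numpy as np
import pytest

from rhinotools.structure import (
    Atom,
    DEFAULT_VDW_RADII,
    apply_transform,
    detect_clashes,
    kabsch,
    load_structure,
    superpose,
)

# frozen output of a 200-restart Nelder-Mead minimization over rigid
# transforms for the perturbed-triangle pairing below
TRIANGLE_ORACLE_RMSD = 0.0887655


def random_rigid(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


class TestKabsch:
    def test_identical_coordinates_give_zero_rmsd_and_identity(self):
        coords = np.random.default_rng(0).normal(size=(10, 3))
        res = kabsch(coords, coords)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.rotation == pytest.approx(np.eye(3), abs=1e-12)

    def test_pure_translation_removed(self):
        coords = np.random.default_rng(1).normal(size=(8, 3))
        res = kabsch(coords + np.array([5.0, 0, 0]), coords)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_triangle_matches_numerical_minimization_oracle(self):
        target = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        mobile = np.array([[0, 0, 0], [1, 0, 0], [0, 1.2, 0]], float)
        res = kabsch(mobile, target)
        assert res.rmsd == pytest.approx(TRIANGLE_ORACLE_RMSD, abs=1e-5)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        # mirror-image pairing must still yield det(R) = +1
        coords = rng.normal(size=(6, 3))
        res = kabsch(coords * np.array([-1.0, 1.0, 1.0]), coords)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_agrees_with_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        target = rng.normal(size=(12, 3))
        R, t = random_rigid(rng)
        mobile = target @ R.T + t + rng.normal(scale=0.3, size=target.shape)
        res = kabsch(mobile, target)
        rot, ssd = Rotation.align_vectors(
            target - target.mean(0), mobile - mobile.mean(0)
        )
        moved = (mobile - mobile.mean(0)) @ rot.as_matrix().T + target.mean(0)
        scipy_rmsd = np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))
        assert res.rmsd == pytest.approx(scipy_rmsd, rel=1e-9)

    def test_rmsd_invariant_under_rigid_pretransform_of_mobile(self):
        rng = np.random.default_rng(4)
        target = rng.normal(size=(15, 3))
        mobile = target + rng.normal(scale=0.5, size=target.shape)
        base = kabsch(mobile, target).rmsd
        for _ in range(5):
            R, t = random_rigid(rng)
            assert kabsch(mobile @ R.T + t, target).rmsd == pytest.approx(base, rel=1e-9)

    def test_optimal_among_random_rigid_transforms(self):
        rng = np.random.default_rng(5)
        target = rng.normal(size=(20, 3))
        mobile = target + rng.normal(scale=0.4, size=target.shape)
        best = kabsch(mobile, target).rmsd
        for _ in range(1000):
            R, t = random_rigid(rng)
            moved = mobile @ R.T + t
            rmsd = np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_selection_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)

    def test_stated_transform_reproduces_stated_rmsd(self):
        rng = np.random.default_rng(6)
        target = rng.normal(size=(9, 3))
        mobile = target + rng.normal(scale=0.2, size=target.shape)
        res = kabsch(mobile, target)
        moved = apply_transform(mobile, res)
        assert np.sqrt(np.mean(np.sum((moved - target) ** 2, 1))) == pytest.approx(res.rmsd)


MINIMAL_PDB = """\
ATOM      1  N   GLY A  26      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A  26      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A  26      12.748   7.092  -4.973  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  CA  ALA A   2      12.800   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""


class TestLoadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = load_structure(p)
        assert list(model.chains) == ["A"]
        (res,) = model.chains["A"]
        assert res.number == 26 and len(res.atoms) == 3

    def test_first_model_only(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_MODEL_PDB)
        model = load_structure(p)
        ca = model.chains["A"][0].atoms["CA"]
        assert ca.pos == (0.0, 0.0, 0.0)

    def test_waters_dropped(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(
            MINIMAL_PDB.replace(
                "END\n",
                "HETATM    4  O   HOH A 100       0.000   0.000   0.000"
                "  1.00  0.00           O\nEND\n",
            )
        )
        model = load_structure(p)
        assert all(r.name != "HOH" for r in model.chains["A"])

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError):
            load_structure(p)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        model = load_structure(p)
        assert model.chains["A"][0].atoms["CA"].pos[0] == pytest.approx(5.0)


class TestSuperpose:
    def helix(self, n=30, seed=0):
        """Synthetic Cα trace (ideal alpha-helix geometry) as a structure model."""
        from rhinotools.structure import Residue, StructureModel

        t = np.arange(n)
        coords = np.stack(
            [2.3 * np.cos(t * 1.745), 2.3 * np.sin(t * 1.745), 1.5 * t], axis=1
        )
        residues = [
            Residue(number=i + 1, name="ALA",
                    atoms={"CA": Atom("CA", "C", tuple(c))})
            for i, c in enumerate(coords)
        ]
        return StructureModel(id="helix", chains={"A": residues})

    def test_rigid_copy_superposes_to_zero(self):
        model = self.helix()
        rng = np.random.default_rng(7)
        R, t = random_rigid(rng)
        moved = self.helix()
        for res in moved.chains["A"]:
            atom = res.atoms["CA"]
            res.atoms["CA"] = Atom("CA", "C", tuple(R @ atom.xyz + t))
        result = superpose(moved, ("A", 5, 25), model, ("A", 5, 25))
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.n_atoms == 21

    def test_selection_size_mismatch_rejected(self):
        model = self.helix()
        with pytest.raises(ValueError, match="mismatch"):
            superpose(model, ("A", 1, 10), model, ("A", 1, 11))


class TestClashes:
    def atoms(self, *positions, element="C"):
        return [
            (f"a{i}", Atom(f"a{i}", element, tuple(p))) for i, p in enumerate(positions)
        ]

    def test_two_carbons_at_2p8_clash_at_default_tolerance(self):
        report = detect_clashes(self.atoms((0, 0, 0)), self.atoms((2.8, 0, 0)))
        (pair,) = report.pairs
        assert pair.cutoff == pytest.approx(3.0)
        assert pair.distance == pytest.approx(2.8)

    def test_two_carbons_at_3p2_do_not_clash(self):
        report = detect_clashes(self.atoms((0, 0, 0)), self.atoms((3.2, 0, 0)))
        assert len(report) == 0

    def test_empty_group_gives_empty_report(self):
        assert len(detect_clashes([], self.atoms((0, 0, 0)))) == 0

    def test_symmetric_in_groups(self):
        a = self.atoms((0, 0, 0), (5, 5, 5))
        b = self.atoms((2.5, 0, 0), (5, 5, 7.9), element="S")
        ra = detect_clashes(a, b)
        rb = detect_clashes(b, a)
        assert {(p.distance, p.cutoff) for p in ra.pairs} == {
            (p.distance, p.cutoff) for p in rb.pairs
        }

    def test_larger_tolerance_reports_subset(self):
        rng = np.random.default_rng(8)
        a = self.atoms(*rng.uniform(0, 6, size=(20, 3)))
        b = self.atoms(*rng.uniform(0, 6, size=(20, 3)))
        loose = {(p.atom_a, p.atom_b) for p in detect_clashes(a, b, tolerance=1.0).pairs}
        strict = {(p.atom_a, p.atom_b) for p in detect_clashes(a, b, tolerance=0.2).pairs}
        assert loose <= strict

    def test_sorted_by_overlap_depth(self):
        a = self.atoms((0, 0, 0))
        b = self.atoms((2.9, 0, 0), (1.5, 0, 0))
        report = detect_clashes(a, b)
        overlaps = [p.overlap for p in report.pairs]
        assert overlaps == sorted(overlaps, reverse=True)

    def test_unknown_element_named_in_error(self):
        a = [("odd", Atom("odd", "XX", (0, 0, 0)))]
        with pytest.raises(ValueError, match="XX"):
            detect_clashes(a, self.atoms((1, 0, 0)))

    def test_hydrogens_excluded_by_default(self):
        a = [("h", Atom("H1", "H", (0, 0, 0)))]
        assert len(detect_clashes(a, self.atoms((0.5, 0, 0)))) == 0
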