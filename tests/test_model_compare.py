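import numpy as np
import pytest

from structloc import simulate_map
from structloc.errors import EmptySelectionError
from structloc.model_compare import (
    interface_report,
    kabsch_superpose,
    per_residue_rmsd,
    per_sse_map_cc,
    sasa,
)
from structloc.structure import Atom, AtomicStructure

from conftest import single_atom


def rigid(coords, axis, angle_deg, t):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K
    return coords @ R.T + np.asarray(t, float)


def horn_quaternion_rmsd(a, b):
    """Independent optimal-superposition RMSD via Horn's quaternion method."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    M = b.T @ a
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(N).max()
    sq = (np.sum(a**2) + np.sum(b**2) - 2 * lam) / len(a)
    return np.sqrt(max(sq, 0.0))


class TestKabsch:
    def test_identical_sets_zero_rmsd(self):
        pts = np.random.default_rng(0).normal(0, 5, (12, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12

    def test_rigid_transform_zero_rmsd_and_proper_rotation(self):
        pts = np.random.default_rng(1).normal(0, 5, (15, 3))
        moved = rigid(pts, [1, 2, 3], 47.0, [4.0, -1.0, 2.0])
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_reflection_never_returned(self):
        pts = np.random.default_rng(2).normal(0, 5, (10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        R, _, rmsd = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd > 0  # a reflection cannot be absorbed by proper rotation

    def test_matches_independent_horn_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 5, (10, 3))
        b = a.copy()
        b[4] += [3.0, -2.0, 1.0]  # one displaced point
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(horn_quaternion_rmsd(a, b), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 5, (8, 3))
        b = a + rng.normal(0, 0.5, (8, 3))
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            kabsch_superpose(b, a)[2], rel=1e-9)

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((5, 3)), np.zeros((4, 3)))


class TestPerResidueRmsd:
    def test_self_comparison_all_zero(self, toy_structure):
        prof = per_residue_rmsd(toy_structure, toy_structure, atoms="all-heavy")
        assert len(prof.residue_numbers) == 60
        assert np.all(prof.rmsd < 1e-12)

    def test_rigid_copy_all_zero(self, toy_structure):
        R_moved = toy_structure.transformed(_rotmat([0, 1, 0], 30.0),
                                            np.array([5.0, 1.0, -2.0]))
        prof = per_residue_rmsd(toy_structure, R_moved, atoms="CA-only")
        assert np.all(prof.rmsd < 1e-9)

    def test_single_displaced_residue_dominates(self, toy_structure):
        from dataclasses import replace
        atoms = [replace(a, coord=a.coord + (np.array([5.0, 0, 0])
                                             if a.residue_number == 30 else 0.0))
                 for a in toy_structure.atoms]
        altered = AtomicStructure(atoms=atoms)
        prof = per_residue_rmsd(toy_structure, altered, atoms="all-heavy")
        i30 = prof.residue_numbers.index(30)
        assert prof.rmsd[i30] == prof.rmsd.max()
        assert prof.rmsd[i30] == pytest.approx(5.0, abs=0.5)

    def test_matches_naive_recomputation(self, toy_structure):
        """Superpose once with the independent Horn rotation, then loop residues."""
        from dataclasses import replace
        rng = np.random.default_rng(5)
        atoms = [replace(a, coord=a.coord + rng.normal(0, 0.3, 3))
                 for a in toy_structure.atoms]
        altered = AtomicStructure(atoms=atoms)
        prof = per_residue_rmsd(toy_structure, altered, atoms="CA-only")

        # naive path: independent superposition + explicit residue loop
        ca_a = {a.residue_number: a.coord for a in toy_structure.atoms
                if a.atom_name == "CA"}
        ca_b = {a.residue_number: a.coord for a in altered.atoms
                if a.atom_name == "CA"}
        keys = sorted(ca_a)
        A = np.array([ca_a[k] for k in keys])
        B = np.array([ca_b[k] for k in keys])
        R, t, _ = kabsch_superpose(A, B)
        Bm = B @ R.T + t
        naive = {k: np.linalg.norm(Bm[i] - A[i]) for i, k in enumerate(keys)}
        for k, r in zip(prof.residue_numbers, prof.rmsd):
            assert r == pytest.approx(naive[k], abs=1e-9)

    def test_missing_atoms_skipped_and_noted(self, toy_structure):
        truncated = AtomicStructure(
            atoms=[a for a in toy_structure.atoms
                   if not (a.residue_number == 5 and a.atom_name == "CA")])
        prof = per_residue_rmsd(toy_structure, truncated, atoms="CA-only")
        assert 5 not in prof.residue_numbers
        assert "A5" in prof.alignment_note

    def test_empty_pairing_raises(self, toy_structure):
        with pytest.raises(EmptySelectionError):
            per_residue_rmsd(toy_structure, toy_structure, pairing={})


def _rotmat(axis, angle_deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


class TestSasa:
    def test_single_atom_matches_analytic_sphere(self):
        st = single_atom(radius=1.7)
        area = sasa(st, probe_radius=1.4, n_sphere_points=960)[0]
        assert area == pytest.approx(4 * np.pi * 3.1**2, rel=0.02)

    def test_two_distant_atoms_each_isolated(self):
        st = AtomicStructure(atoms=[Atom(1, "C", 1.7, np.zeros(3)),
                                    Atom(2, "C", 1.7, np.array([100.0, 0, 0]))])
        areas = sasa(st, 1.4, 960)
        assert areas[0] == pytest.approx(areas[1])
        assert areas[0] == pytest.approx(4 * np.pi * 3.1**2, rel=0.02)

    def test_two_sphere_overlap_matches_spherical_cap_formula(self):
        d = 2.0
        st = AtomicStructure(atoms=[Atom(1, "C", 1.7, np.zeros(3)),
                                    Atom(2, "C", 1.7, np.array([d, 0, 0]))])
        total = sasa(st, 1.4, 960).sum()
        r = 1.7 + 1.4
        cap_h = r - d / 2.0  # equal radii: plane bisects the center line
        analytic = 2 * (4 * np.pi * r**2 - 2 * np.pi * r * cap_h)
        assert total == pytest.approx(analytic, rel=0.02)

    def test_rigid_invariance(self, small_structure):
        a = sasa(small_structure, 1.4, 240)
        moved = small_structure.transformed(_rotmat([1, 1, 1], 60.0),
                                            np.array([3.0, -7.0, 2.0]))
        b = sasa(moved, 1.4, 240)
        # quadrature grid is fixed in space, so allow small per-atom jitter
        assert np.abs(a - b).max() < 3.0
        assert b.sum() == pytest.approx(a.sum(), rel=0.02)

    def test_point_count_validated(self):
        with pytest.raises(ValueError):
            sasa(single_atom(), 1.4, 50)


class TestInterface:
    def test_distant_chains_no_burial_no_contacts(self, small_structure):
        far = small_structure.transformed(np.eye(3), np.array([100.0, 0, 0]))
        rep = interface_report(small_structure, far)
        assert rep.buried_area == pytest.approx(0.0, abs=1.0)
        assert rep.contact_pairs == []

    def test_contact_boundary_inclusive(self):
        a = AtomicStructure(atoms=[Atom(1, "C", 1.7, np.zeros(3))])
        b = AtomicStructure(atoms=[Atom(2, "C", 1.7, np.array([3.4, 0, 0]))])
        rep = interface_report(a, b, contact_cutoff=0.0)
        assert len(rep.contact_pairs) == 1
        assert rep.contact_pairs[0][2] == pytest.approx(3.4)

    def test_two_sphere_burial_matches_cap_oracle(self):
        d = 2.5
        a = AtomicStructure(atoms=[Atom(1, "C", 1.7, np.zeros(3))])
        b = AtomicStructure(atoms=[Atom(2, "C", 1.7, np.array([d, 0, 0]))])
        rep = interface_report(a, b)
        r = 3.1
        cap_h = r - d / 2.0
        analytic_total = 2 * 2 * np.pi * r * cap_h
        assert rep.buried_area_total == pytest.approx(analytic_total, rel=0.03)
        assert rep.buried_area == pytest.approx(analytic_total / 2.0, rel=0.03)

    def test_symmetry_and_nonnegativity(self, small_structure):
        other = small_structure.transformed(np.eye(3), np.array([6.0, 0, 0]))
        r1 = interface_report(small_structure, other)
        r2 = interface_report(other, small_structure)
        assert r1.buried_area == pytest.approx(r2.buried_area, rel=1e-6)
        assert r1.buried_area >= 0


class TestPerSseCc:
    def test_self_simulated_map_all_segments_one(self, toy_structure):
        dmap = simulate_map(toy_structure, 6.0, 1.5, padding=6.0)
        results = per_sse_map_cc(toy_structure, dmap, 6.0, local_radius=3.0)
        assert len(results) == 3
        for seg, cc in results:
            assert cc == pytest.approx(1.0, abs=1e-6)

    def test_zeroed_helix_region_is_minimum(self, toy_structure):
        dmap = simulate_map(toy_structure, 6.0, 1.5, padding=6.0)
        h2 = toy_structure.select_residues("A", 21, 40).heavy_coords()
        ax = [dmap.voxel_centers_axis(d) for d in range(3)]
        gi, gj, gk = np.meshgrid(*ax, indexing="ij")
        vox = np.stack([gi.ravel(), gj.ravel(), gk.ravel()], axis=1)
        from scipy.spatial import cKDTree
        kill = cKDTree(h2).query(vox, k=1)[0] < 4.0
        vals = dmap.values.copy().ravel()
        vals[kill] = 0.0
        damaged = dmap.copy_with(vals.reshape(dmap.values.shape))
        results = per_sse_map_cc(toy_structure, damaged, 6.0, 3.0)
        ccs = {seg.label: cc for seg, cc in results}
        assert ccs["H2"] == min(ccs.values())

    def test_intensity_scale_invariance(self, toy_structure):
        dmap = simulate_map(toy_structure, 6.0, 1.5, padding=6.0)
        r1 = per_sse_map_cc(toy_structure, dmap, 6.0, 3.0)
        r2 = per_sse_map_cc(toy_structure, dmap.copy_with(4.0 * dmap.values),
                            6.0, 3.0)
        for (_, c1), (_, c2) in zip(r1, r2):
            assert c1 == pytest.approx(c2, abs=1e-12)

    def test_missing_annotation_raises(self, toy_structure):
        bare = AtomicStructure(atoms=toy_structure.atoms)
        dmap = simulate_map(toy_structure, 6.0, 1.5, padding=6.0)
        with pytest.raises(EmptySelectionError):
            per_sse_map_cc(bare, dmap, 6.0)
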