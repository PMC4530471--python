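import numpy as np
import pytest

from structloc import exhaustive_search, refine_pose, compare_placements, simulate_map
from structloc.docking import (
    DockResult,
    Pose,
    matrix_to_quat,
    orientation_grid,
    quat_to_matrix,
    rotation_angle_deg,
)
from structloc.errors import DegenerateGeometryError
from structloc.structure import AtomicStructure


def axis_angle_quat(axis, angle_deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    half = np.radians(angle_deg) / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


class TestPose:
    def test_quaternion_normalization_enforced(self):
        with pytest.raises(ValueError):
            Pose(rotation=np.array([1.0, 1.0, 0.0, 0.0]))

    def test_matrix_quaternion_round_trip(self):
        q = axis_angle_quat([1, 2, 3], 73.0)
        q2 = matrix_to_quat(quat_to_matrix(q))
        assert rotation_angle_deg(q, q2) < 1e-9

    def test_pose_inverse_composition_is_identity(self, small_structure):
        pose = Pose(rotation=axis_angle_quat([0, 0, 1], 30.0),
                    translation=np.array([1.0, -2.0, 3.0]))
        coords = small_structure.coords()
        center = small_structure.centroid()
        moved = pose.apply(coords, center)
        # invert about the same center: x = R^T (y - c - t) + c
        back = (moved - center - pose.translation) @ pose.matrix() + center
        np.testing.assert_allclose(back, coords, atol=1e-6)


class TestOrientationGrid:
    def test_deterministic_unit_quaternions(self):
        g1 = orientation_grid(20.0)
        g2 = orientation_grid(20.0)
        np.testing.assert_array_equal(g1, g2)
        np.testing.assert_allclose(np.linalg.norm(g1, axis=1), 1.0, atol=1e-12)

    def test_covering_radius_close_to_step(self):
        grid = orientation_grid(30.0)
        rng = np.random.default_rng(0)
        q = rng.normal(size=(500, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        dots = np.abs(q @ grid.T).max(axis=1)
        worst = np.degrees(2 * np.arccos(np.clip(dots, -1, 1))).max()
        assert worst <= 1.3 * 30.0

    def test_step_bounds_enforced(self):
        for bad in (4.0, 61.0):
            with pytest.raises(ValueError):
                orientation_grid(bad)


@pytest.fixture(scope="module")
def noiseless_setup():
    from structloc.synthetic import make_toy_structure
    # 3 short helices: asymmetric enough that no pseudo-symmetric pose
    # outscores the generative one at a 20 degree grid
    probe = make_toy_structure(n_helices=3, helix_length=12, seed=2)
    dmap = simulate_map(probe, 6.0, 1.5, padding=6.0)
    return dmap, probe


class TestExhaustiveSearch:
    @pytest.fixture(scope="class")
    def result(self, noiseless_setup):
        dmap, probe = noiseless_setup
        return dmap, probe, exhaustive_search(dmap, probe, 6.0, angular_step=20.0)

    def test_recovers_generative_pose_within_one_step(self, result):
        _, _, res = result
        top = res.hits[0]
        assert rotation_angle_deg(top.pose.rotation, IDENTITY_Q) <= 20.0
        assert np.linalg.norm(top.pose.translation) <= 1.5 * 1.5

    def test_top_hit_normalized_cc_is_one(self, result):
        _, _, res = result
        assert res.hits[0].normalized_cc == 1.0
        assert all(h.normalized_cc <= 1.0 + 1e-12 for h in res.hits)
        ccs = [h.cc for h in res.hits]
        assert ccs == sorted(ccs, reverse=True)

    def test_intensity_scale_invariance(self, result):
        dmap, probe, res = result
        res_scaled = exhaustive_search(dmap.copy_with(10.0 * dmap.values),
                                       probe, 6.0, angular_step=20.0)
        assert len(res.hits) == len(res_scaled.hits)
        for h1, h2 in zip(res.hits, res_scaled.hits):
            assert h1.cc == pytest.approx(h2.cc, abs=1e-9)
            np.testing.assert_allclose(h1.pose.translation, h2.pose.translation)

    def test_deterministic_across_runs(self, result):
        dmap, probe, res = result
        res2 = exhaustive_search(dmap, probe, 6.0, angular_step=20.0)
        for h1, h2 in zip(res.hits, res2.hits):
            assert h1.cc == h2.cc
            np.testing.assert_array_equal(h1.pose.rotation, h2.pose.rotation)
            np.testing.assert_array_equal(h1.pose.translation, h2.pose.translation)

    def test_cluster_representatives_separated(self, result):
        _, _, res = result
        for i, hi in enumerate(res.hits):
            for hj in res.hits[i + 1:]:
                rot_d = rotation_angle_deg(hi.pose.rotation, hj.pose.rotation)
                trans_d = np.linalg.norm(hi.pose.translation - hj.pose.translation)
                assert rot_d > 2 * 20.0 or trans_d > 1.5 * 1.5

    def test_degenerate_inputs_raise(self, noiseless_setup):
        dmap, probe = noiseless_setup
        with pytest.raises(DegenerateGeometryError):
            exhaustive_search(dmap.copy_with(np.zeros_like(dmap.values)),
                              probe, 6.0)


class TestRefinePose:
    def test_perturbed_start_refined_to_truth(self, noiseless_setup):
        dmap, probe = noiseless_setup
        start = Pose(rotation=axis_angle_quat([0, 1, 0], 5.0),
                     translation=np.array([2.0, 0.0, 0.0]))
        pose, cc = refine_pose(dmap, probe, start, 6.0)
        assert rotation_angle_deg(pose.rotation, IDENTITY_Q) <= 1.0
        assert np.linalg.norm(pose.translation) <= 0.5

    def test_start_at_optimum_stays(self, noiseless_setup):
        dmap, probe = noiseless_setup
        pose, cc = refine_pose(dmap, probe, Pose(), 6.0)
        assert rotation_angle_deg(pose.rotation, IDENTITY_Q) <= 0.5
        assert np.linalg.norm(pose.translation) <= 0.25
        assert cc > 0.99

    def test_cc_never_below_start(self, noiseless_setup):
        dmap, probe = noiseless_setup
        from structloc.docking import _pose_cc, _probe_arrays
        from structloc.density import _FWHM_TO_SIGMA
        start = Pose(rotation=axis_angle_quat([1, 1, 0], 8.0),
                     translation=np.array([-2.0, 1.0, 0.0]))
        coords, weights = _probe_arrays(probe)
        cc_start = _pose_cc(dmap, coords, weights, coords.mean(axis=0), start,
                            6.0 * _FWHM_TO_SIGMA)
        _, cc = refine_pose(dmap, probe, start, 6.0)
        assert cc >= cc_start


class TestComparePlacements:
    def test_complete_model_beats_truncated(self, noiseless_setup):
        dmap, probe = noiseless_setup
        truncated = AtomicStructure(
            atoms=probe.atoms[:120], sse_annotation=probe.sse_annotation[:2])
        ranked = compare_placements(dmap, [(truncated, Pose()), (probe, Pose())],
                                    6.0)
        assert ranked[0][0] == 1  # the full generative structure wins
        assert ranked[0][1] > ranked[1][1]

    def test_duplicate_candidates_tie(self, noiseless_setup):
        dmap, probe = noiseless_setup
        ranked = compare_placements(dmap, [(probe, Pose()), (probe, Pose())], 6.0)
        assert ranked[0][1] == pytest.approx(ranked[1][1], abs=1e-6)

    def test_single_candidate_scored(self, noiseless_setup):
        dmap, probe = noiseless_setup
        ranked = compare_placements(dmap, [(probe, Pose())], 6.0)
        assert len(ranked) == 1
        assert ranked[0][1] > 0.99


def test_rotation_of_map_and_probe_preserves_score(toy_structure):
    """Rotating both map and probe by the same rotation leaves cc unchanged."""
    from structloc.density import cross_correlation, simulate_on_grid

    dmap = simulate_map(toy_structure, 6.0, 1.5, padding=8.0)
    sim = simulate_on_grid(toy_structure, 6.0, dmap)
    cc0 = cross_correlation(dmap, sim, "full")

    q = axis_angle_quat([0, 0, 1], 90.0)
    R = quat_to_matrix(q)
    center = toy_structure.centroid()
    rotated = toy_structure.transformed(R, np.zeros(3), center=center)
    dmap_r = simulate_map(rotated, 6.0, 1.5, padding=8.0)
    sim_r = simulate_on_grid(rotated, 6.0, dmap_r)
    cc1 = cross_correlation(dmap_r, sim_r, "full")
    assert abs(cc1 - cc0) <= 0.02
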