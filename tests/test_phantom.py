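import numpy as np
import pytest

from mirrorsym import (
    MeshError,
    PatchDefect,
    PhantomSpec,
    RegionOfInterest,
    deform_patch,
    deform_radial,
    make_cohort,
    make_cup_pair,
    mirror_mesh,
    run_symmetry_case,
    save_pair,
    read_stl,
)


class TestGeneration:
    def test_deterministic_bit_identical(self):
        spec = dict(seed=5, mesh_resolution=2.0, noise_sd=0.2, landmark_jitter_sd=0.3)
        a = make_cup_pair(PhantomSpec(**spec))
        b = make_cup_pair(PhantomSpec(**spec))
        assert np.array_equal(a.left.vertices, b.left.vertices)
        assert np.array_equal(a.right.vertices, b.right.vertices)
        assert np.array_equal(a.landmarks_left.points, b.landmarks_left.points)

    def test_right_is_exact_mirror_before_deformation(self, coarse_pair):
        mirrored = mirror_mesh(coarse_pair.left, "x=0")
        assert np.array_equal(mirrored.vertices, coarse_pair.right.vertices)

    def test_roi_covers_cup_not_flange(self, coarse_pair):
        pair = coarse_pair
        roi_pts = pair.right.vertices[pair.roi_right.vertex_indices]
        out_pts = np.delete(pair.right.vertices, pair.roi_right.vertex_indices, axis=0)
        # flange is flat at the truncation plane; the cup dips below it
        assert roi_pts[:, 2].min() < out_pts[:, 2].min() - 1.0
        assert np.allclose(out_pts[:, 2], out_pts[0, 2])

    def test_landmarks_non_coplanar(self, coarse_pair):
        p = coarse_pair.landmarks_right.points
        vol = np.abs(np.linalg.det(p[1:] - p[0]))
        assert vol > 100.0

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(MeshError, match="coarse"):
            make_cup_pair(PhantomSpec(seed=0, mesh_resolution=40.0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(seed=0, cup_depth_fraction=1.5)

    def test_mesh_valid_and_connected(self, coarse_pair):
        from mirrorsym import clean_mesh

        coarse_pair.left.validate()
        cleaned = clean_mesh(coarse_pair.left, 0.5)
        assert cleaned.n_faces == coarse_pair.left.n_faces  # single component


class TestDeformations:
    def test_radial_zero_delta_identity(self, coarse_pair):
        out = deform_radial(coarse_pair.right, coarse_pair.roi_right, 0.0)
        np.testing.assert_array_equal(out.vertices, coarse_pair.right.vertices)

    def test_radial_moves_roi_by_delta(self, coarse_pair):
        pair = coarse_pair
        out = deform_radial(pair.right, pair.roi_right, 1.0)
        idx = pair.roi_right.vertex_indices
        r0 = np.linalg.norm(pair.right.vertices[idx], axis=1)
        r1 = np.linalg.norm(out.vertices[idx], axis=1)
        np.testing.assert_allclose(r1 - r0, 1.0, atol=1e-12)

    def test_radial_blends_into_flange(self, coarse_pair):
        pair = coarse_pair
        out = deform_radial(pair.right, pair.roi_right, 1.0, falloff_band=3.0)
        moved = np.linalg.norm(out.vertices - pair.right.vertices, axis=1)
        outside = np.delete(np.arange(pair.right.n_vertices), pair.roi_right.vertex_indices)
        # some flange vertices move partially, none by the full delta
        assert moved[outside].max() < 1.0
        assert moved[outside].max() > 0.0

    def test_radial_erosion_matches_construction(self, coarse_pair):
        """Erosion by 0.73 mm shows up as ~0.73 mm mean distance against the
        undeformed copy (no registration involved)."""
        from mirrorsym import surface_distance_map

        pair = coarse_pair
        eroded = deform_radial(pair.right, pair.roi_right, -0.73)
        inner = RegionOfInterest(pair.roi_right.vertex_indices[: len(pair.roi_right) // 2])
        dmap = surface_distance_map(eroded, inner, pair.right)
        assert np.mean(dmap.distances) == pytest.approx(0.73, rel=0.1)

    def test_center_coincident_vertex_rejected(self, coarse_pair):
        with pytest.raises(MeshError, match="center"):
            deform_radial(
                coarse_pair.right,
                coarse_pair.roi_right,
                1.0,
                center=coarse_pair.right.vertices[0],
            )

    def test_patch_zero_depth_identity(self, coarse_pair):
        out = deform_patch(coarse_pair.right, (0, 0, -1), 15.0, 0.0)
        np.testing.assert_array_equal(out.vertices, coarse_pair.right.vertices)

    def test_patch_center_displaced_exactly_depth(self, coarse_pair):
        """The pole vertex lies exactly on the cap axis: taper = 1 there."""
        pair = coarse_pair
        out = deform_patch(pair.right, (0, 0, -1), 15.0, 2.0)
        pole = np.argmin(pair.right.vertices[:, 2])
        shift = np.linalg.norm(out.vertices[pole] - pair.right.vertices[pole])
        assert shift == pytest.approx(2.0, abs=1e-9)

    def test_patch_untouched_outside_cap(self, coarse_pair):
        pair = coarse_pair
        out = deform_patch(pair.right, (0, 0, -1), 15.0, 2.0)
        rel = pair.right.vertices
        gamma = np.degrees(
            np.arccos(np.clip(-rel[:, 2] / np.linalg.norm(rel, axis=1), -1, 1))
        )
        outside = gamma >= 15.0
        np.testing.assert_array_equal(out.vertices[outside], rel[outside])

    def test_patch_invalid_params(self, coarse_pair):
        with pytest.raises(ValueError):
            deform_patch(coarse_pair.right, (0, 0, -1), 120.0, 1.0)
        with pytest.raises(ValueError):
            deform_patch(coarse_pair.right, (0, 0, 0), 15.0, 1.0)


class TestEndToEnd:
    def test_perfect_pair_pipeline_mean_below_1e6(self, coarse_pair):
        pair = coarse_pair
        res = run_symmetry_case(
            pair.left, pair.right, pair.landmarks_left, pair.landmarks_right,
            pair.roi_left, "LM2RO",
        )
        assert res.summary.mean_error < 1e-6
        assert res.profile.surface_percent == (100.0, 100.0, 100.0, 100.0)

    def test_measured_mean_monotone_in_dilation(self):
        """Coarse-resolution version of the dilation monotonicity property."""
        means = []
        for delta in (0.0, 0.25, 0.5):
            pair = make_cup_pair(
                PhantomSpec(seed=31, mesh_resolution=2.0, dilation_delta=delta)
            )
            res = run_symmetry_case(
                pair.left, pair.right, pair.landmarks_left, pair.landmarks_right,
                pair.roi_left, "LM2RO",
            )
            means.append(res.summary.mean_error)
        assert means[0] < means[1] < means[2]

    def test_misalignment_recovered_when_noiseless(self):
        from mirrorsym import IcpParams, random_misalignment

        rng = np.random.default_rng(8)
        mis = random_misalignment(rng, 6.0, 3.0)
        pair = make_cup_pair(
            PhantomSpec(seed=77, mesh_resolution=1.5, misalignment=mis,
                        landmark_jitter_sd=0.4)
        )
        res = run_symmetry_case(
            pair.left, pair.right, pair.landmarks_left, pair.landmarks_right,
            pair.roi_left, "LM2RO",
            icp=IcpParams(max_iterations=400, rms_change_tolerance=1e-7),
        )
        gt = pair.ground_truth.transform_lm2ro
        err = res.transform.compose(gt.inverse())
        assert err.rotation_angle_deg() < 0.5
        assert np.linalg.norm(err.apply(np.zeros(3))) < 0.05


def test_save_pair_writes_complete_bundle(tmp_path, coarse_pair):
    manifest = save_pair(coarse_pair, tmp_path)
    for f in manifest["files"].values():
        assert (tmp_path / f).exists()
    back = read_stl(tmp_path / "left.stl")
    assert back.n_faces == coarse_pair.left.n_faces
    assert (tmp_path / "manifest.json").exists()
    assert manifest["dilation_delta_mm"] == 0.0


def test_make_cohort_structure():
    cases, repeat = make_cohort(n_cases=3, seed=2, mesh_resolution=2.5)
    assert len(cases) == 3
    assert set(repeat) == {c.case_id for c in cases}
    # second assessor shares anatomy but differs in landmark jitter
    a = cases[0].landmarks_left.points
    b = repeat[cases[0].case_id][0].points
    assert not np.array_equal(a, b)
    assert np.abs(a - b).max() < 3.0
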