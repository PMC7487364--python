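"""Stereo triangulation, track filtering, robust LOWESS and mesh building."""

import numpy as np
import pytest

from duramech.stereo import (CameraModel, DegenerateGeometryError,
                             FeatureTrack, MeshSpec, build_frames,
                             filter_tracks, lowess_surface,
                             tracks_from_dataframe, triangulate_points)
from duramech.synthetic import (NoiseSpec, default_rig,
                                render_feature_tracks)


class TestTriangulation:
    def test_principal_point_correspondence_hits_vergence_point(self, rig):
        # the optical axes of the symmetric verging rig cross at the origin
        ppL = rig.left.K[:2, 2]
        ppR = rig.right.K[:2, 2]
        X = triangulate_points(ppL[None], ppR[None], rig.left, rig.right)
        np.testing.assert_allclose(X[0], [0.0, 0.0, 0.0], atol=1e-12)

    def test_projective_round_trip_is_exact(self, rig):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-0.01, 0.01, (100, 3))
        uvL = rig.left.project(pts)
        uvR = rig.right.project(pts)
        rec = triangulate_points(uvL, uvR, rig.left, rig.right)
        assert np.abs(rec - pts).max() < 1e-8 * 0.02

    def test_rectified_zero_disparity_is_degenerate(self):
        K = np.array([[1000.0, 0, 500], [0, 1000.0, 500], [0, 0, 1.0]])
        camL = CameraModel(K, np.eye(3), np.zeros(3))
        camR = CameraModel(K, np.eye(3), np.array([-0.1, 0.0, 0.0]))
        uv = np.array([[500.0, 500.0]])
        with pytest.raises(DegenerateGeometryError):
            triangulate_points(uv, uv, camL, camR)


def _toy_track(tid, n, speed, offset_frame=None, offset=0.0, hole=None):
    u = np.arange(n, dtype=float) * speed
    pix = np.column_stack([u, np.zeros(n)])
    if offset_frame is not None:
        pix[offset_frame:] += offset
    valid = np.ones(n, bool)
    if hole is not None:
        valid[hole] = False
    return FeatureTrack(tid, pix.copy(), pix.copy(), valid)


class TestFilterTracks:
    def test_homogeneous_population_fully_retained(self):
        tracks = [_toy_track(i, 10, 1.0) for i in range(8)]
        assert len(filter_tracks(tracks, 10)) == 8

    def test_track_missing_one_frame_removed(self):
        tracks = [_toy_track(i, 10, 1.0) for i in range(5)]
        tracks.append(_toy_track(5, 10, 1.0, hole=4))
        kept = filter_tracks(tracks, 10)
        assert {t.track_id for t in kept} == {0, 1, 2, 3, 4}

    def test_mean_velocity_outlier_removed_by_mad_rule(self):
        # five coherent tracks at slightly different speeds plus one at 10x
        # the median speed: hand computation puts it far beyond 5 MADs
        speeds = [0.9, 0.95, 1.0, 1.05, 1.1]
        tracks = [_toy_track(i, 10, s) for i, s in enumerate(speeds)]
        tracks.append(_toy_track(9, 10, 10.0))
        kept = filter_tracks(tracks, 10, k_mad=5.0)
        assert {t.track_id for t in kept} == {0, 1, 2, 3, 4}

    def test_empty_survivor_set_raises(self):
        tracks = [_toy_track(0, 5, 1.0, hole=2)]
        with pytest.raises(ValueError, match="no track spans"):
            filter_tracks(tracks, 5)


class TestLowess:
    def test_reproduces_quadratic_exactly(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(-1, 1, (400, 2))
        z = 3 * xy[:, 0] ** 2 + 2 * xy[:, 0] * xy[:, 1] - xy[:, 1] + 1
        q = rng.uniform(-0.5, 0.5, (50, 2))
        zq = lowess_surface(xy, z, q, span=0.2)
        truth = 3 * q[:, 0] ** 2 + 2 * q[:, 0] * q[:, 1] - q[:, 1] + 1
        assert np.abs(zq - truth).max() < 1e-8

    def test_single_gross_outlier_suppressed(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-1, 1, (300, 2))
        z = np.full(300, 2.5)
        z[137] = 1e3
        q = rng.uniform(-0.5, 0.5, (40, 2))
        zq = lowess_surface(xy, z, q, span=0.2)
        assert np.abs(zq - 2.5).max() < 1e-6

    def test_interpolates_smooth_field_at_sample_location(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(-1, 1, (200, 2))
        z = np.sin(xy[:, 0]) + np.cos(xy[:, 1])
        zq = lowess_surface(xy, z, xy[17][None], span=0.15)
        assert zq[0] == pytest.approx(z[17], abs=1e-4)

    def test_idempotent_on_reproduced_fields(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(-1, 1, (300, 2))
        z = 0.5 * xy[:, 0] ** 2 - xy[:, 1] + 2
        once = lowess_surface(xy, z, xy, span=0.2)
        twice = lowess_surface(xy, once, xy, span=0.2)
        assert np.abs(twice - once).max() < 1e-8

    def test_vector_fields_componentwise(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(-1, 1, (200, 2))
        v = np.column_stack([xy[:, 0] ** 2, xy[:, 1] ** 2, xy[:, 0] * xy[:, 1]])
        q = rng.uniform(-0.4, 0.4, (10, 2))
        vq = lowess_surface(xy, v, q, span=0.25)
        truth = np.column_stack([q[:, 0] ** 2, q[:, 1] ** 2, q[:, 0] * q[:, 1]])
        np.testing.assert_allclose(vq, truth, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            lowess_surface(np.zeros((4, 2)), np.zeros(4), np.zeros((1, 2)))


class TestBuildFrames:
    def test_zero_displacement_tracks_reproduce_reference(self, sphere_dataset,
                                                          rig):
        static = np.repeat(sphere_dataset.frames[:1], 3, axis=0)
        tracks, _ = render_feature_tracks(sphere_dataset.mesh, static, rig,
                                          NoiseSpec(seed=9), 400)
        from duramech.stereo import triangulate_points as tp

        cloud = tp(np.stack([t.left[0] for t in tracks]),
                   np.stack([t.right[0] for t in tracks]),
                   rig.left, rig.right)
        mesh, frames = build_frames(cloud, tracks, rig.left, rig.right,
                                    MeshSpec(radius=8e-3, spacing=1.2e-3),
                                    span=0.1)
        np.testing.assert_allclose(frames[1], frames[0], atol=1e-9)
        np.testing.assert_allclose(frames[2], frames[0], atol=1e-9)

    def test_sphere_frames_recovered_noise_free(self, sphere_dataset,
                                                sphere_spec, rig):
        tracks, _ = render_feature_tracks(sphere_dataset.mesh,
                                          sphere_dataset.frames, rig,
                                          NoiseSpec(seed=1), 1000)
        kept = filter_tracks(tracks, sphere_dataset.n_frames)
        cloud = triangulate_points(np.stack([t.left[0] for t in kept]),
                                   np.stack([t.right[0] for t in kept]),
                                   rig.left, rig.right)
        r0 = sphere_spec.clamp_radius
        mesh, frames = build_frames(cloud, kept, rig.left, rig.right,
                                    MeshSpec(radius=0.6 * r0,
                                             spacing=0.9e-3), span=0.08)
        for k in (0, sphere_dataset.n_frames - 1):
            radius_err = np.abs(
                np.linalg.norm(frames[k], axis=1)
                - sphere_spec.stretch_schedule[k] * r0)
            assert radius_err.max() < 0.005 * r0

    def test_noisy_dropout_run_recovers_apex_displacement(self, sphere_dataset,
                                                          sphere_spec, rig):
        tracks, _ = render_feature_tracks(
            sphere_dataset.mesh, sphere_dataset.frames, rig,
            NoiseSpec(pixel_sigma=0.2, dropout_rate=0.3, seed=21), 1500)
        kept = filter_tracks(tracks, sphere_dataset.n_frames)
        cloud = triangulate_points(np.stack([t.left[0] for t in kept]),
                                   np.stack([t.right[0] for t in kept]),
                                   rig.left, rig.right)
        r0 = sphere_spec.clamp_radius
        mesh, frames = build_frames(cloud, kept, rig.left, rig.right,
                                    MeshSpec(radius=0.6 * r0,
                                             spacing=0.9e-3), span=0.08)
        # apex node displacement vs the analytic radial motion
        apex = np.argmax(mesh.nodes[:, 2])
        lam_end = sphere_spec.stretch_schedule[-1]
        true_disp = (lam_end - 1.0) * np.linalg.norm(mesh.nodes[apex])
        meas_disp = np.linalg.norm(frames[-1][apex] - frames[0][apex])
        assert abs(meas_disp - true_disp) < 0.02 * true_disp

    def test_too_few_tracks_rejected(self, rig):
        cloud = np.random.default_rng(0).uniform(-1, 1, (50, 3))
        with pytest.raises(ValueError, match="surviving tracks"):
            build_frames(cloud, [], rig.left, rig.right, MeshSpec(radius=1.0))


def test_tracks_dataframe_round_trip():
    import pandas as pd

    rows = []
    for tid in range(3):
        for f in range(4):
            rows.append((tid, f, "L", 10.0 * tid + f, 1.0))
            rows.append((tid, f, "R", 10.0 * tid + f + 0.5, 1.0))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "cam", "u_px",
                                     "v_px"])
    tracks = tracks_from_dataframe(df)
    assert len(tracks) == 3
    assert tracks[1].left[2, 0] == 12.0
    assert tracks[1].right[2, 0] == 12.5
    assert tracks[0].full_length
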