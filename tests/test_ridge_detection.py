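"""Crest detection and ellipse fitting: recovery, equivariance, oracles."""

import dataclasses

import numpy as np
import pytest
import trimesh
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from nammold._geometry import ellipse_distances, ellipse_point, rotation_about
from nammold.exceptions import DetectionError, FitError
from nammold.ridge_detection import (
    CrestCurve,
    DetectionResult,
    EllipseParams,
    OcclusalFrame,
    bin_max_candidates,
    compute_occlusal_frame,
    detect_ridge,
    extract_crest,
    fit_ellipse,
    measure_gap_width,
)
from nammold.synthetic_anatomy import AnatomyParams, generate_cleft_maxilla


def _angle_deg(u, v):
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return np.degrees(np.arccos(min(1.0, c)))


class TestOcclusalFrame:
    def test_canonical_pose_recovers_occlusal_normal(self, maxilla):
        mesh, truth = maxilla
        frame = compute_occlusal_frame(mesh)
        assert _angle_deg(frame.w, truth.occlusal_normal) < 2.0

    def test_rigid_motion_equivariance(self, maxilla):
        mesh, _ = maxilla
        frame = compute_occlusal_frame(mesh)
        rng = np.random.default_rng(17)
        rot = rotation_about(rng.normal(size=3), rng.uniform(0.5, 2.5))
        shift = rng.uniform(-30, 30, 3)
        moved = trimesh.Trimesh(mesh.vertices @ rot.T + shift, mesh.faces, process=False)
        frame2 = compute_occlusal_frame(moved)
        assert _angle_deg(frame2.w, rot @ frame.w) < 2.0
        assert _angle_deg(frame2.u, rot @ frame.u) < 2.0

    def test_flat_plate_normal(self):
        plate = trimesh.creation.box(extents=[20.0, 15.0, 0.5])
        frame = compute_occlusal_frame(plate)
        assert _angle_deg(frame.w, [0.0, 0.0, 1.0]) < 1e-6


class TestExtractCrest:
    def test_noise_free_crest_close_to_ground_truth(self, maxilla, detection):
        _, truth = maxilla
        gt = np.vstack(list(truth.crest.values()))
        det_pts = np.vstack([c.points for c in detection.crests])
        d, _ = cKDTree(gt).query(det_pts)
        assert d.mean() < 1.0

    def test_single_curve_without_cleft(self, clean_params):
        mesh, _ = generate_cleft_maxilla(dataclasses.replace(clean_params, cleft_width=0.0))
        frame = compute_occlusal_frame(mesh)
        curves = extract_crest(mesh, frame)
        assert len(curves) == 1
        assert curves[0].segment_label == "greater"

    def test_bin_candidates_match_exhaustive_scan(self, clean_params):
        """Vectorized per-bin selection vs a literal python loop over all
        vertices applying the same stated rule."""
        coarse = dataclasses.replace(clean_params, resolution=1.2)
        mesh, _ = generate_cleft_maxilla(coarse)
        assert len(mesh.vertices) < 8000
        frame = compute_occlusal_frame(mesh)
        local = frame.to_local(mesh.vertices)
        n_bins = 72
        got = bin_max_candidates(local, n_bins)

        wc = local[:, 2]
        up = np.flatnonzero(wc >= np.median(wc))
        cxy = local[up, :2].mean(axis=0)
        rel = local[up, :2] - cxy
        radius = np.linalg.norm(rel, axis=1)
        r_med = np.median(radius)
        expected = np.full(n_bins, -1, dtype=int)
        best = {}
        for j, vi in enumerate(up):
            if not (0.25 * r_med <= radius[j] <= 2.5 * r_med):
                continue
            ang = np.arctan2(rel[j, 1], rel[j, 0])
            b = int(np.floor((ang + np.pi) / (2 * np.pi) * n_bins)) % n_bins
            key = (-wc[vi], radius[j], vi)
            if b not in best or key < best[b][0]:
                best[b] = (key, vi)
        for b, (_, vi) in best.items():
            expected[b] = vi
        assert np.array_equal(got, expected)

    def test_minimum_bins_enforced(self, maxilla):
        mesh, _ = maxilla
        frame = compute_occlusal_frame(mesh)
        with pytest.raises(DetectionError):
            extract_crest(mesh, frame, n_bins=12)

    def test_crest_points_lie_on_surface(self, noisy_maxilla):
        from nammold._geometry import SurfaceQuery

        mesh, _ = noisy_maxilla
        frame = compute_occlusal_frame(mesh)
        curves = extract_crest(mesh, frame)
        query = SurfaceQuery.from_mesh(mesh)
        for c in curves:
            assert query.distance(c.points).max() < 0.1


class TestFitEllipse:
    def test_exact_recovery_from_eight_points(self):
        t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = ellipse_point((0.0, 0.0), 15.0, 10.0, 0.0, t)
        params, rms = fit_ellipse(pts)
        assert params.a == pytest.approx(15.0, abs=1e-6)
        assert params.b == pytest.approx(10.0, abs=1e-6)
        assert np.allclose(params.center, 0.0, atol=1e-6)
        assert rms < 1e-6

    def test_circle_degeneracy(self):
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = 12.0 * np.stack([np.cos(t), np.sin(t)], axis=1)
        params, rms = fit_ellipse(pts)
        assert params.a == pytest.approx(12.0, abs=1e-9)
        assert params.b == pytest.approx(12.0, abs=1e-9)
        assert rms < 1e-9

    def test_noisy_fit_close_to_geometric_refit_oracle(self):
        rng = np.random.default_rng(23)
        t = rng.uniform(0, 2 * np.pi, 100)
        pts = ellipse_point((2.0, -1.0), 15.0, 10.0, 0.4, t)
        pts = pts + rng.normal(0, 0.2, pts.shape)
        params, rms = fit_ellipse(pts)
        assert abs(params.a - 15.0) < 0.3
        assert abs(params.b - 10.0) < 0.3

        # oracle: iterative geometric least squares started from the truth
        def resid(x):
            cx, cy, a, b, th = x
            return ellipse_distances(pts, (cx, cy), a, b, th)

        sol = least_squares(resid, x0=[2.0, -1.0, 15.0, 10.0, 0.4])
        oracle_rms = np.sqrt(np.mean(sol.fun**2))
        assert rms <= 1.1 * oracle_rms

    def test_scale_equivariance(self):
        rng = np.random.default_rng(31)
        t = rng.uniform(0, 2 * np.pi, 40)
        pts = ellipse_point((3.0, 1.0), 14.0, 9.0, 1.1, t) + rng.normal(0, 0.1, (40, 2))
        p1, _ = fit_ellipse(pts)
        s = 2.5
        p2, _ = fit_ellipse(pts * s)
        assert p2.a == pytest.approx(s * p1.a, rel=1e-9)
        assert p2.b == pytest.approx(s * p1.b, rel=1e-9)
        assert np.allclose(p2.center, s * p1.center, atol=1e-9)
        assert p2.theta == pytest.approx(p1.theta, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_ellipse(np.zeros((4, 2)))

    def test_collinear_points(self):
        pts = np.stack([np.linspace(0, 10, 20), np.linspace(0, 5, 20)], axis=1)
        with pytest.raises(FitError):
            fit_ellipse(pts)

    def test_theta_canonical_range(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 2 * np.pi, 30)
        for theta in (0.2, 1.5, 2.9):
            pts = ellipse_point((0, 0), 15.0, 9.0, theta, t)
            params, _ = fit_ellipse(pts)
            assert 0.0 <= params.theta < np.pi
            assert params.theta == pytest.approx(theta % np.pi, abs=1e-6)


class TestDetectRidge:
    def test_gap_span_consistent_with_cleft_width(self, detection, clean_params):
        lo, hi = detection.gap_span
        mid = 0.5 * (lo + hi)
        ell = detection.ellipse
        p = ellipse_point(ell.center, ell.a, ell.b, ell.theta, 0.0)  # radius scale only
        r_loc = np.linalg.norm(
            ell.center
            + np.array([np.cos(mid), np.sin(mid)]) * 0.0  # gap angles are polar about center
            - ell.center
        )
        # local radius at the gap: mean distance of crest points near the gap
        near = []
        for c in detection.crests:
            xy = detection.frame.to_local(c.points)[:, :2] - ell.center
            ang = np.arctan2(xy[:, 1], xy[:, 0])
            sel = np.minimum(np.abs(ang - lo), np.abs(ang - hi)) < 0.3
            near.append(np.linalg.norm(xy[sel], axis=1))
        r_loc = np.concatenate(near).mean()
        assert (hi - lo) * r_loc == pytest.approx(clean_params.cleft_width, abs=2.0)

    def test_no_gap_without_cleft(self, clean_params):
        mesh, _ = generate_cleft_maxilla(dataclasses.replace(clean_params, cleft_width=0.0))
        assert detect_ridge(mesh).gap_span is None

    @pytest.mark.parametrize("width", [3.0, 6.0])
    def test_gap_reported_for_clefts(self, clean_params, width):
        mesh, _ = generate_cleft_maxilla(dataclasses.replace(clean_params, cleft_width=width))
        det = detect_ridge(mesh)
        assert det.gap_span is not None
        assert measure_gap_width(mesh, det) == pytest.approx(width, abs=0.5)

    def test_rigid_motion_equivariance(self, maxilla, detection):
        mesh, _ = maxilla
        rng = np.random.default_rng(41)
        rot = rotation_about(rng.normal(size=3), rng.uniform(0.3, 2.0))
        shift = rng.uniform(-20, 20, 3)
        moved = trimesh.Trimesh(mesh.vertices @ rot.T + shift, mesh.faces, process=False)
        det2 = detect_ridge(moved)
        assert _angle_deg(det2.frame.w, rot @ detection.frame.w) < 2.0
        pts1 = np.vstack([c.points for c in detection.crests]) @ rot.T + shift
        pts2 = np.vstack([c.points for c in det2.crests])
        d, _ = cKDTree(pts1).query(pts2)
        assert np.median(d) < 0.5

    def test_arc_param_strictly_monotone(self, detection):
        for c in detection.crests:
            assert np.all(np.diff(c.arc_param) > 0)

    def test_json_round_trip(self, tmp_path, detection):
        path = tmp_path / "det.json"
        detection.to_json(path)
        back = DetectionResult.from_json(path)
        assert np.allclose(back.frame.w, detection.frame.w)
        assert back.ellipse.a == pytest.approx(detection.ellipse.a)
        assert back.gap_span == pytest.approx(detection.gap_span)
        assert len(back.crests) == len(detection.crests)
        assert np.allclose(back.crests[0].points, detection.crests[0].points)

    def test_user_correction_contract(self, tmp_path, detection):
        """A hand-edited detection file feeds back into the pipeline."""
        import json

        path = tmp_path / "det.json"
        detection.to_json(path)
        payload = json.loads(path.read_text())
        payload["ellipse"]["a"] *= 1.05  # clinician widens the arch
        path.write_text(json.dumps(payload))
        edited = DetectionResult.from_json(path)
        assert edited.ellipse.a == pytest.approx(detection.ellipse.a * 1.05)
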