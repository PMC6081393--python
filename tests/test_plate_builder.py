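"""Plate construction: bridging, shelling, pin/hole booleans, smoothing.

The expensive full pipeline runs once per session (conftest.plate_chain);
voxel-oracle checks for the pin/hole use small analytic solids at the
0.2 mm oracle pitch.
"""

import dataclasses

import numpy as np
import pytest
import trimesh

from nammold import plate_builder as pb
from nammold._geometry import SurfaceQuery, ellipse_distances
from nammold.exceptions import BuildError, DetectionError, PlacementError
from nammold.mesh_io import validate_mesh
from nammold.ridge_detection import detect_ridge
from nammold.synthetic_anatomy import AnatomyParams, generate_cleft_maxilla, grow_anatomy


class TestSelectBridgeRegions:
    def test_automatic_regions_flank_the_gap(self, maxilla, detection):
        mesh, truth = maxilla
        regions = pb.select_bridge_regions(mesh, detection)
        assert len(regions.greater_faces) > 0 and len(regions.smaller_faces) > 0
        cg = mesh.triangles_center[regions.greater_faces].mean(axis=0)
        cs = mesh.triangles_center[regions.smaller_faces].mean(axis=0)
        separation = np.linalg.norm(cg - cs)
        lm = truth.landmarks
        assert separation == pytest.approx(np.linalg.norm(lm.SA - lm.SAp), abs=3.0)

    def test_deterministic_across_runs(self, maxilla, detection):
        mesh, _ = maxilla
        r1 = pb.select_bridge_regions(mesh, detection)
        r2 = pb.select_bridge_regions(mesh, detection)
        assert np.array_equal(r1.greater_faces, r2.greater_faces)
        assert np.array_equal(r1.smaller_faces, r2.smaller_faces)

    def test_user_seeds_are_contained(self, maxilla, detection):
        mesh, truth = maxilla
        lm = truth.landmarks
        q = SurfaceQuery.from_mesh(mesh)
        seed_g = int(q.query(lm.SA[None])[2][0])
        seed_s = int(q.query(lm.SAp[None])[2][0])
        regions = pb.select_bridge_regions(mesh, detection, seeds=[seed_g, seed_s])
        assert seed_g in np.concatenate([regions.greater_faces, regions.smaller_faces])
        assert seed_s in np.concatenate([regions.greater_faces, regions.smaller_faces])

    def test_seeds_far_from_gap_rejected(self, maxilla, detection):
        mesh, _ = maxilla
        far = int(np.argmin(mesh.triangles_center[:, 2]))  # base bottom
        with pytest.raises(BuildError):
            pb.select_bridge_regions(mesh, detection, seeds=[far])

    def test_no_cleft_raises(self, clean_params):
        mesh, _ = generate_cleft_maxilla(dataclasses.replace(clean_params, cleft_width=0.0))
        det = detect_ridge(mesh)
        with pytest.raises(DetectionError):
            pb.select_bridge_regions(mesh, det)


class TestBridgeGap:
    def test_no_cleft_returns_mesh_unchanged(self, clean_params):
        mesh, _ = generate_cleft_maxilla(dataclasses.replace(clean_params, cleft_width=0.0))
        det = detect_ridge(mesh)
        out = pb.bridge_gap(mesh, None, det.ellipse, detection=det)
        assert out is mesh

    def test_watertight_and_volume_increases(self, maxilla, plate_chain):
        mesh, _ = maxilla
        bridged = plate_chain["bridged"]
        rep = validate_mesh(bridged)
        assert rep.is_watertight
        assert rep.volume > mesh.volume

    def test_original_vertices_bit_identical(self, maxilla, plate_chain):
        mesh, _ = maxilla
        bridged = plate_chain["bridged"]
        assert np.array_equal(bridged.vertices[: len(mesh.vertices)], mesh.vertices)
        assert np.array_equal(bridged.faces[: len(mesh.faces)], mesh.faces)

    def test_strip_follows_the_ellipse_arc(self, maxilla, plate_chain, detection):
        """Every vertex of the guiding strip stays within tube-radius + 0.5 mm
        of the fitted ellipse outline (the strip spine is the arc)."""
        mesh, _ = maxilla
        bridged = plate_chain["bridged"]
        strip = bridged.vertices[len(mesh.vertices):]
        local = detection.frame.to_local(strip)
        ell = detection.ellipse
        d = ellipse_distances(local[:, :2], ell.center, ell.a, ell.b, ell.theta)
        assert d.max() < 2.5 + 0.5  # tube radius + spine tolerance


class TestOffsetShell:
    @staticmethod
    def _latlong_cap(radius: float, theta_max: float, n_theta=40, n_phi=160) -> trimesh.Trimesh:
        """Spherical cap with an exactly circular rim at theta_max."""
        verts = [np.array([0.0, 0.0, radius])]
        rows = [[0]]
        for i in range(1, n_theta + 1):
            th = theta_max * i / n_theta
            row = []
            for j in range(n_phi):
                ph = 2 * np.pi * j / n_phi
                row.append(len(verts))
                verts.append(
                    radius
                    * np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
                )
            rows.append(row)
        faces = []
        for j in range(n_phi):
            faces.append([0, rows[1][j], rows[1][(j + 1) % n_phi]])
        for i in range(1, n_theta):
            a, b = rows[i], rows[i + 1]
            for j in range(n_phi):
                jn = (j + 1) % n_phi
                faces.append([a[j], b[j], b[jn]])
                faces.append([a[j], b[jn], a[jn]])
        return trimesh.Trimesh(np.array(verts), np.array(faces), process=False)

    def test_spherical_cap_matches_closed_form(self):
        """Shell of a spherical cap: volume vs the analytic concentric-cap
        shell with radial side walls."""
        radius, thickness = 20.0, 2.0
        cos_cut = 0.5  # 60-degree cap
        patch = self._latlong_cap(radius, np.arccos(cos_cut))
        shell = pb.offset_shell(patch, thickness)
        assert shell.is_watertight
        analytic = (2 * np.pi / 3) * ((radius + thickness) ** 3 - radius**3) * (1 - cos_cut)
        assert shell.volume == pytest.approx(analytic, rel=0.02)

    def test_intaglio_vertices_bit_identical(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
        keep = sphere.vertices[sphere.faces].mean(axis=1)[:, 2] >= 10.0
        patch = trimesh.Trimesh(sphere.vertices.copy(), sphere.faces[keep], process=False)
        patch.remove_unreferenced_vertices()
        shell = pb.offset_shell(patch, 2.0)
        assert np.array_equal(shell.vertices[: len(patch.vertices)], patch.vertices)

    def test_downward_patch_is_a_collapse_error(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        keep = sphere.vertices[sphere.faces].mean(axis=1)[:, 2] <= -7.0
        patch = trimesh.Trimesh(sphere.vertices.copy(), sphere.faces[keep], process=False)
        patch.remove_unreferenced_vertices()
        with pytest.raises(BuildError, match="collapse"):
            pb.offset_shell(patch, 2.0)


class TestBuildPlate:
    def test_plate_is_watertight_manifold(self, plate_chain):
        rep = validate_mesh(plate_chain["plate"])
        assert rep.is_watertight and rep.is_manifold
        assert rep.n_components == 1
        assert rep.volume > 0

    def test_intaglio_fidelity(self, maxilla, plate_chain, detection):
        mesh, _ = maxilla
        fid = pb.intaglio_fidelity(mesh, plate_chain["plate"], detection, plate_chain["spec"])
        assert fid < 0.05

    def test_plate_fits_next_month_anatomy(self, clean_params):
        """A plate built against the one-month-grown target must not push
        into that grown anatomy: intaglio points inside the anatomy solid
        must still lie on its surface."""
        from nammold._voxel import contains

        grown_params = grow_anatomy(clean_params, months=1, g=0.02)
        grown, _ = generate_cleft_maxilla(grown_params)
        det = detect_ridge(grown)
        spec = pb.PlateSpec(voxel_pitch=0.25)
        regions = pb.select_bridge_regions(grown, det)
        bridged = pb.bridge_gap(grown, regions, det.ellipse, detection=det, pitch=spec.voxel_pitch)
        plate = pb.build_plate(bridged, det, spec)
        verts = plate.metadata["intaglio"].vertices.view(np.ndarray)
        inside = contains(grown, verts, pitch=0.2)
        if inside.any():
            depth = SurfaceQuery.from_mesh(grown).distance(verts[inside])
            # surface contact within the boolean-engine pitch, no push-in
            assert depth.max() < 1.2 * spec.voxel_pitch


class TestPinAndHole:
    def test_pin_union_contract(self, plate_chain):
        plate, pin = plate_chain["plate"], plate_chain["pin"]
        spec = plate_chain["spec"]
        rep = validate_mesh(pin)
        assert rep.is_watertight and rep.is_manifold
        dv = pin.volume - plate.volume
        cylinder_volume = np.pi * spec.pin_radius**2 * spec.pin_length
        assert 0 < dv <= cylinder_volume

    def test_fully_embedded_pin_changes_nothing(self, plate_chain):
        # a short thin stub pointing down into the wall stays inside the shell
        spec = dataclasses.replace(
            plate_chain["spec"], pin_radius=0.2, pin_length=0.4, pin_elevation_deg=-90.0
        )
        out = pb.add_retention_pin(plate_chain["plate"], spec)
        assert out.volume == pytest.approx(plate_chain["plate"].volume, rel=1e-6)

    def test_pin_off_plate_is_placement_error(self, plate_chain, detection):
        t_ant = pb._anterior_arc_param(detection)
        spec = dataclasses.replace(plate_chain["spec"], pin_arc_param=t_ant + np.pi)
        with pytest.raises(PlacementError):
            pb.add_retention_pin(plate_chain["plate"], spec)

    def test_hole_increases_genus_by_one(self, plate_chain):
        assert plate_chain["hole"].euler_number == plate_chain["pin"].euler_number - 2
        assert validate_mesh(plate_chain["hole"]).is_watertight

    def test_hole_volume_matches_voxel_column_oracle(self, plate_chain, detection):
        """Removed volume ~= pi r^2 x material length along the hole axis."""
        from nammold._geometry import ellipse_point
        from nammold._voxel import Grid

        pin, hole = plate_chain["pin"], plate_chain["hole"]
        spec = plate_chain["spec"]
        ell = detection.ellipse
        t = pb._anterior_arc_param(detection)
        xy = ellipse_point(ell.center, ell.a, ell.b, ell.theta, t)
        inward = np.asarray(ell.center) - xy
        inward /= np.linalg.norm(inward)
        cxy = xy + spec.hole_offset * inward
        local = detection.frame.to_local(pin.vertices)
        zs = np.linspace(local[:, 2].min(), local[:, 2].max(), 400)
        grid = Grid.from_bounds(pin.bounds, 0.2, pad=3)
        phi = grid.signed_field(grid.voxelize(pin)) * 0.2
        # average the material length over the hole footprint (the plate is
        # sloped there, so the axis alone under-measures)
        lengths = []
        angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        offsets = [np.zeros(2)] + [
            0.7 * spec.hole_radius * np.array([np.cos(a), np.sin(a)]) for a in angles
        ]
        for off in offsets:
            probes = detection.frame.to_world(
                np.column_stack(
                    [np.full_like(zs, cxy[0] + off[0]), np.full_like(zs, cxy[1] + off[1]), zs]
                )
            )
            inside = grid.sample_field(phi, probes) < 0
            lengths.append(inside.sum() * (zs[1] - zs[0]))
        expected = np.pi * spec.hole_radius**2 * np.mean(lengths)
        assert pin.volume - hole.volume == pytest.approx(expected, rel=0.10)

    def test_hole_axis_is_clear(self, plate_chain, detection, hole_center_world):
        """A probe segment along the hole axis passes without intersection."""
        from nammold._voxel import Grid

        hole = plate_chain["hole"]
        local_c = detection.frame.to_local(hole_center_world[None]).ravel()
        local = detection.frame.to_local(hole.vertices)
        zs = np.linspace(local[:, 2].min() + 0.3, local[:, 2].max() - 0.3, 200)
        probes = detection.frame.to_world(
            np.column_stack([np.full_like(zs, local_c[0]), np.full_like(zs, local_c[1]), zs])
        )
        grid = Grid.from_bounds(hole.bounds, 0.2, pad=3)
        phi = grid.signed_field(grid.voxelize(hole)) * 0.2
        assert (grid.sample_field(phi, probes) > 0).all()

    def test_hole_off_plate_is_placement_error(self, plate_chain, detection):
        t_ant = pb._anterior_arc_param(detection)
        spec = dataclasses.replace(plate_chain["spec"], hole_arc_param=t_ant + np.pi)
        with pytest.raises(PlacementError):
            pb.add_ventilation_hole(plate_chain["plate"], spec)

    def test_carve_removes_material(self, plate_chain):
        tool = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
        tool.apply_translation(plate_chain["plate"].vertices[0])
        out = pb.carve(plate_chain["plate"], tool, plate_chain["spec"])
        assert out.is_watertight
        assert out.volume < plate_chain["plate"].volume


class TestSmoothing:
    def test_zero_iterations_is_identity(self, plate_chain):
        spec = dataclasses.replace(plate_chain["spec"], smoothing_iterations=0)
        out = pb.smooth_plate(plate_chain["hole"], spec)
        assert np.array_equal(out.vertices, plate_chain["hole"].vertices)

    def test_roughness_strictly_decreases(self, plate_chain):
        spec = dataclasses.replace(plate_chain["spec"], smoothing_iterations=20)
        out = pb.smooth_plate(plate_chain["hole"], spec)
        assert pb.surface_roughness(out) < pb.surface_roughness(plate_chain["hole"])

    def test_volume_change_below_one_percent(self, plate_chain):
        before, after = plate_chain["hole"], plate_chain["smooth"]
        assert abs(after.volume - before.volume) / before.volume < 0.01

    def test_intaglio_displacement_clamped(self, plate_chain):
        before, after = plate_chain["hole"], plate_chain["smooth"]
        intaglio = before.metadata["intaglio"]
        was = SurfaceQuery.from_mesh(intaglio).distance(before.vertices) < 0.02
        moved = np.linalg.norm(after.vertices[was] - before.vertices[was], axis=1)
        assert moved.max() <= 0.05 + 1e-9

    def test_watertight_preserved(self, plate_chain):
        assert validate_mesh(plate_chain["smooth"]).is_watertight


class TestPipelineMonotonicity:
    def test_stage_volumes(self, maxilla, plate_chain):
        mesh, _ = maxilla
        assert plate_chain["bridged"].volume > mesh.volume
        assert plate_chain["pin"].volume > plate_chain["plate"].volume
        assert plate_chain["hole"].volume < plate_chain["pin"].volume
        rel = abs(plate_chain["smooth"].volume - plate_chain["hole"].volume)
        assert rel / plate_chain["hole"].volume < 0.01

    def test_final_fidelity(self, maxilla, plate_chain, detection, hole_center_world):
        mesh, _ = maxilla
        fid = pb.intaglio_fidelity(
            mesh,
            plate_chain["smooth"],
            detection,
            plate_chain["spec"],
            exclude_radius=3.0,
            exclude_point=hole_center_world,
        )
        assert fid < 0.05

    def test_outward_orientation(self, plate_chain):
        for stage in ("plate", "pin", "hole", "smooth"):
            assert plate_chain[stage].volume > 0
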