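"""Construction of one intraoral molding plate from a cast and a detection.

Pipeline: bridge the cleft with a guiding strip along the fitted arch
ellipse, shell the covered anatomy into a plate (intaglio = anatomy surface,
outer = normal offset), attach the retention pin (Boolean union with a capped
cylinder), cut the ventilation hole (Boolean difference with a through
cylinder) and optionally Taubin-smooth the surface with the intaglio held in
place.

Booleans are voxel-backed (column-parity solid voxelization, marching cubes,
then projection of new vertices back onto the exact source surfaces), which
keeps results watertight and preserves the intaglio fit to well below the
voxel pitch. The plate carries its detection context and intaglio patch in
``mesh.metadata`` so the pin/hole/smoothing operations compose on the plate
alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from ._geometry import SurfaceQuery, ellipse_point
from ._voxel import Grid, snap_to_sources
from .exceptions import BuildError, DetectionError, PlacementError
from .ridge_detection import DetectionResult

_FOOTPRINT_MARGIN = 2.0  # mm the plate may overhang the arch ellipse
_POSTERIOR_MARGIN = 0.0  # the patch ends at the tuberal trim line
_TOP_TOL_FACTOR = 0.8  # x pitch: how far below the column top a face may sit


@dataclass
class PlateSpec:
    """Geometric parameters of one molding plate (mm).

    Pin/hole dimensions are clinical placeholders (not standardized);
    ``voxel_pitch`` is the Boolean-engine resolution.
    """

    thickness: float = 2.0
    trim_height: float = 3.0  # vestibular trim above the crest line
    pin_radius: float = 1.5
    pin_length: float = 10.0
    pin_arc_param: float | None = None  # None = anterior midline
    pin_elevation_deg: float = 45.0  # tilt above the occlusal plane
    hole_radius: float = 1.0
    hole_arc_param: float | None = None  # None = anterior midline
    hole_offset: float = 6.0  # palatal offset towards the arch center
    smoothing_iterations: int = 10
    smoothing_method: str = "taubin"
    voxel_pitch: float = 0.15

    def validate(self) -> None:
        if self.thickness <= 0:
            raise BuildError("thickness must be > 0")
        if self.smoothing_method != "taubin":
            raise BuildError(f"unknown smoothing method {self.smoothing_method!r}")
        if self.pin_radius <= 0 or self.hole_radius <= 0 or self.pin_length <= 0:
            raise BuildError("pin/hole dimensions must be > 0")


@dataclass
class BridgeRegions:
    """Face-index sets flanking the cleft on the greater and smaller segment."""

    greater_faces: np.ndarray
    smaller_faces: np.ndarray

    def __post_init__(self):
        self.greater_faces = np.asarray(self.greater_faces, dtype=np.int64)
        self.smaller_faces = np.asarray(self.smaller_faces, dtype=np.int64)
        if len(self.greater_faces) == 0 or len(self.smaller_faces) == 0:
            raise BuildError("bridge regions must be non-empty")
        if np.intersect1d(self.greater_faces, self.smaller_faces).size:
            raise BuildError("bridge regions must be disjoint")


# ---------------------------------------------------------------------------
# helpers on detections
# ---------------------------------------------------------------------------


def _gap_endpoints(detection: DetectionResult) -> tuple[np.ndarray, np.ndarray]:
    """(greater, smaller) crest endpoints facing the cleft gap."""
    if detection.gap_span is None:
        raise DetectionError("detection has no cleft gap")
    lo, hi = detection.gap_span
    by_label = {c.segment_label: c for c in detection.crests}
    out = {}
    for label, c in by_label.items():
        ends = np.array([c.points[0], c.points[-1]])
        angs = np.array([c.arc_param[0], c.arc_param[-1]])
        two_pi = 2 * np.pi
        d = np.minimum(
            np.minimum(np.abs(angs - lo) % two_pi, two_pi - np.abs(angs - lo) % two_pi),
            np.minimum(np.abs(angs - hi) % two_pi, two_pi - np.abs(angs - hi) % two_pi),
        )
        out[label] = ends[int(np.argmin(d))]
    return out["greater"], out["smaller"]


def _crest_height(detection: DetectionResult) -> float:
    """Median crest height in the occlusal frame (w coordinate)."""
    pts = np.vstack([c.points for c in detection.crests])
    return float(np.median(detection.frame.to_local(pts)[:, 2]))


def _posterior_line(detection: DetectionResult) -> tuple[np.ndarray, np.ndarray]:
    """(point, anterior unit direction) of the tuberal trim line in occlusal
    in-plane coordinates: through the midpoint of the two posterior crest
    endpoints, facing the ellipse center."""
    frame = detection.frame
    ends = []
    for c in detection.crests:
        ends.append((c.arc_param[0], c.points[0]))
        ends.append((c.arc_param[-1], c.points[-1]))
    if detection.gap_span is not None:
        ga, gb = _gap_endpoints(detection)
        keep = [e for _, e in ends if not (np.allclose(e, ga) or np.allclose(e, gb))]
    else:
        keep = [e for _, e in ends]
    pts = frame.to_local(np.asarray(keep))[:, :2]
    mt = pts.mean(axis=0)
    anterior = detection.ellipse.center - mt
    n = np.linalg.norm(anterior)
    if n < 1e-9:
        raise BuildError("cannot orient the posterior trim line")
    return mt, anterior / n


# ---------------------------------------------------------------------------
# bridge
# ---------------------------------------------------------------------------


def select_bridge_regions(
    mesh: trimesh.Trimesh,
    detection: DetectionResult,
    seeds: list[int] | None = None,
    radius: float = 3.0,
) -> BridgeRegions:
    """Select the bridging areas flanking the cleft.

    Automatic mode: faces whose centroid lies within ``radius`` of each
    gap-facing crest endpoint. With ``seeds`` (user face picks), disks of the
    same radius grow around each seed, assigned to the nearer side of the
    gap; seeds farther than 10 mm from both margins are rejected. Output
    order is (greater, smaller) by crest arc length. Deterministic.
    """
    e_great, e_small = _gap_endpoints(detection)
    centroids = mesh.triangles_center
    if seeds is None:
        d_g = np.linalg.norm(centroids - e_great, axis=1)
        d_s = np.linalg.norm(centroids - e_small, axis=1)
        greater = np.flatnonzero((d_g <= radius) & (d_g < d_s))
        smaller = np.flatnonzero((d_s <= radius) & (d_s <= d_g))
    else:
        seeds = np.asarray(seeds, dtype=np.int64)
        greater_list, smaller_list = [], []
        for s in seeds:
            c = centroids[s]
            dg = np.linalg.norm(c - e_great)
            ds = np.linalg.norm(c - e_small)
            if min(dg, ds) > 10.0:
                raise BuildError(f"seed face {s} is {min(dg, ds):.1f} mm from the cleft margins")
            target = greater_list if dg < ds else smaller_list
            target.append(np.flatnonzero(np.linalg.norm(centroids - c, axis=1) <= radius))
        if not greater_list or not smaller_list:
            raise BuildError("seeds must cover both sides of the gap")
        greater = np.unique(np.concatenate(greater_list))
        smaller = np.unique(np.concatenate(smaller_list))
        both = np.intersect1d(greater, smaller)
        greater = np.setdiff1d(greater, both)
        smaller = np.setdiff1d(smaller, both) if len(both) else smaller
    return BridgeRegions(greater_faces=greater, smaller_faces=smaller)


def _capsule_arc_mesh(
    spine_xy: np.ndarray,
    z_lo: float,
    z_hi: float,
    radius: float,
    pitch: float,
) -> trimesh.Trimesh:
    """Closed swept-capsule solid around a vertical wall whose (x, y) spine
    is the given polyline and whose axis spans [z_lo, z_hi]; marching cubes
    on the exact capsule distance field."""
    lo = np.array([spine_xy[:, 0].min() - radius, spine_xy[:, 1].min() - radius, z_lo - radius])
    hi = np.array([spine_xy[:, 0].max() + radius, spine_xy[:, 1].max() + radius, z_hi + radius])
    grid = Grid.from_bounds(np.array([lo, hi]), pitch, pad=2)
    nx, ny, nz = grid.shape
    xs = grid.origin[0] + np.arange(nx) * grid.pitch
    ys = grid.origin[1] + np.arange(ny) * grid.pitch
    zs = grid.origin[2] + np.arange(nz) * grid.pitch
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    tree = cKDTree(spine_xy)
    dxy = tree.query(np.stack([X.ravel(), Y.ravel()], axis=1))[0].reshape(nx, ny)
    dz = np.maximum.reduce([z_lo - zs, zs - z_hi, np.zeros_like(zs)])
    phi = np.sqrt(dxy[:, :, None] ** 2 + dz[None, None, :] ** 2) - radius
    return grid.mesh_from_field(phi.astype(np.float32))


def bridge_gap(
    mesh: trimesh.Trimesh,
    regions: BridgeRegions | None,
    ellipse,
    detection: DetectionResult | None = None,
    residual_gap: float = 0.0,
    radius: float = 2.5,
    wall_height: float = 4.0,
    pitch: float = 0.25,
) -> trimesh.Trimesh:
    """Bridge the cleft with a closed guiding strip along the ellipse arc.

    The strip is a swept capsule whose spine follows the fitted-ellipse arc
    between the two margin regions — the "guiding track" the growing arch
    expands into. ``residual_gap`` (mm) leaves a centered channel open (used
    by the plate-series closure schedule). The cast itself is untouched
    (vertex positions bit-identical); the result is the watertight compound
    of cast and strip. With no cleft (``regions`` None) the mesh is returned
    unchanged.
    """
    if regions is None:
        return mesh
    if detection is None:
        raise BuildError("bridge_gap needs the DetectionResult for frame/gap context")
    frame = detection.frame
    e_g, e_s = _gap_endpoints(detection)
    m_g = frame.to_local(e_g).ravel()
    m_s = frame.to_local(e_s).ravel()

    # parametric angles of the margins on the ellipse
    def param_of(xy):
        d = xy[:2] - ellipse.center
        ct, st = np.cos(ellipse.theta), np.sin(ellipse.theta)
        local = np.array([ct * d[0] + st * d[1], -st * d[0] + ct * d[1]])
        return float(np.arctan2(local[1] / ellipse.b, local[0] / ellipse.a))

    t_g, t_s = param_of(m_g), param_of(m_s)
    # short way around, extended one tube radius into each segment so the
    # strip anchors inside the margins
    dt = (t_s - t_g + np.pi) % (2 * np.pi) - np.pi
    r_loc = 0.5 * (np.linalg.norm(m_g[:2] - ellipse.center) + np.linalg.norm(m_s[:2] - ellipse.center))
    t_ext = 0.5 * radius / max(r_loc, 1e-6)
    lo = t_g - np.sign(dt) * t_ext
    hi = t_g + dt + np.sign(dt) * t_ext
    n_pts = max(8, int(abs(hi - lo) * max(ellipse.a, ellipse.b) / (0.5 * pitch)))
    ts = np.linspace(lo, hi, n_pts)
    spine = ellipse_point(ellipse.center, ellipse.a, ellipse.b, ellipse.theta, ts)

    if residual_gap > 0:
        # drop the central part of the spine so an open channel of chordal
        # width residual_gap remains between the two strip end caps
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(spine, axis=0), axis=1))])
        half = 0.5 * (residual_gap + 2 * radius)
        mid = 0.5 * arc[-1]
        keep = np.abs(arc - mid) >= half
        if not np.any(keep[: len(keep) // 2]) or not np.any(keep[len(keep) // 2 :]):
            return mesh  # nothing left to bridge at this schedule step
        pieces = [spine[keep & (arc <= mid)], spine[keep & (arc > mid)]]
    else:
        pieces = [spine]

    z_hi = _crest_height(detection) - radius
    z_lo = z_hi - wall_height
    parts = [mesh]
    for piece in pieces:
        if len(piece) < 2:
            continue
        tube_local = _capsule_arc_mesh(piece, z_lo, z_hi, radius, pitch)
        tube = trimesh.Trimesh(
            frame.to_world(tube_local.vertices), tube_local.faces, process=False
        )
        parts.append(tube)
    if len(parts) == 1:
        return mesh
    out = trimesh.util.concatenate(parts)
    out.metadata["name"] = f"{mesh.metadata.get('name', 'cast')}_bridged"
    return out


# ---------------------------------------------------------------------------
# shelling
# ---------------------------------------------------------------------------


def _smooth_vertex_normals(mesh: trimesh.Trimesh, iterations: int = 3) -> np.ndarray:
    normals = mesh.vertex_normals.view(np.ndarray).copy()
    adj = mesh.edges_unique
    for _ in range(iterations):
        acc = normals.copy()
        np.add.at(acc, adj[:, 0], normals[adj[:, 1]])
        np.add.at(acc, adj[:, 1], normals[adj[:, 0]])
        norms = np.linalg.norm(acc, axis=1, keepdims=True)
        normals = acc / np.maximum(norms, 1e-12)
    return normals


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary of a face patch."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    keys = np.sort(edges, axis=1)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]  # directed, winding order preserved
    nxt = {int(a): int(b) for a, b in boundary}
    loops = []
    visited: set[int] = set()
    for start in sorted(nxt):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = nxt.get(start)
        while cur is not None and cur != start and cur not in visited:
            loop.append(cur)
            visited.add(cur)
            cur = nxt.get(cur)
        if cur == start and len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def _make_boundary_manifold(faces: np.ndarray) -> np.ndarray:
    """Drop faces incident to bowtie vertices (boundary vertices with more
    than two boundary edges) until every boundary vertex has exactly one
    incoming and one outgoing boundary edge, so loops close."""
    faces = np.asarray(faces)
    for _ in range(20):
        edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        keys = np.sort(edges, axis=1)
        _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
        boundary = edges[counts[inv] == 1]
        if len(boundary) == 0:
            return faces
        deg = np.bincount(boundary.ravel(), minlength=faces.max() + 1)
        bad = np.flatnonzero(deg > 2)
        if len(bad) == 0:
            return faces
        incident = np.isin(faces, bad).any(axis=1)
        faces = faces[~incident]
        if len(faces) == 0:
            raise BuildError("patch vanished while repairing its boundary")
    raise BuildError("could not repair the patch boundary")


def _ball_envelope(base: np.ndarray, thickness: float, query_xy: np.ndarray) -> np.ndarray:
    """Upper envelope of radius-``thickness`` spheres centered on the patch
    vertices (morphological dilation of the surface by a ball), evaluated at
    the query (x, y) positions via a max-dilated heightfield.

    On smooth convex regions this reproduces the plain normal offset; at
    concave creases it rounds the offset like a rolling ball, so the outer
    surface never folds over and the clearance to the patch is >= thickness
    (up to the heightfield cell size)."""
    cell = max(thickness / 10.0, 0.12)
    mins = base[:, :2].min(axis=0) - thickness - 2 * cell
    gi = np.floor((base[:, 0] - mins[0]) / cell).astype(int)
    gj = np.floor((base[:, 1] - mins[1]) / cell).astype(int)
    ni, nj = gi.max() + 1, gj.max() + 1
    H = np.full((ni, nj), -np.inf)
    np.maximum.at(H, (gi, gj), base[:, 2])
    r_cells = int(np.ceil(thickness / cell))
    pad = r_cells + 1
    Hp = np.full((ni + 2 * pad, nj + 2 * pad), -np.inf)
    Hp[pad:-pad, pad:-pad] = H
    out = np.full_like(Hp, -np.inf)
    with np.errstate(invalid="ignore"):  # empty cells carry -inf
        for di in range(-r_cells, r_cells + 1):
            for dj in range(-r_cells, r_cells + 1):
                d2 = (di * cell) ** 2 + (dj * cell) ** 2
                if d2 > thickness**2:
                    continue
                dz = np.sqrt(thickness**2 - d2)
                shifted = np.roll(np.roll(Hp, di, axis=0), dj, axis=1)
                np.maximum(out, shifted + dz, out=out)
    qi = np.clip((query_xy[:, 0] - mins[0]) / cell + pad, 0, out.shape[0] - 1.001)
    qj = np.clip((query_xy[:, 1] - mins[1]) / cell + pad, 0, out.shape[1] - 1.001)
    i0 = qi.astype(int)
    j0 = qj.astype(int)
    fi = qi - i0
    fj = qj - j0
    c00 = out[i0, j0]
    c10 = out[i0 + 1, j0]
    c01 = out[i0, j0 + 1]
    c11 = out[i0 + 1, j0 + 1]
    vals = (
        c00 * (1 - fi) * (1 - fj)
        + c10 * fi * (1 - fj)
        + c01 * (1 - fi) * fj
        + c11 * fi * fj
    )
    return vals


def _fill_small_holes(patch: trimesh.Trimesh, max_perimeter: float = 20.0) -> trimesh.Trimesh:
    """Close interior holes of the patch (perimeter below ``max_perimeter``)
    with centroid fans; the outer boundary (longest loop) is kept open."""
    loops = _boundary_loops(patch.faces)
    if len(loops) <= 1:
        return patch
    verts = patch.vertices.view(np.ndarray)

    def perimeter(loop):
        p = verts[loop]
        return float(np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1).sum())

    perims = [perimeter(lp) for lp in loops]
    keep_open = int(np.argmax(perims))
    new_verts = [verts]
    new_faces = [patch.faces]
    next_idx = len(verts)
    for i, loop in enumerate(loops):
        if i == keep_open or perims[i] >= max_perimeter:
            continue
        center = verts[loop].mean(axis=0)
        new_verts.append(center[None])
        a = loop
        b = np.roll(loop, -1)
        # boundary edges run a->b in face winding order; the fan must be
        # wound opposite to face the same side as the surrounding faces
        new_faces.append(np.stack([b, a, np.full(len(a), next_idx)], axis=1))
        next_idx += 1
    out = trimesh.Trimesh(np.vstack(new_verts), np.vstack(new_faces), process=False)
    return out


def offset_shell(patch: trimesh.Trimesh, thickness: float) -> trimesh.Trimesh:
    """Thicken an open surface patch into a closed shell: the patch itself is
    the intaglio (bit-identical vertices); the outer surface sits at the
    smoothed-normal lateral offset with its height from a rolling-ball
    envelope of the patch; side walls close every boundary loop.

    The patch must be a height-field-like top surface (its faces oriented
    with positive z in the build frame)."""
    if len(patch.faces) == 0:
        raise BuildError("empty patch")
    normals = _smooth_vertex_normals(patch, iterations=8)
    base = patch.vertices.view(np.ndarray)
    tri = patch.faces
    if np.median(normals[:, 2]) <= 0:
        where = base[np.argmin(normals[:, 2])]
        raise BuildError(
            f"offset collapse: surface orientation degenerate for thickness "
            f"{thickness} near {where.round(2).tolist()}"
        )
    # diffusion-smoothed normals are one-sided at the boundary and tilt the
    # rim offset inward; raw vertex normals are unbiased there, and the rim
    # ribbon smoothing below absorbs their noise on jagged loops
    raw = patch.vertex_normals.view(np.ndarray)
    for loop in _boundary_loops(tri):
        normals[loop] = raw[loop]
    top_xy = base[:, :2] + thickness * normals[:, :2]
    # densify the envelope sources with edge midpoints and face centroids so
    # the discrete sphere envelope does not dip between coarse vertices
    edges = base[patch.edges_unique]
    sources = np.vstack([base, edges.mean(axis=1), base[tri].mean(axis=1)])
    top_z = _ball_envelope(sources, thickness, top_xy)
    bad = ~np.isfinite(top_z)
    if bad.any():
        top_z[bad] = base[bad, 2] + thickness * np.abs(normals[bad, 2])
    # never thinner than half the nominal thickness straight up
    top_z = np.maximum(top_z, base[:, 2] + 0.5 * thickness)
    top = np.column_stack([top_xy, top_z])
    # smooth the rim ribbon along each boundary loop: a jagged base loop
    # with per-vertex lateral offsets would twist the side wall into itself
    for loop in _boundary_loops(tri):
        if len(loop) < 8:
            continue
        ring = top[loop]
        kernel = 9
        pad = kernel // 2
        ext = np.vstack([ring[-pad:], ring, ring[:pad]])
        sm = np.stack([ext[i : i + len(ring)] for i in range(kernel)]).mean(axis=0)
        # averaging shortens the offset (chord shrink): keep the smoothed
        # direction but restore its length to exactly the wall thickness
        d = sm - base[loop]
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        sm = base[loop] + d * (thickness / np.maximum(norms, 1e-12))
        sm[:, 2] = np.maximum(sm[:, 2], base[loop, 2] + 0.5 * thickness)
        top[loop] = sm
    n = len(base)
    verts = np.vstack([base, top])
    faces = [tri[:, ::-1], tri + n]  # intaglio flipped outward, top as-is
    for loop in _boundary_loops(tri):
        a = loop
        b = np.roll(loop, -1)
        faces.append(np.stack([a, b, a + n], axis=1))
        faces.append(np.stack([b, b + n, a + n], axis=1))
    shell = trimesh.Trimesh(verts, np.vstack(faces), process=False)
    if shell.volume < 0:
        shell.invert()
    return shell


def build_plate(
    bridged: trimesh.Trimesh,
    detection: DetectionResult,
    spec: PlateSpec,
) -> trimesh.Trimesh:
    """Shell the bridged cast into a molding plate.

    The covered (retained) region is the upward-facing top surface of the
    cast solid inside the arch footprint (ellipse inflated by a small
    margin, trimmed at the tuberal line posteriorly and ``trim_height``
    below the crest on the vestibular side); the intaglio reproduces it
    exactly, the outer surface is offset by ``thickness``.
    """
    spec.validate()
    frame = detection.frame
    local_mesh = trimesh.Trimesh(frame.to_local(bridged.vertices), bridged.faces, process=False)
    components = local_mesh.split(only_watertight=False)
    if len(components) > 1:
        # voxel-union overlapping closed shells into a single surface, then
        # pull vertices back onto the exact inputs
        bounds = np.array(
            [
                np.min([c.bounds[0] for c in components], axis=0),
                np.max([c.bounds[1] for c in components], axis=0),
            ]
        )
        grid = Grid.from_bounds(bounds, spec.voxel_pitch, pad=3)
        occ = np.zeros(grid.shape, dtype=bool)
        for c in components:
            occ |= grid.voxelize(c)
        surface = grid.mesh_from_occupancy(occ)
        surface = snap_to_sources(surface, list(components), max_dist=2.0 * spec.voxel_pitch)
        grid_for_top = grid
        occ_for_top = occ
    else:
        surface = local_mesh
        grid_for_top = Grid.from_bounds(local_mesh.bounds, spec.voxel_pitch, pad=3)
        occ_for_top = grid_for_top.voxelize(local_mesh)

    # column-top height map of the solid
    nz = occ_for_top.shape[2]
    zs = grid_for_top.origin[2] + np.arange(nz) * grid_for_top.pitch
    any_occ = occ_for_top.any(axis=2)
    top_idx = nz - 1 - np.argmax(occ_for_top[:, :, ::-1], axis=2)
    top_z = np.where(any_occ, zs[top_idx], -np.inf)

    # vertical-insertion reachability: a face belongs to the intaglio when a
    # probe just outside it has no solid above (the plate seats occlusally;
    # vertical walls are reachable, undercuts are not)
    centroids = surface.triangles_center
    pitch = grid_for_top.pitch
    probes = centroids + 0.6 * pitch * surface.face_normals
    ci = np.clip(
        np.round((probes[:, 0] - grid_for_top.origin[0]) / pitch).astype(int),
        0,
        occ_for_top.shape[0] - 1,
    )
    cj = np.clip(
        np.round((probes[:, 1] - grid_for_top.origin[1]) / pitch).astype(int),
        0,
        occ_for_top.shape[1] - 1,
    )
    on_top = top_z[ci, cj] <= probes[:, 2] + _TOP_TOL_FACTOR * pitch
    upward = surface.face_normals[:, 2] > -0.3

    ell = detection.ellipse
    ct, st = np.cos(ell.theta), np.sin(ell.theta)
    d = centroids[:, :2] - ell.center
    lu = ct * d[:, 0] + st * d[:, 1]
    lv = -st * d[:, 0] + ct * d[:, 1]
    margin = _FOOTPRINT_MARGIN
    rho = np.sqrt((lu / (ell.a + margin)) ** 2 + (lv / (ell.b + margin)) ** 2)
    in_footprint = rho <= 1.0

    mt, anterior = _posterior_line(detection)
    ahead = (centroids[:, :2] - mt) @ anterior >= -_POSTERIOR_MARGIN

    # the vestibular trim applies only outside the arch: the palatal side is
    # always covered, the outer skirt stops trim_height below the crest
    z_floor = _crest_height(detection) - spec.trim_height
    above_floor = centroids[:, 2] >= z_floor
    inside_arch = np.sqrt((lu / ell.a) ** 2 + (lv / ell.b) ** 2) <= 1.0
    keep = on_top & upward & in_footprint & ahead & (above_floor | inside_arch)
    if keep.sum() < 10:
        raise BuildError("retained region is empty; check detection and trim parameters")

    patch = trimesh.Trimesh(surface.vertices.copy(), surface.faces[keep], process=False)
    patch.remove_unreferenced_vertices()
    # largest connected face component with a manifold boundary
    for _ in range(5):
        comps = trimesh.graph.connected_components(
            patch.face_adjacency, nodes=np.arange(len(patch.faces))
        )
        biggest = max(comps, key=len)
        faces = _make_boundary_manifold(patch.faces[np.asarray(biggest)])
        done = len(faces) == len(biggest)
        patch = trimesh.Trimesh(patch.vertices.copy(), faces, process=False)
        if done:
            break
    patch = _fill_small_holes(patch)
    patch.remove_unreferenced_vertices()

    shell_local = offset_shell(patch, spec.thickness)
    plate = trimesh.Trimesh(frame.to_world(shell_local.vertices), shell_local.faces, process=False)
    plate.metadata["name"] = "plate"
    plate.metadata["detection_json"] = detection.to_json()
    plate.metadata["intaglio"] = trimesh.Trimesh(
        frame.to_world(patch.vertices), patch.faces, process=False
    )
    return plate


# ---------------------------------------------------------------------------
# pin / hole / smoothing
# ---------------------------------------------------------------------------


def _plate_detection(plate: trimesh.Trimesh) -> DetectionResult:
    try:
        return DetectionResult.from_json(plate.metadata["detection_json"])
    except KeyError as exc:
        raise BuildError("plate is missing its detection context metadata") from exc


def _anterior_arc_param(detection: DetectionResult) -> float:
    """Parametric angle of the anterior midline point on the arch ellipse."""
    mt, anterior = _posterior_line(detection)
    ts = np.linspace(-np.pi, np.pi, 721)
    pts = ellipse_point(
        detection.ellipse.center, detection.ellipse.a, detection.ellipse.b, detection.ellipse.theta, ts
    )
    return float(ts[np.argmax((pts - mt) @ anterior)])


def _voxel_op(
    plate: trimesh.Trimesh, tool: trimesh.Trimesh, op: str, pitch: float
) -> tuple[trimesh.Trimesh, np.ndarray, np.ndarray, Grid]:
    bounds = np.array(
        [
            np.minimum(plate.bounds[0], tool.bounds[0]),
            np.maximum(plate.bounds[1], tool.bounds[1]),
        ]
    )
    grid = Grid.from_bounds(bounds, pitch, pad=3)
    occ_p = grid.voxelize(plate)
    occ_t = grid.voxelize(tool)
    occ = (occ_p | occ_t) if op == "union" else (occ_p & ~occ_t)
    out = grid.mesh_from_occupancy(occ)
    out = snap_to_sources(
        out, [plate, tool], max_dist=2.0 * pitch, priority=plate.metadata.get("intaglio")
    )
    return out, occ_p, occ_t, grid


def _carry_metadata(new: trimesh.Trimesh, old: trimesh.Trimesh, name: str) -> trimesh.Trimesh:
    for key in ("detection_json", "intaglio"):
        if key in old.metadata:
            new.metadata[key] = old.metadata[key]
    new.metadata["name"] = name
    return new


def add_retention_pin(plate: trimesh.Trimesh, spec: PlateSpec) -> trimesh.Trimesh:
    """Attach the retention pin: Boolean union with a capped cylinder seated
    at the anterior midline crest, tilted ``pin_elevation_deg`` above the
    occlusal plane. The pin anchors the extraoral taping."""
    spec.validate()
    detection = _plate_detection(plate)
    frame = detection.frame
    ell = detection.ellipse
    t_pin = spec.pin_arc_param if spec.pin_arc_param is not None else _anterior_arc_param(detection)
    xy = ellipse_point(ell.center, ell.a, ell.b, ell.theta, t_pin)
    z_crest = _crest_height(detection)
    # seat the pin on the outer face of the plate: the inner end must stay
    # inside the shell wall, never pierce the intaglio into the anatomy
    p0 = np.array([xy[0], xy[1], z_crest + 0.75 * spec.thickness])
    outward = np.array([xy[0] - ell.center[0], xy[1] - ell.center[1], 0.0])
    outward /= np.linalg.norm(outward)
    elev = np.radians(spec.pin_elevation_deg)
    axis = np.cos(elev) * outward + np.sin(elev) * np.array([0.0, 0.0, 1.0])
    seg_local = np.array([p0 - 0.15 * spec.pin_length * axis, p0 + 0.85 * spec.pin_length * axis])
    seg_world = frame.to_world(seg_local)
    pin = trimesh.creation.cylinder(radius=spec.pin_radius, segment=seg_world, sections=48)

    out, occ_p, occ_t, grid = _voxel_op(plate, pin, "union", spec.voxel_pitch)
    if not (occ_p & occ_t).any():
        raise PlacementError("retention pin does not touch the plate")
    if not (occ_t & ~occ_p).any():
        return _carry_metadata(plate.copy(), plate, plate.metadata.get("name", "plate"))
    return _carry_metadata(out, plate, f"{plate.metadata.get('name', 'plate')}_pin")


def add_ventilation_hole(plate: trimesh.Trimesh, spec: PlateSpec) -> trimesh.Trimesh:
    """Cut the ventilation hole: Boolean difference with a cylinder along the
    occlusal normal at the hole position (arc position moved ``hole_offset``
    towards the arch center). The channel must pierce the plate."""
    spec.validate()
    detection = _plate_detection(plate)
    frame = detection.frame
    ell = detection.ellipse
    t_hole = (
        spec.hole_arc_param if spec.hole_arc_param is not None else _anterior_arc_param(detection)
    )
    xy = ellipse_point(ell.center, ell.a, ell.b, ell.theta, t_hole)
    inward = np.array([ell.center[0] - xy[0], ell.center[1] - xy[1]])
    inward /= np.linalg.norm(inward)
    cxy = xy + spec.hole_offset * inward
    local = frame.to_local(plate.vertices)
    z_lo, z_hi = local[:, 2].min() - 2.0, local[:, 2].max() + 2.0
    seg_world = frame.to_world(
        np.array([[cxy[0], cxy[1], z_lo], [cxy[0], cxy[1], z_hi]])
    )
    tool = trimesh.creation.cylinder(radius=spec.hole_radius, segment=seg_world, sections=48)

    out, occ_p, occ_t, grid = _voxel_op(plate, tool, "difference", spec.voxel_pitch)
    if not (occ_p & occ_t).any():
        raise PlacementError("ventilation hole does not intersect the plate")
    # through-going probe: no residual material along the hole axis
    occ_after = occ_p & ~occ_t
    zs = np.linspace(z_lo + 1.0, z_hi - 1.0, 64)
    probes_local = np.column_stack([np.full_like(zs, cxy[0]), np.full_like(zs, cxy[1]), zs])
    probe_world = frame.to_world(probes_local)
    idx = np.round((probe_world - grid.origin) / grid.pitch).astype(int)
    inside = np.zeros(len(idx), dtype=bool)
    ok = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
    inside[ok] = occ_after[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    if inside.any():
        raise PlacementError("ventilation channel is not through-going")
    return _carry_metadata(out, plate, f"{plate.metadata.get('name', 'plate')}_hole")


def carve(plate: trimesh.Trimesh, tool: trimesh.Trimesh, spec: PlateSpec) -> trimesh.Trimesh:
    """Grind away a user-supplied tool volume (clinical plate adjustment);
    reuses the ventilation-hole difference machinery."""
    out, occ_p, occ_t, _ = _voxel_op(plate, tool, "difference", spec.voxel_pitch)
    if not (occ_p & occ_t).any():
        raise PlacementError("carve tool does not intersect the plate")
    return _carry_metadata(out, plate, f"{plate.metadata.get('name', 'plate')}_carved")


def smooth_plate(plate: trimesh.Trimesh, spec: PlateSpec) -> trimesh.Trimesh:
    """Taubin lambda/mu smoothing (volume-preserving pair) with the intaglio
    vertices constrained to at most 0.05 mm displacement so the fit is kept."""
    spec.validate()
    if spec.smoothing_iterations <= 0:
        return _carry_metadata(plate.copy(), plate, plate.metadata.get("name", "plate"))
    out = plate.copy()
    trimesh.smoothing.filter_taubin(out, lamb=0.5, nu=0.53, iterations=spec.smoothing_iterations)
    intaglio = plate.metadata.get("intaglio")
    if intaglio is not None and len(intaglio.faces):
        query = SurfaceQuery.from_mesh(intaglio)
        was_intaglio = query.distance(plate.vertices) < 0.02
        if was_intaglio.any():
            before = plate.vertices.view(np.ndarray)[was_intaglio]
            after = out.vertices.view(np.ndarray)[was_intaglio]
            delta = after - before
            norms = np.linalg.norm(delta, axis=1, keepdims=True)
            factor = np.minimum(1.0, 0.05 / np.maximum(norms, 1e-12))
            verts = out.vertices.view(np.ndarray).copy()
            verts[was_intaglio] = before + delta * factor
            out = trimesh.Trimesh(verts, out.faces.copy(), process=False)
    return _carry_metadata(out, plate, f"{plate.metadata.get('name', 'plate')}_smoothed")


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------


def intaglio_fidelity(
    cast: trimesh.Trimesh,
    plate: trimesh.Trimesh,
    detection: DetectionResult,
    spec: PlateSpec,
    exclude_radius: float = 0.0,
    exclude_point: np.ndarray | None = None,
    boundary_margin: float = 1.0,
) -> float:
    """Max nearest-distance from retained cast-surface vertices to the plate.

    A cast vertex counts as retained when its projection onto the intaglio
    patch lands at least ``boundary_margin`` inside the patch boundary and
    the projection distance is below 0.5 mm (this excludes the trim border,
    the bridged cleft channel — where the intaglio follows the guiding strip,
    not the cast — and anything the plate never covered). An optional disk
    around ``exclude_point`` is ignored, e.g. the ventilation hole.
    """
    intaglio = plate.metadata.get("intaglio")
    if intaglio is None or len(intaglio.faces) == 0:
        raise BuildError("plate has no intaglio metadata")
    query = SurfaceQuery.from_mesh(intaglio)
    proj, dint, _ = query.query(cast.vertices)
    loops = _boundary_loops(intaglio.faces)
    sel = dint < 0.5
    if loops:
        bpts = intaglio.vertices.view(np.ndarray)[np.concatenate(loops)]
        dbound = cKDTree(bpts).query(proj)[0]
        sel &= dbound > boundary_margin
    if detection.gap_span is not None:
        # the bridged channel: the intaglio follows the guiding strip there,
        # so exclude everything within strip reach of the gap-arc spine
        frame = detection.frame
        ell = detection.ellipse
        local = frame.to_local(cast.vertices)
        lo, hi = detection.gap_span
        thetas = np.linspace(lo - 0.35, hi + 0.35, 64)
        phi = thetas - ell.theta
        r = ell.a * ell.b / np.hypot(ell.b * np.cos(phi), ell.a * np.sin(phi))
        spine_xy = np.column_stack(
            [ell.center[0] + r * np.cos(thetas), ell.center[1] + r * np.sin(thetas)]
        )
        # vertical sheet: anything above/below the strip arc is channel too
        d_strip = cKDTree(spine_xy).query(local[:, :2])[0]
        sel &= d_strip > 7.0
    pts = cast.vertices.view(np.ndarray)[sel]
    if exclude_point is not None and exclude_radius > 0:
        pts = pts[np.linalg.norm(pts - exclude_point, axis=1) > exclude_radius]
    if len(pts) == 0:
        raise BuildError("no cast vertices in the retained region")
    plate_query = SurfaceQuery.from_mesh(plate)
    return float(plate_query.distance(pts).max())


def surface_roughness(mesh: trimesh.Trimesh) -> float:
    """RMS dihedral angle across face adjacencies (radians)."""
    return float(np.sqrt(np.mean(mesh.face_adjacency_angles**2)))
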