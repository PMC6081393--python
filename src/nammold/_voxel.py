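"""Voxel-backed solid modeling: solid voxelization by z-column parity,
boolean set operations on shared grids, and remeshing via marching cubes on
a signed distance field.

Marching-cubes vertices are optionally projected back onto the exact input
surfaces (``snap_to_sources``) so that boolean results keep the source
geometry to well below the voxel pitch wherever a single source surface is
locally nearest.
"""

from __future__ import annotations

import numpy as np
import trimesh
from numba import njit
from scipy import ndimage
from skimage import measure

from ._geometry import SurfaceQuery

# fractional offsets dodge exact edge/vertex ray hits and voxel-center
# coincidences with flat model surfaces (exact zeros break marching cubes)
_JITTER_X = 0.12345678
_JITTER_Y = 0.23456789
_JITTER_Z = 0.34567891
_EPS = 1e-9


@njit(cache=True)
def _rasterize(tri, x0, y0, pitch, nx, ny, crossings, signs, counts, maxc):  # pragma: no cover - numba
    for t in range(tri.shape[0]):
        ax, ay, az = tri[t, 0, 0], tri[t, 0, 1], tri[t, 0, 2]
        bx, by, bz = tri[t, 1, 0], tri[t, 1, 1], tri[t, 1, 2]
        cx, cy, cz = tri[t, 2, 0], tri[t, 2, 1], tri[t, 2, 2]
        minx = min(ax, bx, cx)
        maxx = max(ax, bx, cx)
        miny = min(ay, by, cy)
        maxy = max(ay, by, cy)
        i0 = max(0, int(np.ceil((minx - x0) / pitch - _EPS)))
        i1 = min(nx - 1, int(np.floor((maxx - x0) / pitch + _EPS)))
        j0 = max(0, int(np.ceil((miny - y0) / pitch - _EPS)))
        j1 = min(ny - 1, int(np.floor((maxy - y0) / pitch + _EPS)))
        d = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        if d == 0.0:
            continue
        # d > 0 <=> face normal points up: the ray leaves the solid there
        s = np.int8(-1) if d > 0.0 else np.int8(1)
        for i in range(i0, i1 + 1):
            px = x0 + i * pitch
            for j in range(j0, j1 + 1):
                py = y0 + j * pitch
                w0 = ((bx - px) * (cy - py) - (by - py) * (cx - px)) / d
                w1 = ((cx - px) * (ay - py) - (cy - py) * (ax - px)) / d
                w2 = 1.0 - w0 - w1
                if w0 < 0.0 or w1 < 0.0 or w2 < 0.0:
                    continue
                z = w0 * az + w1 * bz + w2 * cz
                col = i * ny + j
                c = counts[col]
                if c < maxc:
                    crossings[col, c] = z
                    signs[col, c] = s
                counts[col] = c + 1


@njit(cache=True)
def _fill(occ, crossings, signs, counts, z0, pitch, nx, ny, nz):  # pragma: no cover - numba
    """Nonzero-winding fill: a voxel center is inside when the signed count
    of surface crossings below it is positive. Robust to locally
    double-covered sheets (opposite orientations cancel), unlike even-odd
    parity."""
    for col in range(nx * ny):
        c = counts[col]
        if c < 2:
            continue
        order = np.argsort(crossings[col, :c])
        i = col // ny
        j = col % ny
        winding = 0
        for k in range(c - 1):
            winding += signs[col, order[k]]
            z_lo = crossings[col, order[k]]
            z_hi = crossings[col, order[k + 1]]
            if winding <= 0:
                continue
            k0 = int(np.ceil((z_lo - z0) / pitch - 1e-9))
            k1 = int(np.floor((z_hi - z0) / pitch + 1e-9))
            if k0 < 0:
                k0 = 0
            if k1 > nz - 1:
                k1 = nz - 1
            for kk in range(k0, k1 + 1):
                occ[i, j, kk] = True


class Grid:
    """A shared voxel grid: origin (cell-center of voxel (0,0,0)), pitch, shape."""

    def __init__(self, origin: np.ndarray, pitch: float, shape: tuple[int, int, int]):
        self.origin = np.asarray(origin, dtype=float)
        self.pitch = float(pitch)
        self.shape = tuple(int(s) for s in shape)

    @classmethod
    def from_bounds(cls, bounds: np.ndarray, pitch: float, pad: int = 3) -> "Grid":
        b0, b1 = np.asarray(bounds, dtype=float)
        shape = tuple(int(np.ceil((b1[k] - b0[k]) / pitch)) + 2 * pad + 1 for k in range(3))
        origin = np.array(
            [
                b0[0] - pad * pitch + _JITTER_X * pitch,
                b0[1] - pad * pitch + _JITTER_Y * pitch,
                b0[2] - pad * pitch + _JITTER_Z * pitch,
            ]
        )
        return cls(origin, pitch, shape)

    def voxelize(self, mesh: trimesh.Trimesh, maxc: int = 128) -> np.ndarray:
        """Solid occupancy of a closed, outward-oriented mesh on this grid
        (z-column crossings with the nonzero-winding rule)."""
        nx, ny, nz = self.shape
        crossings = np.empty((nx * ny, maxc), dtype=np.float64)
        signs = np.zeros((nx * ny, maxc), dtype=np.int8)
        counts = np.zeros(nx * ny, dtype=np.int64)
        tri = np.ascontiguousarray(mesh.triangles, dtype=np.float64)
        _rasterize(
            tri, self.origin[0], self.origin[1], self.pitch, nx, ny, crossings, signs, counts, maxc
        )
        occ = np.zeros(self.shape, dtype=np.bool_)
        _fill(occ, crossings, signs, counts, self.origin[2], self.pitch, nx, ny, nz)
        return occ

    def signed_field(self, occ: np.ndarray) -> np.ndarray:
        """Signed distance estimate (voxel units, negative inside).

        A deterministic sub-millivoxel dither breaks the exact value ties of
        the lattice distance transform, which otherwise produce nonmanifold
        saddle configurations in marching cubes; the surface shift is below
        1e-3 voxel."""
        inside = ndimage.distance_transform_edt(occ)
        outside = ndimage.distance_transform_edt(~occ)
        phi = (outside - inside).astype(np.float32)
        nx, ny, nz = phi.shape
        ii = (np.arange(nx, dtype=np.int64) * 73856093)[:, None, None]
        jj = (np.arange(ny, dtype=np.int64) * 19349663)[None, :, None]
        kk = (np.arange(nz, dtype=np.int64) * 83492791)[None, None, :]
        dither = (((ii ^ jj ^ kk) % 1024).astype(np.float32) / 1024.0 - 0.5) * 1e-3
        return phi + dither

    def mesh_from_occupancy(self, occ: np.ndarray, clean: bool = True) -> trimesh.Trimesh:
        if clean:
            occ = clean_occupancy(occ)
        phi = self.signed_field(occ)
        return self.mesh_from_field(phi)

    def mesh_from_field(self, phi: np.ndarray, level: float = 0.0) -> trimesh.Trimesh:
        """Marching cubes on a scalar field sampled at voxel centers."""
        phi = np.asarray(phi, dtype=np.float32)
        verts, faces, _, _ = measure.marching_cubes(phi, level=level)
        mesh = trimesh.Trimesh(verts * self.pitch + self.origin, faces, process=True)
        mesh.fix_normals()
        return mesh

    def sample_field(self, phi: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of a grid field at world points (mm units
        for distance fields after multiplying by pitch is the caller's job)."""
        pts = (np.atleast_2d(points) - self.origin) / self.pitch
        return ndimage.map_coordinates(phi, pts.T, order=1, mode="nearest")


def clean_occupancy(occ: np.ndarray) -> np.ndarray:
    """Topological cleanup of a solid occupancy: seal one-voxel pinholes
    (binary closing), keep the largest connected component, and fill internal
    cavities (voids not reaching the grid border). Leaves through-channels
    (e.g. drilled holes) open."""
    occ = ndimage.binary_closing(occ)
    labels, n = ndimage.label(occ)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        occ = labels == np.argmax(sizes)
    voids, n = ndimage.label(~occ)
    if n > 1:
        border = np.zeros_like(occ)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        outside = np.unique(voids[border])
        internal = ~np.isin(voids, outside) & ~occ
        occ = occ | internal
    return occ


def boolean(
    meshes_a: list[trimesh.Trimesh],
    meshes_b: list[trimesh.Trimesh],
    op: str,
    pitch: float = 0.2,
    snap: bool = True,
    pad: int = 3,
) -> trimesh.Trimesh:
    """Voxel-backed boolean of union(meshes_a) with union(meshes_b).

    op: "union" | "difference" | "intersection"
    With ``snap``, marching-cubes vertices within 0.7 pitch of exactly one
    source surface are projected onto it.
    """
    all_meshes = list(meshes_a) + list(meshes_b)
    bounds = np.array(
        [
            np.min([m.bounds[0] for m in all_meshes], axis=0),
            np.max([m.bounds[1] for m in all_meshes], axis=0),
        ]
    )
    grid = Grid.from_bounds(bounds, pitch, pad=pad)
    occ_a = np.zeros(grid.shape, dtype=bool)
    for m in meshes_a:
        occ_a |= grid.voxelize(m)
    occ_b = np.zeros(grid.shape, dtype=bool)
    for m in meshes_b:
        occ_b |= grid.voxelize(m)
    if op == "union":
        occ = occ_a | occ_b
    elif op == "difference":
        occ = occ_a & ~occ_b
    elif op == "intersection":
        occ = occ_a & occ_b
    else:  # pragma: no cover
        raise ValueError(f"unknown op {op!r}")
    out = grid.mesh_from_occupancy(occ)
    if snap:
        out = snap_to_sources(out, all_meshes, max_dist=2.0 * pitch)
    return out


def snap_to_sources(
    mesh: trimesh.Trimesh,
    sources: list[trimesh.Trimesh],
    max_dist: float,
    ambiguity_ratio: float = 0.75,
    priority: trimesh.Trimesh | None = None,
) -> trimesh.Trimesh:
    """Project vertices onto the nearest source surface.

    A vertex moves only if its nearest source is within ``max_dist`` and no
    other source is nearly as close (closer than ``ambiguity_ratio`` times
    ``max_dist``); vertices near an intersection curve stay where marching
    cubes put them to avoid fold-overs. ``max_dist`` of ~2 voxel pitch
    covers the worst-case bias of the lattice distance transform.

    ``priority`` is an exact reference surface (e.g. a plate's intaglio
    patch) that wins outright wherever it is within ``max_dist``: repeated
    remeshing then cannot accumulate error on it.
    """
    verts = mesh.vertices.view(np.ndarray).copy()
    # snap distances are well below the local edge length: few candidate
    # triangles suffice
    queries = [SurfaceQuery.from_mesh(s, k=6) for s in sources]
    closest = np.stack([q.query(verts)[0] for q in queries])  # (s, n, 3)
    dists = np.linalg.norm(closest - verts[None], axis=2)  # (s, n)
    order = np.argsort(dists, axis=0)
    best = order[0]
    n = len(verts)
    rows = np.arange(n)
    d_best = dists[best, rows]
    prio_done = np.zeros(len(verts), dtype=bool)
    if priority is not None and len(priority.faces):
        pq = SurfaceQuery.from_mesh(priority, k=6)
        pc, pd, _ = pq.query(verts)
        # the exact reference wins outright unless another source is clearly
        # closer (e.g. the rim of a freshly drilled hole)
        prio_done = (pd <= max_dist) & (pd <= d_best + 0.25 * max_dist)
        verts[prio_done] = pc[prio_done]
    movable = (d_best <= max_dist) & ~prio_done
    if len(sources) > 1:
        d_second = dists[order[1], rows]
        movable &= d_second > ambiguity_ratio * max_dist
    verts[movable] = closest[best[movable], rows[movable]]
    out = trimesh.Trimesh(verts, mesh.faces.copy(), process=False)
    return out


def contains(mesh: trimesh.Trimesh, points: np.ndarray, pitch: float = 0.2) -> np.ndarray:
    """Inside test for a closed mesh via the voxel signed field (tolerance
    about half a voxel; adequate for collision checks, not for exact CSG)."""
    grid = Grid.from_bounds(mesh.bounds, pitch, pad=3)
    phi = grid.signed_field(grid.voxelize(mesh))
    vals = grid.sample_field(phi, points) * pitch
    return vals < 0.0
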