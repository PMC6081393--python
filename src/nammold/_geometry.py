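"""Low-level geometry kernels: point-to-triangle distance, nearest-surface
queries, and ellipse geometry (parameterization, nearest point, arc sampling).

These are deliberately dependency-light (numpy + scipy.spatial only); the
nearest-surface query replaces rtree-backed proximity structures with a
KDTree over triangle centroids plus an exact point-triangle distance on a
small candidate set.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

# ---------------------------------------------------------------------------
# point -> triangle
# ---------------------------------------------------------------------------


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point on each triangle for each point (broadcast pairwise).

    Parameters
    ----------
    points : (n, 3)
    tri : (n, 3, 3) one triangle per point

    Returns
    -------
    closest : (n, 3), dist : (n,)

    Uses the Ericson/Eberly region classification, fully vectorized.
    """
    p = np.asarray(points, dtype=float)
    a = tri[:, 0]
    b = tri[:, 1]
    c = tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex a
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex b
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # edge ab
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    # vertex c
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge ac
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    # edge bc
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    dist = np.linalg.norm(p - out, axis=1)
    return out, dist


class SurfaceQuery:
    """Nearest point / distance queries against a triangle soup.

    Candidate triangles come from a KDTree over triangle centroids (k nearest,
    inflated by triangle size), then the exact point-triangle distance picks
    the winner. Exact provided ``k`` covers the true nearest triangle, which
    holds for the near-surface queries this package performs (query distance
    comparable to the local edge length).
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 16):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.vertices[self.faces]
        self.centroids = self.tri.mean(axis=1)
        self._tree = cKDTree(self.centroids)
        self.k = min(k, len(self.faces))

    @classmethod
    def from_mesh(cls, mesh, k: int = 16) -> "SurfaceQuery":
        return cls(mesh.vertices, mesh.faces, k=k)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, distances, face_indices)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n_total = len(pts)
        out_c = np.empty((n_total, 3))
        out_d = np.empty(n_total)
        out_f = np.empty(n_total, dtype=np.int64)
        chunk = 20000  # bound peak memory of the pairwise evaluation
        for lo in range(0, n_total, chunk):
            sub = pts[lo : lo + chunk]
            _, idx = self._tree.query(sub, k=self.k)
            idx = np.atleast_2d(idx)
            n, k = idx.shape
            flat_pts = np.repeat(sub, k, axis=0)
            flat_tri = self.tri[idx.ravel()]
            closest, dist = closest_point_on_triangles(flat_pts, flat_tri)
            dist = dist.reshape(n, k)
            closest = closest.reshape(n, k, 3)
            best = np.argmin(dist, axis=1)
            rows = np.arange(n)
            out_c[lo : lo + chunk] = closest[rows, best]
            out_d[lo : lo + chunk] = dist[rows, best]
            out_f[lo : lo + chunk] = idx[rows, best]
        return out_c, out_d, out_f

    def distance(self, points: np.ndarray) -> np.ndarray:
        return self.query(points)[1]


# ---------------------------------------------------------------------------
# ellipse geometry
# ---------------------------------------------------------------------------


def ellipse_point(center, a, b, theta, t):
    """Point(s) on the ellipse at parametric angle(s) t (radians)."""
    t = np.asarray(t, dtype=float)
    ct, st = np.cos(theta), np.sin(theta)
    x = a * np.cos(t)
    y = b * np.sin(t)
    px = center[0] + ct * x - st * y
    py = center[1] + st * x + ct * y
    return np.stack([px, py], axis=-1)


def _nearest_on_canonical_ellipse(a: float, b: float, px: float, py: float) -> tuple[float, float]:
    """Nearest point on an axis-aligned, origin-centered ellipse.

    First-quadrant reduction, then the unique root s of
    (a x / (s + a^2))^2 + (b y / (s + b^2))^2 = 1 on (-min(a,b)^2, inf);
    the function is strictly decreasing there, so bracketing is safe. This
    is robust for interior points (inside the evolute), where parametric
    Newton has multiple stationary points."""
    from scipy.optimize import brentq

    sx = 1.0 if px >= 0 else -1.0
    sy = 1.0 if py >= 0 else -1.0
    # nudge off the axes: avoids the degenerate split cases with ~1e-12 error
    x = max(abs(px), 1e-12 * a)
    y = max(abs(py), 1e-12 * b)

    def f(s):
        return (a * x / (s + a * a)) ** 2 + (b * y / (s + b * b)) ** 2 - 1.0

    lo = -min(a, b) ** 2
    lo = lo + max(1e-14, abs(lo) * 1e-13)
    while f(lo) <= 0:  # numerically inside the pole: step closer
        lo *= 0.5 if lo < 0 else 1.0
        lo -= 1e-9
        if lo <= -min(a, b) ** 2:
            lo = -min(a, b) ** 2 * (1 - 1e-15)
            break
    hi = max(a * x, b * y) + max(a, b)
    while f(hi) > 0:
        hi = 2 * hi + 1.0
    s = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
    ex = a * a * x / (s + a * a)
    ey = b * b * y / (s + b * b)
    return sx * ex, sy * ey


def ellipse_nearest_points(points: np.ndarray, center, a, b, theta) -> np.ndarray:
    """Nearest point on the ellipse outline for each 2D point."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ct, st = np.cos(theta), np.sin(theta)
    rot = np.array([[ct, st], [-st, ct]])  # world -> canonical
    local = (pts - np.asarray(center)) @ rot.T
    out = np.empty_like(local)
    for i, (x, y) in enumerate(local):
        out[i] = _nearest_on_canonical_ellipse(a, b, x, y)
    inv = np.array([[ct, -st], [st, ct]])
    return out @ inv.T + np.asarray(center)


def ellipse_distances(points: np.ndarray, center, a, b, theta) -> np.ndarray:
    """Geometric (orthogonal) distance from each 2D point to the ellipse."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    nearest = ellipse_nearest_points(pts, center, a, b, theta)
    return np.linalg.norm(pts - nearest, axis=1)


def rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u to unit vector v."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees: rotate about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return rotation_about(axis, np.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    return rotation_about(axis, float(np.arctan2(s, c)))


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
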