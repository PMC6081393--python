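"""Automatic detection of the edentulous alveolar crest and the arch ellipse.

The detector is self-contained: it estimates an occlusal reference frame by
principal components of the vertex cloud, extracts the crest as per-angular-
bin maximum-height surface points (polar max-height profiles), splits the
crest at the cleft (empty or low bins, or a positional jump), and fits the
dental-arch ellipse by the direct least-squares conic fit constrained to
ellipses (Fitzgibbon's constraint in the numerically stable Halir-Flusser
form), followed by a geometric (orthogonal-distance) residual.

The result serializes to JSON so a clinician can confirm or correct the
detection by editing the file and re-running downstream stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from ._geometry import ellipse_distances
from .exceptions import DetectionError, FitError, FrameError

_DEFAULT_N_BINS = 180
_GAP_JUMP_MM = 2.0  # positional discontinuity that splits the crest
_HEIGHT_DROP_MM = 1.8  # bins this far below the median crest height are "empty"


@dataclass
class OcclusalFrame:
    """Right-handed orthonormal frame: u, v span the occlusal plane, w is the
    occlusal normal (crest side positive)."""

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def to_local(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - self.origin
        return np.stack([p @ self.u, p @ self.v, p @ self.w], axis=1)

    def to_world(self, local: np.ndarray) -> np.ndarray:
        local = np.atleast_2d(local)
        return (
            self.origin
            + np.outer(local[:, 0], self.u)
            + np.outer(local[:, 1], self.v)
            + np.outer(local[:, 2], self.w)
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in ("origin", "u", "v", "w")}

    @classmethod
    def from_dict(cls, d: dict) -> "OcclusalFrame":
        return cls(*(np.asarray(d[k], dtype=float) for k in ("origin", "u", "v", "w")))


@dataclass
class CrestCurve:
    """Ordered crest polyline of one alveolar segment."""

    points: np.ndarray  # (n, 3) world coordinates, mm
    segment_label: str  # "greater" | "smaller"
    arc_param: np.ndarray  # (n,) strictly monotone angle about the arch center

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def to_dict(self) -> dict:
        return {
            "segment_label": self.segment_label,
            "points": self.points.tolist(),
            "arc_param": self.arc_param.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrestCurve":
        return cls(
            points=np.asarray(d["points"], dtype=float),
            segment_label=d["segment_label"],
            arc_param=np.asarray(d["arc_param"], dtype=float),
        )


@dataclass
class EllipseParams:
    """Arch ellipse in the occlusal plane: center, semi-axes a >= b, rotation
    theta of the major axis in [0, pi)."""

    center: np.ndarray
    a: float
    b: float
    theta: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "a": self.a, "b": self.b, "theta": self.theta}

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseParams":
        return cls(np.asarray(d["center"], float), float(d["a"]), float(d["b"]), float(d["theta"]))


@dataclass
class DetectionResult:
    frame: OcclusalFrame
    crests: list[CrestCurve]
    ellipse: EllipseParams
    rms_residual: float
    gap_span: tuple[float, float] | None  # (start, end) arc angles; None if continuous

    def to_json(self, path=None) -> str:
        payload = {
            "frame": self.frame.to_dict(),
            "crests": [c.to_dict() for c in self.crests],
            "ellipse": self.ellipse.to_dict(),
            "rms_residual": self.rms_residual,
            "gap_span": list(self.gap_span) if self.gap_span is not None else None,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DetectionResult":
        from pathlib import Path

        if isinstance(source, Path) or (
            isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{")
        ):
            with open(source) as fh:
                payload = json.load(fh)
        elif isinstance(source, (str, bytes)):
            payload = json.loads(source)
        else:
            payload = json.load(source)
        return cls(
            frame=OcclusalFrame.from_dict(payload["frame"]),
            crests=[CrestCurve.from_dict(c) for c in payload["crests"]],
            ellipse=EllipseParams.from_dict(payload["ellipse"]),
            rms_residual=float(payload["rms_residual"]),
            gap_span=tuple(payload["gap_span"]) if payload["gap_span"] is not None else None,
        )


# ---------------------------------------------------------------------------
# occlusal frame
# ---------------------------------------------------------------------------


def _signed_axis(coords: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Fix the sign of an axis so the third central moment of the projected
    coordinates is positive (rotation-equivariant, deterministic)."""
    proj = coords @ axis
    skew = np.mean((proj - proj.mean()) ** 3)
    if abs(skew) < 1e-12:
        # symmetric distribution: point towards the farthest vertex
        far = proj[np.argmax(np.abs(proj - proj.mean()))]
        return axis if far >= proj.mean() else -axis
    return axis if skew > 0 else -axis


def compute_occlusal_frame(mesh: trimesh.Trimesh) -> OcclusalFrame:
    """Estimate the occlusal frame: w = least-variance principal direction of
    the vertex positions (sign such that the crest side is positive), origin
    at the vertex centroid."""
    verts = np.asarray(mesh.vertices, dtype=float)
    if len(verts) < 3:
        raise FrameError("too few vertices for a frame")
    centroid = verts.mean(axis=0)
    centered = verts - centroid
    cov = centered.T @ centered / len(verts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] < 1e-12 * max(evals[2], 1.0):
        raise FrameError("degenerate (collinear) vertex distribution")
    w = _signed_axis(centered, evecs[:, 0])
    u = _signed_axis(centered, evecs[:, 2])
    v = np.cross(w, u)
    v /= np.linalg.norm(v)
    u = np.cross(v, w)  # exact right-handed orthonormal triple
    return OcclusalFrame(origin=centroid, u=u, v=v, w=w)


# ---------------------------------------------------------------------------
# crest extraction
# ---------------------------------------------------------------------------


def bin_max_candidates(local: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-angular-bin crest candidate: among upper-half vertices (w at or
    above the median) inside the radial band [0.25, 2.5] x the median radius
    about their in-plane centroid, the vertex of maximum w; ties broken by
    smaller radius, then lower vertex index. Returns one vertex index per bin
    (-1 for empty bins)."""
    wc = local[:, 2]
    up_idx = np.flatnonzero(wc >= np.median(wc))
    if len(up_idx) < 2:
        raise DetectionError("no upper-half vertices")
    cxy = local[up_idx, :2].mean(axis=0)
    rel = local[up_idx, :2] - cxy
    radius = np.linalg.norm(rel, axis=1)
    r_med = np.median(radius)
    band = (radius >= 0.25 * r_med) & (radius <= 2.5 * r_med)
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    bin_idx = np.floor((angles + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    best_vertex = np.full(n_bins, -1, dtype=np.int64)
    order = np.lexsort((up_idx, radius, -wc[up_idx]))
    seen = np.zeros(n_bins, dtype=bool)
    for j in order:
        if not band[j]:
            continue
        b = bin_idx[j]
        if not seen[b]:
            seen[b] = True
            best_vertex[b] = up_idx[j]
    return best_vertex


def extract_crest(
    mesh: trimesh.Trimesh,
    frame: OcclusalFrame,
    n_bins: int = _DEFAULT_N_BINS,
    gap_jump: float = _GAP_JUMP_MM,
    height_drop: float = _HEIGHT_DROP_MM,
) -> list[CrestCurve]:
    """Polar max-height crest extraction.

    Vertices in the upper half (w-coordinate above the median) are binned by
    angle about their in-plane centroid; the crest point of a bin is the
    candidate of maximum w within the radial band (ties: smaller radius, then
    lower vertex index). Bins without candidates, bins far below the median
    crest height, and positional jumps split the crest into labeled segments.
    Each curve is smoothed with a 3-point moving average (endpoints kept).
    """
    if n_bins < 36:
        raise DetectionError("n_bins must be >= 36")
    local = frame.to_local(mesh.vertices)
    wc = local[:, 2]
    best_vertex = bin_max_candidates(local, n_bins)
    best_h = np.where(best_vertex >= 0, wc[np.maximum(best_vertex, 0)], -np.inf)
    seen = best_vertex >= 0
    populated = np.flatnonzero(seen)
    if len(populated) < 2:
        raise DetectionError("fewer than 2 populated angular bins")
    # gate bins against a robustly fitted crest plane: the crest is nearly
    # planar, while vault/base/pedestal bins sit far below it; a plane also
    # absorbs any residual tilt of the estimated occlusal frame
    pop_pts = local[best_vertex[populated]]
    sel = best_h[populated] >= np.median(best_h[populated])
    res = np.zeros(len(populated))
    for _ in range(3):
        A = np.column_stack([pop_pts[sel, 0], pop_pts[sel, 1], np.ones(sel.sum())])
        coef, *_ = np.linalg.lstsq(A, pop_pts[sel, 2], rcond=None)
        res = pop_pts[:, 2] - (coef[0] * pop_pts[:, 0] + coef[1] * pop_pts[:, 1] + coef[2])
        sel = np.abs(res) < max(0.75, np.percentile(np.abs(res[sel]), 80))
        if sel.sum() < 3:
            sel = best_h[populated] >= np.median(best_h[populated])
            break
    keep = np.zeros(n_bins, dtype=bool)
    keep[populated[res >= -height_drop]] = True
    kept = np.flatnonzero(keep)
    if len(kept) < 2:
        raise DetectionError("fewer than 2 crest bins after height gating")

    bin_angle = -np.pi + (kept + 0.5) * 2 * np.pi / n_bins
    pts_local = local[best_vertex[kept]]

    # circular runs of consecutive kept bins
    runs: list[list[int]] = []
    current = [0]
    for i in range(1, len(kept)):
        contiguous = kept[i] == kept[i - 1] + 1
        jump = np.linalg.norm(pts_local[i] - pts_local[i - 1]) > gap_jump
        if contiguous and not jump:
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    runs.append(current)
    # wrap-around merge
    if len(runs) > 1 and kept[0] == 0 and kept[-1] == n_bins - 1:
        if np.linalg.norm(pts_local[0] - pts_local[-1]) <= gap_jump:
            first = runs.pop(0)
            runs[-1] = runs[-1] + [i for i in first]

    curves: list[CrestCurve] = []
    for run in runs:
        if len(run) < 2:
            continue
        idx = np.asarray(run)
        pts = pts_local[idx]
        ang = np.unwrap(bin_angle[idx])
        # 3-point moving average, endpoints kept
        sm = pts.copy()
        if len(pts) > 2:
            sm[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
        world = frame.to_world(sm)
        curves.append(CrestCurve(points=world, segment_label="", arc_param=ang))
    if curves:
        # smoothing can lift points slightly off the surface: project back
        from ._geometry import SurfaceQuery

        query = SurfaceQuery.from_mesh(mesh)
        for c in curves:
            c.points = query.query(c.points)[0]
    if not curves:
        raise DetectionError("no crest segments found")
    curves.sort(key=lambda c: -c.arc_length)
    curves = curves[:2]
    if len(curves) == 1:
        curves[0].segment_label = "greater"
    else:
        curves[0].segment_label = "greater"
        curves[1].segment_label = "smaller"
        curves.sort(key=lambda c: c.arc_param[0])
    return curves


# ---------------------------------------------------------------------------
# ellipse fitting
# ---------------------------------------------------------------------------


def _conic_to_params(coef: np.ndarray) -> EllipseParams:
    """Convert conic coefficients [A,B,C,D,E,F] (Ax²+Bxy+Cy²+Dx+Ey+F=0) to
    center / semi-axes / rotation."""
    A, B, C, D, E, F = coef
    disc = B * B - 4 * A * C
    if disc >= 0:
        raise FitError("conic fit did not yield an ellipse")
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    # value of the quadratic form at the center
    f0 = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    m = np.array([[A, B / 2], [B / 2, C]])
    evals, evecs = np.linalg.eigh(m)
    axes2 = -f0 / evals
    if np.any(axes2 <= 0):
        raise FitError("degenerate conic (non-positive axis length)")
    axes = np.sqrt(axes2)
    order = np.argsort(-axes)  # semi-major first
    a_len, b_len = axes[order]
    major = evecs[:, order[0]]
    theta = float(np.arctan2(major[1], major[0])) % np.pi
    return EllipseParams(center=np.array([cx, cy]), a=float(a_len), b=float(b_len), theta=theta)


def fit_ellipse(points: np.ndarray) -> tuple[EllipseParams, float]:
    """Direct least-squares conic fit constrained to ellipses
    (Halir & Flusser's numerically stable partitioning of Fitzgibbon's
    method), plus the RMS of geometric point-to-ellipse distances."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 5:
        raise FitError(f"need at least 5 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    x, y = (pts - centroid).T  # center for conditioning
    # collinearity check
    _, svals, _ = np.linalg.svd(np.stack([x, y], axis=1), full_matrices=False)
    if svals[1] < 1e-10 * max(svals[0], 1.0):
        raise FitError("points are collinear")
    d1 = np.stack([x * x, x * y, y * y], axis=1)
    d2 = np.stack([x, y, np.ones_like(x)], axis=1)
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular scatter matrix") from exc
    m = s1 + s2 @ t
    c_inv = np.array([[0, 0, 0.5], [0, -1, 0], [0.5, 0, 0]])
    evals, evecs = np.linalg.eig(c_inv @ m)
    # the ellipse solution has 4ac - b^2 > 0
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    good = np.flatnonzero((cond > 0) & np.isfinite(evals.real))
    if len(good) == 0:
        raise FitError("no ellipse solution (hyperbola-only fit)")
    a1 = evecs[:, good[np.argmin(np.abs(evals[good].real))]].real
    coef = np.concatenate([a1, t @ a1])
    params = _conic_to_params(coef)
    # undo the conditioning shift
    params = EllipseParams(params.center + centroid, params.a, params.b, params.theta)
    resid = ellipse_distances(pts, params.center, params.a, params.b, params.theta)
    return params, float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# full detection
# ---------------------------------------------------------------------------


def _strictly_monotone(sorted_vals: np.ndarray) -> np.ndarray:
    """Indices keeping a sorted sequence strictly increasing (dedup)."""
    keep = [0]
    for i in range(1, len(sorted_vals)):
        if sorted_vals[i] > sorted_vals[keep[-1]] + 1e-12:
            keep.append(i)
    return np.asarray(keep)


def detect_ridge(mesh: trimesh.Trimesh, n_bins: int = _DEFAULT_N_BINS) -> DetectionResult:
    """Compose frame estimation, crest extraction and ellipse fitting.

    gap_span is the arc interval of the cleft: with two crest segments it is
    the shorter of the two empty intervals between their endpoints (the long
    one is the open posterior side of the arch); with one continuous crest it
    is None.
    """
    frame = compute_occlusal_frame(mesh)
    crests = extract_crest(mesh, frame, n_bins=n_bins)
    all_pts = np.vstack([c.points for c in crests])
    local = frame.to_local(all_pts)
    ellipse, rms = fit_ellipse(local[:, :2])
    # re-parameterize arc angles about the fitted ellipse center
    # (CrestCurve contract: radians about the arch center, strictly monotone)
    for c in crests:
        xy = frame.to_local(c.points)[:, :2] - ellipse.center
        ang = np.unwrap(np.arctan2(xy[:, 1], xy[:, 0]))
        order = np.argsort(ang)
        keep_idx = _strictly_monotone(ang[order])
        c.points = c.points[order][keep_idx]
        c.arc_param = ang[order][keep_idx]
    crests.sort(key=lambda c: c.arc_param[0])
    gap_span = None
    if len(crests) == 2:
        c0, c1 = crests  # ordered by starting arc angle
        two_pi = 2 * np.pi
        gap_a = (c1.arc_param[0] - c0.arc_param[-1]) % two_pi  # end of c0 -> start of c1
        gap_b = (c0.arc_param[0] - c1.arc_param[-1]) % two_pi  # end of c1 -> start of c0
        if gap_a <= gap_b:
            gap_span = (float(c0.arc_param[-1]), float(c0.arc_param[-1] + gap_a))
        else:
            gap_span = (float(c1.arc_param[-1]), float(c1.arc_param[-1] + gap_b))
    return DetectionResult(
        frame=frame, crests=crests, ellipse=ellipse, rms_residual=rms, gap_span=gap_span
    )


def measure_gap_width(mesh: trimesh.Trimesh, detection: DetectionResult) -> float:
    """Shortest 3D distance across the cleft between the wall surfaces of the
    two segments near their gap-facing crest endpoints (the SA-SA' contract).

    Only vertices in the upper wall band (above half the median crest height)
    and within 8 mm of a gap endpoint are considered.
    """
    if detection.gap_span is None or len(detection.crests) < 2:
        raise DetectionError("no gap to measure")
    frame = detection.frame
    local = frame.to_local(mesh.vertices)
    span0 = detection.gap_span[0] % (2 * np.pi)
    # gap-facing endpoints: the crest endpoints adjacent to gap_span
    endpoints = []
    for c in detection.crests:
        ends = [c.points[0], c.points[-1]]
        angs = [c.arc_param[0] % (2 * np.pi), c.arc_param[-1] % (2 * np.pi)]
        d = [min(abs(a - span0), 2 * np.pi - abs(a - span0)) for a in angs]
        span1 = detection.gap_span[1] % (2 * np.pi)
        d = [
            min(di, min(abs(a - span1), 2 * np.pi - abs(a - span1)))
            for di, a in zip(d, angs)
        ]
        endpoints.append(ends[int(np.argmin(d))])
    e0, e1 = (frame.to_local(np.asarray(e)).ravel() for e in endpoints)
    crest_h = np.median(np.concatenate([frame.to_local(c.points)[:, 2] for c in detection.crests]))
    wall = local[:, 2] >= 0.5 * crest_h
    pts = local[wall]
    d0 = np.linalg.norm(pts - e0, axis=1)
    d1 = np.linalg.norm(pts - e1, axis=1)
    side0 = pts[(d0 <= 8.0) & (d0 < d1)]
    side1 = pts[(d1 <= 8.0) & (d1 <= d0)]
    if len(side0) == 0 or len(side1) == 0:
        raise DetectionError("no wall vertices near the gap endpoints")
    tree = cKDTree(side1)
    dmin, _ = tree.query(side0)
    return float(np.min(dmin))
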