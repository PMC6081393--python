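"""Parametric synthetic neonatal cleft-maxilla generator with ground truth.

The model emulates a digitized plaster cast of a newborn maxilla with a
unilateral cleft lip and palate: the alveolar ridge is a rounded wall swept
along a planar elliptic arc (the arch form), interrupted over the cleft; a
depressed palatal vault closes the interior, with a wedge-shaped palatal
channel representing the posterior hard-palate cleft; a flat pedestal mimics
the cast base. The surface is extracted from an analytic implicit field by
marching cubes, so every anatomical feature has exact ground truth: the ten
measuring landmarks, the arch ellipse, and the crest polylines per segment.

Default dimensions are calibrated so the seven-distance table of the default
anatomy falls inside the printed ranges of neonatal unilateral-cleft cohorts
(arch length ~28 mm, tuberal width ~34 mm, cleft width ~10 mm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from ._geometry import SurfaceQuery
from ._voxel import Grid
from .exceptions import ParameterError
from .morphometrics import LandmarkSet
from .ridge_detection import EllipseParams

# fixed model constants (not exposed as parameters to keep the surface small)
BLEND_RADIUS = 1.0  # mm fillet at implicit-solid junctions (mucosa has no sharp creases)
PHI_MAX_DEG = 110.0  # arc half-extent: posterior ends = tubera
BASE_THICKNESS = 3.0  # mm, cast pedestal
RHO_CHANNEL = 0.45  # palatal channel starts at this elliptic radius
RHO_SD = 0.8  # elliptic radius of the posterior cleft landmarks SD/SD'
RHO_P = 0.8  # elliptic radius of the papilla incisiva on the midline
ARC_END_MARGIN_DEG = 5.0  # cleft must stay this far from the arch ends


@dataclass
class AnatomyParams:
    """Parameters of one synthetic cleft maxilla (all lengths in mm)."""

    ellipse_a: float = 20.7  # anterior-posterior semi-axis
    ellipse_b: float = 18.3  # transversal semi-axis
    ridge_height: float = 4.0  # crest wall height above the occlusal base plane
    ridge_halfwidth: float = 2.5  # alveolar ridge half-thickness
    cleft_width: float = 10.0  # target SA-SA' gap
    cleft_angle: float = 25.0  # degrees from anterior midline, + = patient's left
    segment_shift: tuple[float, float, float] = (1.0, 0.0, 0.5)  # smaller-segment offset
    palate_depth: float = 5.0  # vault depression below the ridge shoulder
    resolution: float = 0.5  # target edge length / sampling pitch
    noise_sigma: float = 0.05  # Gaussian vertex jitter along normals
    seed: int = 0

    def validate(self) -> None:
        for name in ("ellipse_a", "ellipse_b", "ridge_height", "ridge_halfwidth", "resolution"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.cleft_width < 0:
            raise ParameterError("cleft_width must be >= 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.palate_depth < 0:
            raise ParameterError("palate_depth must be >= 0")


@dataclass
class GroundTruth:
    """Known-by-construction features of a generated maxilla."""

    landmarks: LandmarkSet
    ellipse: EllipseParams
    crest: dict[str, np.ndarray]  # segment label -> (n, 3) polyline on the surface
    occlusal_normal: np.ndarray


@dataclass
class CohortParams:
    """Sampling distributions for a paired (pre/post molding) cohort.

    Each entry of ``param_dists`` is (mean, sd, lower, upper) for a truncated
    normal; unlisted AnatomyParams fields come from ``base``. The second
    impression applies a per-subject multiplicative arch growth and a cleft
    reduction (mm). ``landmark_sigma`` emulates observer landmark-placement
    error on the emitted measured landmark sets.
    """

    n_subjects: int = 7
    param_dists: dict = field(
        default_factory=lambda: {
            "ellipse_a": (20.7, 1.8, 17.0, 25.5),
            "ellipse_b": (18.3, 1.2, 15.5, 21.5),
            "cleft_width": (11.4, 5.0, 4.5, 19.5),
        }
    )
    growth_factor: tuple[float, float] = (1.07, 0.02)  # per-subject multiplicative change
    cleft_reduction: tuple[float, float] = (6.4, 1.5)  # mm removed from cleft width
    landmark_sigma: float = 0.3  # mm observer error on measured landmarks
    base: AnatomyParams = field(default_factory=AnatomyParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        for name, spec in self.param_dists.items():
            if not hasattr(self.base, name):
                raise ParameterError(f"unknown parameter {name!r} in param_dists")
            mean, sd, lo, hi = spec
            if sd < 0 or lo > hi:
                raise ParameterError(f"bad distribution for {name!r}")


@dataclass
class CohortSubject:
    index: int
    pre_mesh: trimesh.Trimesh
    post_mesh: trimesh.Trimesh
    truth_pre: GroundTruth
    truth_post: GroundTruth
    measured_pre: LandmarkSet  # ground truth + observer jitter
    measured_post: LandmarkSet
    params_pre: AnatomyParams
    params_post: AnatomyParams


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _spine_xy(a: float, b: float, phi: np.ndarray) -> np.ndarray:
    """Arch centerline point(s): x = b sin(phi), y = a cos(phi)."""
    phi = np.asarray(phi, dtype=float)
    return np.stack([b * np.sin(phi), a * np.cos(phi)], axis=-1)


def _solve_gap_halfangle(p: AnatomyParams) -> float:
    """Gap half-angle gamma such that the horizontal distance between the two
    wall margins (spine endpoints, smaller one shifted) equals
    cleft_width + 2*ridge_halfwidth, i.e. the surface gap equals cleft_width."""
    phic = np.radians(p.cleft_angle)
    phimax = np.radians(PHI_MAX_DEG)
    margin = np.radians(ARC_END_MARGIN_DEG)
    shift = np.asarray(p.segment_shift, dtype=float)
    target = p.cleft_width + 2 * p.ridge_halfwidth

    def f(gamma):
        p1 = _spine_xy(p.ellipse_a, p.ellipse_b, phic - gamma)
        p2 = _spine_xy(p.ellipse_a, p.ellipse_b, phic + gamma) + shift[:2]
        return np.linalg.norm(p2 - p1) - target

    hi = min(phimax + phic, phimax - phic) - margin
    if hi <= 1e-6 or f(hi) < 0:
        raise ParameterError(
            f"cleft span (width {p.cleft_width} mm at {p.cleft_angle} deg) exceeds the arch extent"
        )
    lo = 1e-6
    if f(lo) >= 0:
        # even a zero-width spine gap exceeds the target (large shift): keep minimal
        return lo
    return float(brentq(f, lo, hi, xtol=1e-12))


def _smooth_min(a: np.ndarray, b: np.ndarray, k: float = BLEND_RADIUS) -> np.ndarray:
    """Polynomial smooth union of two implicit fields (fillet radius ~k)."""
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


def _smooth_max(a: np.ndarray, b: np.ndarray, k: float = BLEND_RADIUS) -> np.ndarray:
    """Polynomial smooth intersection (used for the channel subtraction)."""
    return -_smooth_min(-a, -b, k)


def _vault_height(p: AnatomyParams, rho2: np.ndarray) -> np.ndarray:
    """Vault top surface height: ridge shoulder at the rim, depressed by
    palate_depth at the center."""
    return p.ridge_height - p.palate_depth * np.clip(1.0 - rho2, 0.0, None)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_cleft_maxilla(params: AnatomyParams) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Generate a watertight synthetic cleft maxilla and its ground truth.

    Deterministic given ``params.seed``.
    """
    p = params
    p.validate()
    a, b = p.ellipse_a, p.ellipse_b
    h, w = p.ridge_height, p.ridge_halfwidth
    phimax = np.radians(PHI_MAX_DEG)
    phic = np.radians(p.cleft_angle)
    shift = np.asarray(p.segment_shift, dtype=float)
    has_cleft = p.cleft_width > 0

    if has_cleft:
        gamma = _solve_gap_halfangle(p)
        phi1, phi2 = phic - gamma, phic + gamma
        r_c = float(np.linalg.norm(_spine_xy(a, b, phic)))
        gamma_ch = float(np.arcsin(min(0.95, (p.cleft_width + w) / r_c)))
    else:
        phi1 = phi2 = phic
        gamma_ch = 0.0

    # spine polylines (greater = contains the anterior midline side opposite
    # the cleft; with cleft_angle > 0 the greater segment is phi < phi1)
    step = p.resolution / (2.0 * max(a, b))

    def _arc(lo, hi):
        n = max(2, int(np.ceil((hi - lo) / step)) + 1)
        return np.linspace(lo, hi, n)  # exact endpoints: margins sit at phi1/phi2

    phi_g = _arc(-phimax, phi1) if has_cleft else _arc(-phimax, phimax)
    spine_g = _spine_xy(a, b, phi_g)
    if has_cleft:
        phi_s = _arc(phi2, phimax)
        spine_s = _spine_xy(a, b, phi_s) + shift[:2]
        z_s = (shift[2], h + shift[2])
    else:
        phi_s = np.empty(0)
        spine_s = np.empty((0, 2))
        z_s = (0.0, h)

    y_cut = a * np.cos(phimax) - w - 2.0
    base_bx, base_ay = b + w + 1.0, a + w + 1.0
    smin = min(a, b)

    bounds = np.array(
        [
            [-base_bx - 1.0, y_cut - 1.0, -BASE_THICKNESS - 1.0],
            [base_bx + 1.0, base_ay + 1.0, h + w + 1.0],
        ]
    )
    grid = Grid.from_bounds(bounds, p.resolution, pad=3)
    nx, ny, nz = grid.shape
    xs = grid.origin[0] + np.arange(nx) * grid.pitch
    ys = grid.origin[1] + np.arange(ny) * grid.pitch
    zs = grid.origin[2] + np.arange(nz) * grid.pitch
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    cols = np.stack([X.ravel(), Y.ravel()], axis=1)

    # wall capsules: sqrt(d_xy^2 + dz^2) - halfwidth
    def wall_field(spine: np.ndarray, z_lo: float, z_hi: float) -> np.ndarray:
        if len(spine) == 0:
            return np.full((nx, ny, nz), np.inf)
        tree = cKDTree(spine)
        dxy = tree.query(cols)[0].reshape(nx, ny)
        dz = np.maximum.reduce([z_lo - zs, zs - z_hi, np.zeros_like(zs)])
        return np.sqrt(dxy[:, :, None] ** 2 + dz[None, None, :] ** 2) - w

    phi_wall = np.minimum(wall_field(spine_g, 0.0, h), wall_field(spine_s, *z_s))

    rho2 = (X / b) ** 2 + (Y / a) ** 2
    rho = np.sqrt(rho2)
    hv = _vault_height(p, rho2)
    Z = zs[None, None, :]
    vault = np.maximum.reduce(
        [
            Z - hv[:, :, None],
            -(Z + BASE_THICKNESS) * np.ones_like(hv)[:, :, None],
            ((rho - 1.0) * smin)[:, :, None] * np.ones_like(zs)[None, None, :],
            (y_cut - Y)[:, :, None] * np.ones_like(zs)[None, None, :],
        ]
    )
    if has_cleft:
        ang = np.arctan2(X / b, Y / a)  # elliptic angle of each column
        chan2d = np.maximum((np.abs(ang - phic) - gamma_ch) * smin, (RHO_CHANNEL - rho) * smin)
        vault = _smooth_max(vault, -chan2d[:, :, None] * np.ones_like(zs)[None, None, :])

    rho_out = np.sqrt((X / base_bx) ** 2 + (Y / base_ay) ** 2)
    base = np.maximum.reduce(
        [
            -(Z + BASE_THICKNESS) * np.ones_like(hv)[:, :, None],
            Z * np.ones_like(hv)[:, :, None],
            ((rho_out - 1.0) * smin)[:, :, None] * np.ones_like(zs)[None, None, :],
            (y_cut - Y)[:, :, None] * np.ones_like(zs)[None, None, :],
        ]
    )

    phi_field = _smooth_min(_smooth_min(phi_wall, vault), base)
    mesh = grid.mesh_from_field(phi_field.astype(np.float32))

    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        normals = mesh.vertex_normals.view(np.ndarray)
        mesh = trimesh.Trimesh(
            mesh.vertices + normals * rng.normal(0.0, p.noise_sigma, (len(mesh.vertices), 1)),
            mesh.faces,
            process=False,
        )
    mesh.metadata["name"] = f"synthetic_maxilla_seed{p.seed}"

    truth = _ground_truth(p, mesh, phi1, phi2, gamma_ch, phi_g, phi_s, spine_g, spine_s, z_s)
    return mesh, truth


def _crest_point(p: AnatomyParams, phi: float, shifted: bool) -> np.ndarray:
    xy = _spine_xy(p.ellipse_a, p.ellipse_b, phi)
    pt = np.array([xy[0], xy[1], p.ridge_height + p.ridge_halfwidth])
    if shifted:
        pt = pt + np.asarray(p.segment_shift, dtype=float)
    return pt


def _ground_truth(
    p: AnatomyParams,
    mesh: trimesh.Trimesh,
    phi1: float,
    phi2: float,
    gamma_ch: float,
    phi_g: np.ndarray,
    phi_s: np.ndarray,
    spine_g: np.ndarray,
    spine_s: np.ndarray,
    z_s: tuple[float, float],
) -> GroundTruth:
    a, b, h, w = p.ellipse_a, p.ellipse_b, p.ridge_height, p.ridge_halfwidth
    phic = np.radians(p.cleft_angle)
    has_cleft = p.cleft_width > 0
    shift = np.asarray(p.segment_shift, dtype=float)

    if has_cleft:
        m1 = np.array([*spine_g[-1], 0.0])  # greater margin wall axis base
        m2 = np.array([*spine_s[0], z_s[0]])
        u_xy = (m2[:2] - m1[:2]) / np.linalg.norm(m2[:2] - m1[:2])
        z_star = 0.5 * (max(0.0, z_s[0]) + min(h, z_s[1]))
        SA = np.array([*(m1[:2] + w * u_xy), z_star])
        SAp = np.array([*(m2[:2] - w * u_xy), z_star])
    else:
        SA = SAp = _crest_point(p, phic, shifted=False)

    phi_A = float(np.clip(0.0, -np.radians(PHI_MAX_DEG), phi1)) if has_cleft else 0.0
    A = _crest_point(p, phi_A, shifted=False)
    rho2_P = RHO_P**2
    P = np.array([0.0, RHO_P * a, float(_vault_height(p, np.array(rho2_P)))])
    phi_L = np.radians(60.0)
    L = _crest_point(p, -phi_L, shifted=False)
    Lp = _crest_point(p, phi_L, shifted=has_cleft and phi_L >= phi2)
    T = _crest_point(p, -np.radians(PHI_MAX_DEG), shifted=False)
    Tp = _crest_point(p, np.radians(PHI_MAX_DEG), shifted=has_cleft)

    def vault_point(phi):
        xy = RHO_SD * _spine_xy(a, b, phi)
        rho2 = (xy[0] / b) ** 2 + (xy[1] / a) ** 2
        return np.array([xy[0], xy[1], float(_vault_height(p, np.array(rho2)))])

    if has_cleft:
        SD = vault_point(phic - gamma_ch)
        SDp = vault_point(phic + gamma_ch)
    else:
        SD = SDp = vault_point(phic)

    landmarks = LandmarkSet(A=A, P=P, SA=SA, SAp=SAp, L=L, Lp=Lp, T=T, Tp=Tp, SD=SD, SDp=SDp)

    if a >= b:
        ellipse = EllipseParams(center=np.zeros(2), a=a, b=b, theta=np.pi / 2)
    else:
        ellipse = EllipseParams(center=np.zeros(2), a=b, b=a, theta=0.0)

    # analytic crest polylines, projected onto the emitted surface
    query = SurfaceQuery.from_mesh(mesh)
    crest: dict[str, np.ndarray] = {}
    coarse = max(1, int(round(np.radians(1.0) / (phi_g[1] - phi_g[0]))))
    crest_g = np.column_stack([spine_g[::coarse], np.full(len(spine_g[::coarse]), h + w)])
    crest["greater"] = query.query(crest_g)[0]
    if len(spine_s):
        crest_s = np.column_stack([spine_s[::coarse], np.full(len(spine_s[::coarse]), h + w + shift[2])])
        crest["smaller"] = query.query(crest_s)[0]

    return GroundTruth(
        landmarks=landmarks,
        ellipse=ellipse,
        crest=crest,
        occlusal_normal=np.array([0.0, 0.0, 1.0]),
    )


# ---------------------------------------------------------------------------
# growth and cohorts
# ---------------------------------------------------------------------------


def grow_anatomy(
    params: AnatomyParams,
    months: float,
    g: float,
    new_cleft_width: float | None = None,
) -> AnatomyParams:
    """Apply the monthly relative growth factor: ellipse axes scale by
    (1+g)^months; cleft_width follows the supplied closure value if given."""
    if months < 0:
        raise ParameterError("months must be >= 0")
    if g <= -1:
        raise ParameterError("growth fraction must be > -1")
    factor = (1.0 + g) ** months
    return dataclasses.replace(
        params,
        ellipse_a=params.ellipse_a * factor,
        ellipse_b=params.ellipse_b * factor,
        cleft_width=params.cleft_width if new_cleft_width is None else new_cleft_width,
    )


def _truncnorm_rvs(mean, sd, lo, hi, rng):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_cohort_params(cohort: CohortParams) -> list[tuple[AnatomyParams, AnatomyParams]]:
    """Draw the per-subject (pre, post) anatomy parameters (no meshes)."""
    cohort.validate()
    out = []
    for i in range(cohort.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence((cohort.seed, i)))
        subject_seed = int(rng.integers(0, 2**31 - 1))
        drawn = {
            name: _truncnorm_rvs(*spec, rng) for name, spec in cohort.param_dists.items()
        }
        pre = dataclasses.replace(cohort.base, seed=subject_seed, **drawn)
        gf_mean, gf_sd = cohort.growth_factor
        factor = max(0.8, gf_mean if gf_sd == 0 else rng.normal(gf_mean, gf_sd))
        red_mean, red_sd = cohort.cleft_reduction
        reduction = max(0.0, red_mean if red_sd == 0 else rng.normal(red_mean, red_sd))
        post = dataclasses.replace(
            pre,
            ellipse_a=pre.ellipse_a * factor,
            ellipse_b=pre.ellipse_b * factor,
            cleft_width=max(0.0, pre.cleft_width - reduction),
            seed=subject_seed + 1,
        )
        out.append((pre, post))
    return out


def generate_cohort(cohort: CohortParams) -> list[CohortSubject]:
    """Generate paired pre/post meshes with ground truth and jittered
    "measured" landmark sets for every subject. Reproducible by seed."""
    pairs = sample_cohort_params(cohort)
    subjects = []
    for i, (pre_p, post_p) in enumerate(pairs):
        pre_mesh, truth_pre = generate_cleft_maxilla(pre_p)
        post_mesh, truth_post = generate_cleft_maxilla(post_p)
        jit_rng = np.random.default_rng(np.random.SeedSequence((cohort.seed, i, 7919)))

        def jitter(lm: LandmarkSet) -> LandmarkSet:
            if cohort.landmark_sigma == 0:
                return lm
            return LandmarkSet(
                **{
                    rec.name: rec.position + jit_rng.normal(0.0, cohort.landmark_sigma, 3)
                    for rec in lm.to_records()
                }
            )

        subjects.append(
            CohortSubject(
                index=i,
                pre_mesh=pre_mesh,
                post_mesh=post_mesh,
                truth_pre=truth_pre,
                truth_post=truth_post,
                measured_pre=jitter(truth_pre.landmarks),
                measured_post=jitter(truth_post.landmarks),
                params_pre=pre_p,
                params_post=post_p,
            )
        )
    return subjects
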