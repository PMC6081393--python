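"""Landmark morphometrics of neonatal maxillary casts and the paired
statistics used to evaluate molding therapy.

Ten stored landmarks (A, P, SA, SA', L, L', T, T', SD, SD'; primed names use
an ASCII ``p`` suffix) define seven inter-landmark distances; MT, the
midpoint of the tuberal connecting line T–T', is always derived. Cohort
columns are summarized as min / 1st quartile / median / mean / 3rd quartile /
max / SD, and paired pre/post changes are tested with the Wilcoxon
signed-rank test (exact by sign-flip enumeration for small n) and an exact
rank-sum test for between-group comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields

import numpy as np
from scipy import stats as sps

from .exceptions import LandmarkError, StatsError
from .mesh_io import LANDMARK_NAMES, LandmarkFileRecord

#: The seven measured distances, as (attribute, endpoint-pair label).
DISTANCE_LABELS = (
    ("d_A_MT", "A - MT"),
    ("d_L_Lp", "L - L'"),
    ("d_SA_SAp", "SA - SA'"),
    ("d_T_Tp", "T - T'"),
    ("d_SD_SDp", "SD - SD'"),
    ("d_A_P", "A - P"),
    ("d_SA_SD", "SA - SD"),
)


@dataclass
class LandmarkSet:
    """The ten stored anatomical points (mm); MT is derived, never stored."""

    A: np.ndarray
    P: np.ndarray
    SA: np.ndarray
    SAp: np.ndarray
    L: np.ndarray
    Lp: np.ndarray
    T: np.ndarray
    Tp: np.ndarray
    SD: np.ndarray
    SDp: np.ndarray

    def __post_init__(self):
        for f in fields(self):
            setattr(self, f.name, np.asarray(getattr(self, f.name), dtype=float))

    @property
    def MT(self) -> np.ndarray:
        """Midpoint of the T–T' connecting line (derived)."""
        return 0.5 * (self.T + self.Tp)

    @classmethod
    def from_records(cls, records: list[LandmarkFileRecord]) -> "LandmarkSet":
        by_name = {rec.name: rec.position for rec in records}
        missing = [n for n in LANDMARK_NAMES if n not in by_name]
        if missing:
            raise LandmarkError(f"missing landmark(s): {', '.join(missing)}")
        return cls(**{n: by_name[n] for n in LANDMARK_NAMES})

    def to_records(self) -> list[LandmarkFileRecord]:
        return [LandmarkFileRecord(n, getattr(self, n)) for n in LANDMARK_NAMES]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(
            **{n: rotation @ getattr(self, n) + translation for n in LANDMARK_NAMES}
        )


@dataclass
class DistanceTable:
    """The seven inter-landmark distances (mm)."""

    d_A_MT: float
    d_L_Lp: float
    d_SA_SAp: float
    d_T_Tp: float
    d_SD_SDp: float
    d_A_P: float
    d_SA_SD: float

    def as_dict(self, labels: bool = False) -> dict[str, float]:
        if labels:
            return {label: getattr(self, attr) for attr, label in DISTANCE_LABELS}
        return {attr: getattr(self, attr) for attr, _ in DISTANCE_LABELS}


@dataclass
class SummaryRow:
    """Seven-column cohort summary (mm): min, q1, median, mean, q3, max, sd."""

    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    sd: float

    def rounded(self, decimals: int = 1) -> "SummaryRow":
        """Presentation rounding (tables print one decimal)."""
        return SummaryRow(*(round(getattr(self, f.name), decimals) for f in fields(self)))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class PairedTestResult:
    n: int  # pairs used (after zero handling)
    W: float  # signed-rank statistic (sum of positive-difference ranks)
    p_exact: float | None
    p_asymptotic: float
    method_note: str


def compute_distances(lm: LandmarkSet) -> DistanceTable:
    """Euclidean 3D distances for the seven measured pairs; MT derived first."""

    def d(p, q):
        return float(np.linalg.norm(p - q))

    mt = lm.MT
    return DistanceTable(
        d_A_MT=d(lm.A, mt),
        d_L_Lp=d(lm.L, lm.Lp),
        d_SA_SAp=d(lm.SA, lm.SAp),
        d_T_Tp=d(lm.T, lm.Tp),
        d_SD_SDp=d(lm.SD, lm.SDp),
        d_A_P=d(lm.A, lm.P),
        d_SA_SD=d(lm.SA, lm.SD),
    )


def summarize(values) -> SummaryRow:
    """Seven-column summary; quartiles by linear interpolation of order
    statistics (type-7), sd with n-1 denominator (0 for a single value)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise StatsError("cannot summarize an empty list")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # numpy default = type-7
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return SummaryRow(
        min=float(vals.min()),
        q1=float(q1),
        median=float(med),
        mean=float(vals.mean()),
        q3=float(q3),
        max=float(vals.max()),
        sd=sd,
    )


def paired_change(pre, post) -> tuple[np.ndarray, SummaryRow]:
    """Elementwise post - pre differences and their summary row."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise StatsError(f"length mismatch: {pre.shape} vs {post.shape}")
    diff = post - pre
    return diff, summarize(diff)


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

_EXACT_SIGNED_RANK_MAX_N = 25
_EXACT_RANK_SUM_MAX_N = 20


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p over all 2^n sign assignments of the ranks,
    computed by dynamic programming on the doubled (integer) ranks —
    identical to literal enumeration because W depends only on which ranks
    get a positive sign."""
    m = np.round(2 * ranks).astype(np.int64)  # midranks are multiples of 0.5
    total = int(m.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for mi in m:
        shifted = np.zeros_like(counts)
        shifted[mi:] = counts[: total + 1 - mi]
        counts = counts + shifted
    e2 = total / 2.0  # E[2W] under the null
    dev = abs(2 * w_obs - e2)
    support = np.arange(total + 1)
    mask = np.abs(support - e2) >= dev - 1e-9
    return float(counts[mask].sum() / 2.0 ** len(m))


def wilcoxon_signed_rank(pre, post, mode: str = "exact", zero_method: str = "wilcox") -> PairedTestResult:
    """Paired Wilcoxon signed-rank test of post vs pre.

    mode: "exact" (sign-flip enumeration, n <= 25) or "asymptotic" (normal
    approximation with tie-corrected variance and continuity correction);
    the asymptotic p is always reported alongside.
    zero_method: "wilcox" drops zero differences (classical), "pratt" ranks
    them but drops their contribution.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise StatsError(f"length mismatch: {pre.shape} vs {post.shape}")
    if mode not in ("exact", "asymptotic"):
        raise StatsError(f"unknown mode {mode!r}")
    diff = post - pre
    n_zero = int(np.sum(diff == 0))
    if zero_method == "wilcox":
        diff_used = diff[diff != 0]
        ranks_all = _midranks(np.abs(diff_used))
        signs = diff_used > 0
    elif zero_method == "pratt":
        ranks_full = _midranks(np.abs(diff))
        nonzero = diff != 0
        ranks_all = ranks_full[nonzero]
        signs = diff[nonzero] > 0
    else:
        raise StatsError(f"unknown zero_method {zero_method!r}")
    n = len(ranks_all)
    if n == 0:
        raise StatsError("all paired differences are zero; test is degenerate")
    w_obs = float(ranks_all[signs].sum())
    note = f"zero_method={zero_method}, {n_zero} zero difference(s) of {len(diff)} pairs"

    # asymptotic: E[W] = S/2, Var[W] = sum r_i^2 / 4 (midranks absorb ties)
    mean_w = ranks_all.sum() / 2.0
    var_w = float(np.sum(ranks_all**2)) / 4.0
    if var_w == 0:
        p_asym = 1.0
    else:
        z = max(abs(w_obs - mean_w) - 0.5, 0.0) / np.sqrt(var_w)
        p_asym = min(1.0, 2.0 * float(sps.norm.sf(z)))

    p_exact = None
    if mode == "exact":
        if n > _EXACT_SIGNED_RANK_MAX_N:
            raise StatsError(
                f"exact mode limited to n <= {_EXACT_SIGNED_RANK_MAX_N} nonzero pairs (got {n})"
            )
        p_exact = _signed_rank_exact_p(ranks_all, w_obs)
    return PairedTestResult(n=n, W=w_obs, p_exact=p_exact, p_asymptotic=p_asym, method_note=note)


@dataclass
class RankSumResult:
    n1: int
    n2: int
    W: float  # rank-sum of group 1 (midranks)
    p_exact: float
    method_note: str


def wilcoxon_rank_sum_exact(group1, group2) -> RankSumResult:
    """Exact two-sided Wilcoxon rank-sum test by enumeration of all
    C(n1+n2, n1) assignments of the combined (mid)ranks to group 1."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise StatsError("both groups must be non-empty")
    n1, n2 = g1.size, g2.size
    if n1 + n2 > _EXACT_RANK_SUM_MAX_N:
        raise StatsError(
            f"exact rank-sum limited to combined n <= {_EXACT_RANK_SUM_MAX_N} (got {n1 + n2})"
        )
    combined = np.concatenate([g1, g2])
    ranks = _midranks(combined)
    w_obs = float(ranks[:n1].sum())
    e_w = n1 * ranks.mean()
    dev = abs(w_obs - e_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - e_w) >= dev - 1e-9:
            count += 1
    return RankSumResult(
        n1=n1,
        n2=n2,
        W=w_obs,
        p_exact=count / total,
        method_note=f"enumerated all {total} rank assignments",
    )


# ---------------------------------------------------------------------------
# box-plot statistics
# ---------------------------------------------------------------------------


def boxplot_stats(values) -> dict:
    """Five-number summary with Tukey whiskers (most extreme data within
    1.5 IQR of the box) and listed outliers; JSON-ready dict. The box spans
    the 1st to 3rd quartile with the median bar inside."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise StatsError("cannot compute box-plot statistics of an empty list")
    row = summarize(vals)
    iqr = row.q3 - row.q1
    lo_fence = row.q1 - 1.5 * iqr
    hi_fence = row.q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return {
        "min": row.min,
        "q1": row.q1,
        "median": row.median,
        "mean": row.mean,
        "q3": row.q3,
        "max": row.max,
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": sorted(float(v) for v in outliers),
    }
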