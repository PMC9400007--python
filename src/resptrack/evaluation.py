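"""Trajectory comparison (DTW) and the group-testing workflow.

Free-breathing rate series from different recordings cannot be compared
point-by-point (breaths are not synchronized), so similarity is measured by
dynamic time warping with absolute-difference local cost.  The
:func:`dtw_distance` here is the radius-constrained multiresolution
approximation (recursively coarsen by 2, solve, project the warp path up and
refine within a radius; radius defaults to 2), which is linear-time and
closely tracks the exact quadratic dynamic program.

Group comparisons follow the workflow: Levene's test (median-centered) for
equality of variances, the Kruskal–Wallis H test for equality of medians,
and Dunn's rank-based post-hoc z tests to localize which groups differ.
Dunn's test is implemented directly (mean-rank differences with tie
correction); p-values are unadjusted by default with an optional Holm
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import RateSeries

__all__ = [
    "DistanceMatrixSummary",
    "GroupTestReport",
    "dtw_distance",
    "cohort_dtw_summary",
    "run_group_tests",
]


# ---------------------------------------------------------------------------
# dynamic time warping

def _as_series(x) -> np.ndarray:
    if isinstance(x, RateSeries):
        x = x.rates
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("DTW input series must be non-empty")
    return arr


def _dtw_windowed(a: np.ndarray, b: np.ndarray, window: list[tuple[int, int]] | None):
    """Exact DTW restricted to ``window`` (all cells when None).

    Returns (distance, path); local cost |a_i - b_j|, full-sequence
    alignment with the standard (up / left / diagonal) recursion.
    """
    n, m = a.size, b.size
    if window is None:
        window = [(i, j) for i in range(n) for j in range(m)]
    D: dict[tuple[int, int], float] = {(-1, -1): 0.0}
    for i, j in window:
        cost = abs(a[i] - b[j])
        best = min(
            D.get((i - 1, j), np.inf),
            D.get((i, j - 1), np.inf),
            D.get((i - 1, j - 1), np.inf),
        )
        D[(i, j)] = cost + best
    if (n - 1, m - 1) not in D or not np.isfinite(D[(n - 1, m - 1)]):
        raise RuntimeError("DTW window does not connect the sequence ends")
    # backtrack
    path = []
    i, j = n - 1, m - 1
    while (i, j) != (-1, -1):
        path.append((i, j))
        steps = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        vals = [D.get(s, np.inf) for s in steps]
        if all(not np.isfinite(v) for v in vals):
            break
        i, j = steps[int(np.argmin(vals))]
    path.reverse()
    if path and path[0] == (-1, -1):
        path = path[1:]
    return D[(n - 1, m - 1)], path

def _halve(x: np.ndarray) -> np.ndarray:
    n = x.size // 2
    out = (x[: 2 * n : 2] + x[1 : 2 * n : 2]) / 2.0
    if x.size % 2:
        out = np.concatenate([out, x[-1:]])
    return out


def _expand_window(path, n: int, m: int, radius: int) -> list[tuple[int, int]]:
    """Project a coarse warp path to the finer grid and dilate by ``radius``."""
    cells = set()
    for i, j in path:
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                cells.add((i + di, j + dj))
    fine = set()
    for i, j in cells:
        for fi in (2 * i, 2 * i + 1):
            for fj in (2 * j, 2 * j + 1):
                if 0 <= fi < n and 0 <= fj < m:
                    fine.add((fi, fj))
    return sorted(fine)


def _fastdtw(a: np.ndarray, b: np.ndarray, radius: int):
    min_size = radius + 2
    if a.size <= min_size or b.size <= min_size:
        return _dtw_windowed(a, b, None)
    _, coarse_path = _fastdtw(_halve(a), _halve(b), radius)
    window = _expand_window(coarse_path, a.size, b.size, radius)
    return _dtw_windowed(a, b, window)


def dtw_distance(a, b, radius: int = 2) -> float:
    """Approximate DTW distance between two rate series (or arrays).

    Absolute-difference local cost, full-sequence alignment; identical
    series give 0.  ``radius`` controls the refinement corridor of the
    multiresolution approximation.
    """
    return float(_fastdtw(_as_series(a), _as_series(b), radius)[0])


# ---------------------------------------------------------------------------
# cohort DTW structure

@dataclass(frozen=True)
class DistanceMatrixSummary:
    """DTW distances for one comparison group."""

    comparison_type: str  # {belt_to_radar_same_subject, belt_to_belt_cross, radar_to_radar_cross}
    distances: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    @property
    def n(self) -> int:
        return int(self.distances.size)


def cohort_dtw_summary(
    belt_series: list, radar_series: list, radius: int = 2
) -> dict[str, DistanceMatrixSummary]:
    """The three comparison groups of a paired-device cohort.

    ``belt_series[i]`` and ``radar_series[i]`` must belong to the same
    subject.  Same-subject cross-device comparisons use each subject once
    (n distances for n subjects); cross-subject within-device comparisons
    use all ordered pairs i != j (n*(n-1) distances).
    """
    if len(belt_series) != len(radar_series):
        raise ValueError("belt and radar series lists must be subject-aligned")
    n = len(belt_series)
    if n < 2:
        raise ValueError("need at least two subjects")
    same = np.array(
        [dtw_distance(belt_series[i], radar_series[i], radius) for i in range(n)]
    )

    def _cross(series):
        out = []
        cache: dict[tuple[int, int], float] = {}
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                key = (min(i, j), max(i, j))
                if key not in cache:
                    cache[key] = dtw_distance(series[key[0]], series[key[1]], radius)
                out.append(cache[key])
        return np.asarray(out)

    return {
        "belt_to_radar_same_subject": DistanceMatrixSummary(
            "belt_to_radar_same_subject", same
        ),
        "belt_to_belt_cross": DistanceMatrixSummary(
            "belt_to_belt_cross", _cross(belt_series)
        ),
        "radar_to_radar_cross": DistanceMatrixSummary(
            "radar_to_radar_cross", _cross(radar_series)
        ),
    }


# ---------------------------------------------------------------------------
# Levene -> Kruskal-Wallis -> Dunn workflow

@dataclass
class GroupTestReport:
    levene_stat: float
    levene_p: float
    kw_stat: float
    kw_p: float
    dunn_p_matrix: pd.DataFrame
    summary: pd.DataFrame  # per-group median / IQR / SD
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        names = list(self.dunn_p_matrix.index)
        out = []
        for i, gi in enumerate(names):
            for gj in names[i + 1 :]:
                if self.dunn_p_matrix.loc[gi, gj] < self.alpha:
                    out.append((gi, gj))
        return out


def _dunn_posthoc(groups: dict[str, np.ndarray], p_adjust: str | None) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    N = pooled.size
    mean_ranks = {}
    pos = 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = ranks[pos : pos + k].mean()
        pos += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    pvals = []
    pairs = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / groups[gi].size + 1.0 / groups[gj].size))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            pvals.append(2.0 * stats.norm.sf(abs(z)))
            pairs.append((gi, gj))
    pvals = np.asarray(pvals)
    if p_adjust == "holm" and pvals.size:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="holm")[1]
    elif p_adjust not in (None, "holm"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (gi, gj), p in zip(pairs, pvals):
        mat.loc[gi, gj] = mat.loc[gj, gi] = p
    return mat


def run_group_tests(
    groups: dict[str, np.ndarray], alpha: float = 0.05, p_adjust: str | None = None
) -> GroupTestReport:
    """Levene (median-centered), Kruskal–Wallis and Dunn's post hoc on labeled groups.

    Also reports each group's median, IQR and SD.  Degenerate inputs (e.g. a
    zero-variance group) are reported, not raised; the rank tests remain
    defined as long as there are >= 2 groups of >= 2 values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float).ravel() for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least two values")
    values = list(arrays.values())
    with np.errstate(invalid="ignore"):  # zero-variance groups: report NaN, don't raise
        lev_stat, lev_p = stats.levene(*values, center="median")
    try:
        kw_stat, kw_p = stats.kruskal(*values)
    except ValueError:  # all values identical across every group
        kw_stat, kw_p = 0.0, 1.0
    dunn = _dunn_posthoc(arrays, p_adjust)
    summary = pd.DataFrame(
        {
            "median": {g: float(np.median(v)) for g, v in arrays.items()},
            "iqr": {g: float(stats.iqr(v)) for g, v in arrays.items()},
            "sd": {g: float(np.std(v, ddof=1)) for g, v in arrays.items()},
        }
    )
    return GroupTestReport(
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        kw_stat=float(kw_stat),
        kw_p=float(kw_p),
        dunn_p_matrix=dunn,
        summary=summary,
        alpha=alpha,
    )
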