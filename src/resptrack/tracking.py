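"""Fundamental-period trajectory tracking with octave-error elimination.

The estimator walks the maxima lattice in three heuristic stages:

1. *Naive Euclidean selection with a voting classifier.*  Per frame, the
   maximum closest (in normalized lag/amplitude coordinates) to the central
   peak is taken as the fundamental-period candidate; small spurious maxima
   between the central peak and the true one are naturally skipped because
   their low amplitude makes them distant on the y-axis.  A voting rule then
   flags isolated octave errors: a selection whose lag differs by a factor of
   1.8 or more from at least 3 of the 5 preceding selections is replaced by
   the current frame's maximum nearest the previous selection.
2. *k-means outlier repair.*  Each path point is described by four features
   (its lag, the lag distances to its left and right neighbours, and the
   implied fundamental frequency); 2-means on the standardized features
   splits the path into a majority cluster and a minority "outlier" cluster,
   and outliers are swept left-to-right onto the lattice maximum nearest the
   preceding (repaired) point's lag until the path is stable.
3. *Sub-path split and merge.*  The path is cut wherever a transition is not
   between nearest-neighbour maxima of adjacent frames; fragments are then
   re-joined left-to-right, each junction comparing the original continuation
   with an alternative built by nearest-neighbour hops and keeping whichever
   has the shorter cumulative length in normalized coordinates.

Chosen lags convert to breaths/min as 60 * rate / lag on the frame-center
time grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .lattice import MaximaLattice, build_lattice
from .signal_io import (
    COMMON_RATE,
    DEFAULT_FRAME_LENGTH,
    DEFAULT_OVERLAP,
    SampledSignal,
    frame_signal,
    resample_to_common_rate,
)

__all__ = [
    "TrackingConfig",
    "TrajectoryPath",
    "SubPath",
    "RateSeries",
    "TrackingError",
    "naive_maxima_selection",
    "voting_classifier_correction",
    "kmeans_classifier_correction",
    "split_into_subpaths",
    "merge_subpaths",
    "lags_to_rates",
    "estimate_breathing_rate",
]


class TrackingError(RuntimeError):
    """Raised when no usable trajectory can be extracted."""


@dataclass(frozen=True)
class TrackingConfig:
    """All tunable parameters of the estimation pipeline.

    Defaults are the study geometry: 4096-sample frames at 100 Sa/s with
    overlap 0.85, and the 1.8-fold / 3-of-5 voting rule.
    """

    frame_length: int = DEFAULT_FRAME_LENGTH
    overlap: float = DEFAULT_OVERLAP
    common_rate: float = COMMON_RATE
    voting_window: int = 5
    voting_votes: int = 3
    voting_ratio: float = 1.8
    #: Which lag jumps the voting rule flags: "up" (current >= ratio x prior),
    #: "down" (current <= prior / ratio) or "both".  Octave errors proper —
    #: readouts at twice the true rate — are lag-halving ("down") events, but
    #: the symmetric default also repairs lag-doubling glitches.
    voting_direction: str = "both"
    kmeans_restarts: int = 10
    kmeans_max_sweeps: int = 50
    seed: int = 0
    variant: str = "proposed"  # "proposed" (all stages) or "naive" (stage-1 selection only)

    def __post_init__(self) -> None:
        if self.variant not in ("proposed", "naive"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.voting_direction not in ("up", "down", "both"):
            raise ValueError(f"unknown voting_direction {self.voting_direction!r}")


@dataclass
class TrajectoryPath:
    """One chosen ACF maximum per frame.

    ``amps`` holds each point's ACF amplitude normalized by the frame's
    phi(0).  ``flags`` accumulates single-character stage markers per frame:
    ``F`` copied from the previous frame (no in-band maxima), ``V`` corrected
    by the voting classifier, ``K`` repaired by the k-means stage, ``M``
    rerouted by sub-path merging.
    """

    frames: np.ndarray
    lags: np.ndarray
    amps: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.lags = np.asarray(self.lags, dtype=int)
        self.amps = np.asarray(self.amps, dtype=float)
        if not self.flags:
            self.flags = [""] * self.frames.size
        if np.any(self.lags <= 0):
            raise ValueError("all path lags must be positive")

    def __len__(self) -> int:
        return self.frames.size

    def copy(self) -> "TrajectoryPath":
        return TrajectoryPath(
            self.frames.copy(), self.lags.copy(), self.amps.copy(), list(self.flags)
        )


@dataclass
class SubPath:
    """A contiguous run of trajectory points (consecutive frames)."""

    frames: np.ndarray
    lags: np.ndarray
    amps: np.ndarray
    flags: list[str]

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class RateSeries:
    """Breaths/min estimates on the frame time grid, with audit data."""

    times: np.ndarray
    rates: np.ndarray
    lags: np.ndarray
    flags: list[str]

    def __len__(self) -> int:
        return self.times.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "rate_bpm": self.rates,
                "lag_samples": self.lags,
                "stage_flags": self.flags,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# helpers

def _candidate_maxima(lattice: MaximaLattice, frame: int) -> np.ndarray:
    """In-band maxima of a frame, falling back to all maxima if none in band."""
    m = lattice.in_band_maxima(frame)
    if m.size == 0:
        m = lattice.maxima[frame]
    return m


def _nearest_max(lattice: MaximaLattice, frame: int, target_lag: float) -> int | None:
    """The frame's candidate maximum closest in lag to ``target_lag``."""
    m = _candidate_maxima(lattice, frame)
    if m.size == 0:
        return None
    return int(m[np.argmin(np.abs(m - target_lag))])


def _path_coords(
    frames: np.ndarray, lags: np.ndarray, amps: np.ndarray, lattice: MaximaLattice, n_total: int
) -> np.ndarray:
    """Points in normalized (frame, lag, amplitude) coordinates.

    Lag is scaled by the frame length N, amplitude by phi(0) (already done in
    ``amps``), and the frame axis — in hop units — by the trajectory length,
    so that no single axis dominates Euclidean comparisons.
    """
    denom = max(n_total - 1, 1)
    return np.column_stack(
        [frames / denom, lags / lattice.frame_length, amps]
    )


def _segment_length(points: np.ndarray) -> float:
    """Cumulative Euclidean length of a polyline."""
    if points.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# stage 1: naive Euclidean selection + voting classifier

def naive_maxima_selection(lattice: MaximaLattice) -> TrajectoryPath:
    """Choose, per frame, the maximum Euclidean-closest to the central peak.

    In normalized coordinates the central maximum sits at (0, 1); a candidate
    at lag tau contributes the point (tau / N, phi(tau) / phi(0)).  Frames
    with no in-band maxima copy the previous frame's point (flag ``F``); an
    empty first frame is a tracking failure.
    """
    n = lattice.n_frames
    frames = np.arange(n)
    lags = np.zeros(n, dtype=int)
    amps = np.zeros(n)
    flags = [""] * n
    any_selected = False
    for l in range(n):
        m = lattice.in_band_maxima(l)
        if m.size == 0:
            if l == 0:
                raise TrackingError(
                    "first frame has no autocorrelation maxima in the physiologic band"
                )
            lags[l] = lags[l - 1]
            amps[l] = lattice.normalized_amplitude(l, lags[l]) if lags[l] < lattice.frame_length else amps[l - 1]
            flags[l] = "F"
            continue
        c = lattice.central_value[l]
        amp = lattice.acf_values[l, m] / c if c != 0 else np.zeros(m.size)
        dist2 = (m / lattice.frame_length) ** 2 + (1.0 - amp) ** 2
        j = int(np.argmin(dist2))
        lags[l] = int(m[j])
        amps[l] = float(amp[j])
        any_selected = True
    if not any_selected:
        raise TrackingError("no frame has an in-band autocorrelation maximum")
    return TrajectoryPath(frames, lags, amps, flags)


def voting_classifier_correction(
    path: TrajectoryPath,
    lattice: MaximaLattice,
    window: int = 5,
    votes_needed: int = 3,
    ratio: float = 1.8,
    direction: str = "both",
) -> TrajectoryPath:
    """Flag and repair selections that jump an octave away from recent history.

    Walking the path in frame order, a selection is declared an octave error
    when its lag is >= ``ratio`` times (direction "up"), <= 1/``ratio`` times
    (direction "down"), or either (direction "both") the already-corrected lag
    of at least ``votes_needed`` of the ``window`` preceding frames; it is then
    replaced by the current frame's maximum closest in lag to the previous
    frame's selection.  Frames with fewer than ``votes_needed`` predecessors
    are left untouched.
    """
    out = path.copy()
    n = len(out)
    for i in range(n):
        prev = out.lags[max(0, i - window) : i]
        if prev.size < votes_needed:
            continue
        cur = out.lags[i]
        up_votes = int(np.sum(cur >= ratio * prev))
        down_votes = int(np.sum(cur <= prev / ratio))
        fire = False
        if direction in ("up", "both") and up_votes >= votes_needed:
            fire = True
        if direction in ("down", "both") and down_votes >= votes_needed:
            fire = True
        if not fire:
            continue
        repl = _nearest_max(lattice, i, out.lags[i - 1])
        if repl is None or repl == cur:
            continue
        out.lags[i] = repl
        out.amps[i] = lattice.normalized_amplitude(i, repl)
        out.flags[i] += "V"
    return out


# ---------------------------------------------------------------------------
# stage 2: k-means outlier repair

def _outlier_features(path: TrajectoryPath, rate: float) -> np.ndarray:
    """Per-point feature vectors for the 2-means outlier split.

    Features: the point's lag; lag distance to its left neighbour (first
    point mirrors the right distance); lag distance to its right neighbour
    (last point mirrors the left distance); and the implied fundamental
    frequency in Hz (rate / lag).
    """
    lags = path.lags.astype(float)
    dif = np.abs(np.diff(lags))
    left = np.concatenate([[dif[0]], dif]) if dif.size else np.zeros_like(lags)
    right = np.concatenate([dif, [dif[-1]]]) if dif.size else np.zeros_like(lags)
    f0 = rate / lags
    return np.column_stack([lags, left, right, f0])


def kmeans_classifier_correction(
    path: TrajectoryPath,
    lattice: MaximaLattice,
    restarts: int = 10,
    max_sweeps: int = 50,
    seed: int = 0,
) -> TrajectoryPath:
    """Repair trajectory outliers via 2-means clustering on point features.

    Features are z-scored (zero-variance features drop out), then 2-means is
    run to convergence with ``restarts`` seeded initializations; the smaller
    cluster is taken as the outliers (an exact size tie means no correction).
    Outlier points are then swept left-to-right onto the lattice maximum of
    their frame nearest in lag to the preceding repaired point — the first
    point, if an outlier, anchors on the first non-outlier to its right —
    until a full sweep changes nothing or ``max_sweeps`` is reached.
    """
    if len(path) < 4:
        return path.copy()
    feats = _outlier_features(path, lattice.rate)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        return path.copy()  # degenerate: every point identical
    z = (feats[:, keep] - mu[keep]) / sd[keep]
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    with warnings.catch_warnings():
        # duplicate feature rows can collapse to a single distinct cluster;
        # that is a valid degenerate outcome (empty minority -> no outliers)
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = km.fit_predict(z)
    sizes = np.bincount(labels, minlength=2)
    if sizes[0] == sizes[1]:
        return path.copy()  # no "smaller" cluster
    outlier_label = int(np.argmin(sizes))
    is_outlier = labels == outlier_label

    out = path.copy()
    anchor_right = None
    non_out = np.where(~is_outlier)[0]
    for sweep in range(max_sweeps):
        changed = False
        for i in range(len(out)):
            if not is_outlier[i]:
                continue
            if i > 0:
                target = out.lags[i - 1]
            else:
                if anchor_right is None:
                    anchor_right = out.lags[non_out[0]] if non_out.size else out.lags[0]
                target = anchor_right
            repl = _nearest_max(lattice, i, target)
            if repl is not None and repl != out.lags[i]:
                out.lags[i] = repl
                out.amps[i] = lattice.normalized_amplitude(i, repl)
                if "K" not in out.flags[i]:
                    out.flags[i] += "K"
                changed = True
        if not changed:
            break
    else:
        warnings.warn(
            "k-means outlier repair hit the sweep cap before converging; "
            "returning the best-effort path",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# stage 3: sub-path split & merge

def split_into_subpaths(path: TrajectoryPath, lattice: MaximaLattice) -> list[SubPath]:
    """Cut the path wherever a transition is not between nearest-neighbour maxima.

    Between frames l and l+1, the transition is kept only if the point chosen
    in frame l+1 is the lattice maximum of that frame nearest in lag to the
    point chosen in frame l.
    """
    if len(path) == 0:
        raise ValueError("path is empty")
    cuts = []
    for i in range(len(path) - 1):
        nearest = _nearest_max(lattice, path.frames[i + 1], path.lags[i])
        if nearest is not None and path.lags[i + 1] != nearest:
            cuts.append(i + 1)
    bounds = [0] + cuts + [len(path)]
    return [
        SubPath(
            path.frames[a:b].copy(),
            path.lags[a:b].copy(),
            path.amps[a:b].copy(),
            list(path.flags[a:b]),
        )
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def merge_subpaths(subpaths: list[SubPath], lattice: MaximaLattice) -> TrajectoryPath:
    """Re-join sub-paths left-to-right, rerouting junctions onto shorter paths.

    At each junction the original continuation competes with an alternative
    built by hopping, frame by frame across the next sub-path's span, to the
    lattice maximum nearest the previous point's lag.  The cumulative
    Euclidean length (normalized coordinates, junction edge included) decides;
    the shorter continuation is appended and merging proceeds until no
    sub-paths remain.
    """
    if not subpaths:
        raise ValueError("need at least one sub-path")
    n_total = sum(len(sp) for sp in subpaths)
    acc_frames = list(subpaths[0].frames)
    acc_lags = list(subpaths[0].lags)
    acc_amps = list(subpaths[0].amps)
    acc_flags = list(subpaths[0].flags)
    for nxt in subpaths[1:]:
        # alternative continuation: nearest-neighbour hops from the junction
        alt_lags: list[int] = []
        alt_amps: list[float] = []
        prev = acc_lags[-1]
        feasible = True
        for fr in nxt.frames:
            hop_lag = _nearest_max(lattice, int(fr), prev)
            if hop_lag is None:
                feasible = False
                break
            alt_lags.append(hop_lag)
            alt_amps.append(lattice.normalized_amplitude(int(fr), hop_lag))
            prev = hop_lag
        junction = (
            np.array([acc_frames[-1]]),
            np.array([acc_lags[-1]]),
            np.array([acc_amps[-1]]),
        )
        orig_pts = _path_coords(
            np.concatenate([junction[0], nxt.frames]),
            np.concatenate([junction[1], nxt.lags]),
            np.concatenate([junction[2], nxt.amps]),
            lattice,
            n_total,
        )
        use_alt = False
        if feasible:
            alt_pts = _path_coords(
                np.concatenate([junction[0], nxt.frames]),
                np.concatenate([junction[1], np.asarray(alt_lags)]),
                np.concatenate([junction[2], np.asarray(alt_amps)]),
                lattice,
                n_total,
            )
            use_alt = _segment_length(alt_pts) < _segment_length(orig_pts)
        acc_frames.extend(nxt.frames.tolist())
        if use_alt:
            acc_lags.extend(alt_lags)
            acc_amps.extend(alt_amps)
            acc_flags.extend(
                f + "M" if a != b else f
                for f, a, b in zip(nxt.flags, alt_lags, nxt.lags)
            )
        else:
            acc_lags.extend(nxt.lags.tolist())
            acc_amps.extend(nxt.amps.tolist())
            acc_flags.extend(nxt.flags)
    return TrajectoryPath(
        np.asarray(acc_frames), np.asarray(acc_lags), np.asarray(acc_amps), acc_flags
    )


# ---------------------------------------------------------------------------
# rate conversion and the end-to-end estimator

def lags_to_rates(path: TrajectoryPath, lattice: MaximaLattice) -> RateSeries:
    """Convert fundamental-period lags to breaths/min on the frame time grid."""
    if np.any(path.lags <= 0):
        raise TrackingError("zero or negative lag on the trajectory")
    rates = 60.0 * lattice.rate / path.lags
    times = lattice.frame_times()[path.frames]
    return RateSeries(times=times, rates=rates, lags=path.lags.copy(), flags=list(path.flags))


def estimate_breathing_rate(
    signal: SampledSignal, config: TrackingConfig | None = None
) -> RateSeries:
    """End-to-end respiratory-rate estimation.

    Resamples to the common rate, frames the signal, builds the maxima
    lattice, then applies the tracking stages selected by
    ``config.variant``: ``"proposed"`` runs naive selection, voting
    correction, k-means repair and sub-path merging; ``"naive"`` stops after
    the Euclidean selection (no heuristics, the baseline variant).
    """
    cfg = config or TrackingConfig()
    try:
        resampled = resample_to_common_rate(signal, cfg.common_rate)
        frames = frame_signal(resampled, cfg.frame_length, cfg.overlap)
    except ValueError as exc:
        raise TrackingError(f"preprocessing failed: {exc}") from exc
    lat = build_lattice(frames)
    path = naive_maxima_selection(lat)
    if cfg.variant == "proposed":
        path = voting_classifier_correction(
            path,
            lat,
            window=cfg.voting_window,
            votes_needed=cfg.voting_votes,
            ratio=cfg.voting_ratio,
            direction=cfg.voting_direction,
        )
        path = kmeans_classifier_correction(
            path,
            lat,
            restarts=cfg.kmeans_restarts,
            max_sweeps=cfg.kmeans_max_sweeps,
            seed=cfg.seed,
        )
        path = merge_subpaths(split_into_subpaths(path, lat), lat)
    return lags_to_rates(path, lat)
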