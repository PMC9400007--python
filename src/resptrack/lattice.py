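"""Per-frame autocorrelation functions and the maxima lattice.

For each analysis frame the biased, zero-padded autocorrelation estimator

    phi(tau) = (1/N) * sum_{n=0}^{N-1} x(n) * x(n + tau),   x(m) = 0 for m >= N

is evaluated for lags tau = 0..N-1 after removing the frame mean (baseline
drift in belt and radar signals otherwise dominates phi and masks the
breathing peak).  Every local maximum of every frame's ACF — located through
the sign pattern of the first difference, i.e. the first-derivative zero
crossings with negative curvature — is collected into the *maxima lattice*,
the structure all trajectory tracking operates on.  The lag of the maximum
associated with the fundamental breathing period converts to a rate as
60 * rate / lag breaths/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_io import FrameSet

__all__ = [
    "AutocorrelationFunction",
    "MaximaLattice",
    "autocorrelation",
    "find_maxima",
    "build_lattice",
    "physiologic_lag_band",
]

#: Physiologic breathing band in breaths/min; candidate maxima for trajectory
#: selection are restricted to lags corresponding to this band (the lattice
#: itself stores all maxima).
BAND_BPM = (4.0, 60.0)


@dataclass(frozen=True)
class AutocorrelationFunction:
    """One frame's ACF: values phi(tau) for tau = 0..N-1."""

    values: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("ACF needs at least 2 lags")


@dataclass(frozen=True)
class MaximaLattice:
    """All ACF local maxima of all frames.

    Attributes
    ----------
    acf_values
        (L, N) array, one ACF per frame.
    maxima
        Per frame, strictly increasing lag indices of all local maxima
        (lag 0, the central maximum, excluded).
    central_value
        phi(0) per frame; the amplitude normalizer.
    rate, hop, frame_length
        Geometry of the originating :class:`~resptrack.signal_io.FrameSet`,
        carried along so tracking can normalize coordinates and timestamp
        frames.
    """

    acf_values: np.ndarray
    maxima: list[np.ndarray]
    central_value: np.ndarray
    rate: float
    hop: int
    frame_length: int

    @property
    def n_frames(self) -> int:
        return self.acf_values.shape[0]

    def normalized_amplitude(self, frame: int, lag: int) -> float:
        """phi_l(lag) / phi_l(0); 0 when the frame is identically zero."""
        c = self.central_value[frame]
        if c == 0:
            return 0.0
        return float(self.acf_values[frame, lag] / c)

    def frame_times(self) -> np.ndarray:
        starts = np.arange(self.n_frames) * self.hop
        return (starts + (self.frame_length - 1) / 2) / self.rate

    def in_band_maxima(self, frame: int) -> np.ndarray:
        lo, hi = physiologic_lag_band(self.rate, self.frame_length)
        m = self.maxima[frame]
        return m[(m >= lo) & (m <= hi)]

    def to_table(self, path: str | Path | None = None):
        """Tabular export (frame_index, lag, acf_value, is_maximum) for debugging."""
        import pandas as pd

        rows = []
        for l in range(self.n_frames):
            mset = set(self.maxima[l].tolist())
            for tau in range(self.acf_values.shape[1]):
                rows.append((l, tau, self.acf_values[l, tau], tau in mset))
        df = pd.DataFrame(rows, columns=["frame_index", "lag", "acf_value", "is_maximum"])
        if path is not None:
            df.to_csv(path, index=False)
        return df


def physiologic_lag_band(rate: float, frame_length: int) -> tuple[int, int]:
    """Lag range (in samples) spanning the physiologic band.

    60 breaths/min corresponds to the shortest period (``rate`` samples),
    4 breaths/min to the longest (``15 * rate`` samples), capped at the last
    available lag.
    """
    lo = max(1, int(round(rate * 60.0 / BAND_BPM[1])))
    hi = min(frame_length - 1, int(round(rate * 60.0 / BAND_BPM[0])))
    return lo, hi


def autocorrelation(frame: np.ndarray, frame_index: int = 0) -> AutocorrelationFunction:
    """Biased zero-padded ACF of one frame, mean removed first."""
    x = np.asarray(frame, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("frame must be 1-D with length >= 2")
    x = x - x.mean()
    n = x.size
    # full linear autocorrelation via FFT; keep non-negative lags
    full = sps.fftconvolve(x, x[::-1], mode="full")
    phi = full[n - 1 :] / n
    return AutocorrelationFunction(values=phi, frame_index=frame_index)


def find_maxima(acf: AutocorrelationFunction | np.ndarray) -> np.ndarray:
    """Lags of all local maxima of an ACF (central maximum at lag 0 excluded).

    A lag tau >= 1 is a maximum when the first difference changes sign from
    positive to negative there; a run of zero differences after a rise
    (a plateau) reports its first lag.
    """
    v = acf.values if isinstance(acf, AutocorrelationFunction) else np.asarray(acf, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 lags to locate maxima")
    d = np.diff(v)
    s = np.sign(d).astype(int)
    # next nonzero difference sign at or after each position (backward fill),
    # so a plateau inherits the sign of the drop (or rise) that ends it
    n = s.size
    idx = np.where(s != 0, np.arange(n), n)
    idx = np.minimum.accumulate(idx[::-1])[::-1]
    nxt = np.where(idx < n, s[np.minimum(idx, n - 1)], 0)
    cand = np.arange(1, v.size - 1)
    mask = (s[cand - 1] == 1) & (nxt[cand] == -1)
    return cand[mask]


def build_lattice(frames: FrameSet) -> MaximaLattice:
    """Compute one ACF and one maxima list per frame, in frame order.

    Frames with no local maxima (e.g. a constant frame) are recorded with an
    empty maxima list and handled downstream.
    """
    if frames.n_frames == 0:
        raise ValueError("FrameSet is empty")
    acfs = np.empty_like(frames.frames)
    maxima: list[np.ndarray] = []
    for l in range(frames.n_frames):
        acf = autocorrelation(frames.frames[l], frame_index=l)
        acfs[l] = acf.values
        maxima.append(find_maxima(acf))
    return MaximaLattice(
        acf_values=acfs,
        maxima=maxima,
        central_value=acfs[:, 0].copy(),
        rate=frames.rate,
        hop=frames.hop,
        frame_length=frames.frame_length,
    )
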