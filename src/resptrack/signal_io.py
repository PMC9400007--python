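"""Reading, resampling and framing of respiration waveforms.

Chest-motion signals arrive at device-native sample rates (a sensorized belt
records at 1000 Sa/s, a millimeter-wave radar at 30 Sa/s).  Everything
downstream of this module works on a common 100 Sa/s grid split into long
overlapping analysis frames, so that each frame contains several breath
cycles and the autocorrelation of a frame exposes the breathing period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "SampledSignal",
    "FrameSet",
    "SignalReadError",
    "read_signal_csv",
    "write_signal_csv",
    "zero_phase_lowpass",
    "resample_to_common_rate",
    "frame_signal",
]

#: Common processing rate in Sa/s; all estimators resample to this grid.
COMMON_RATE = 100.0
#: Analysis frame length in samples at the common rate (40.96 s at 100 Sa/s).
DEFAULT_FRAME_LENGTH = 4096
#: Fraction of a frame shared with its successor.
DEFAULT_OVERLAP = 0.85
#: Guard factor for the anti-aliasing cutoff when downsampling: the Butterworth
#: roll-off is gentle at third order, so the cutoff is placed at 0.45 of the
#: target Nyquist frequency.
ANTIALIAS_GUARD = 0.45
ANTIALIAS_ORDER = 3


class SignalReadError(ValueError):
    """Raised when a waveform file cannot be parsed."""


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled amplitude series.

    Parameters
    ----------
    samples
        Amplitude values in arbitrary units.
    rate
        Sample rate in Sa/s; must be positive.
    origin
        Provenance label, one of ``{"belt", "radar", "synthetic"}``.
    """

    samples: np.ndarray
    rate: float
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if self.origin not in ("belt", "radar", "synthetic"):
            raise ValueError(f"unknown origin {self.origin!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class FrameSet:
    """Overlapping analysis windows cut from one signal.

    ``frames`` is an (L, N) array: frame ``l`` (0-based) starts at sample
    ``l * hop`` of the source signal and holds exactly ``frame_length``
    samples; the trailing partial window is discarded.
    """

    frames: np.ndarray
    frame_length: int
    hop: int
    rate: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 2 or frames.shape[1] != self.frame_length:
            raise ValueError("frames must be (L, frame_length)")
        if not (1 <= self.hop <= self.frame_length):
            raise ValueError("hop must satisfy 1 <= hop <= frame_length")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Center time of each frame, in seconds from signal start."""
        starts = np.arange(self.n_frames) * self.hop
        return (starts + (self.frame_length - 1) / 2) / self.rate


def read_signal_csv(path: str | Path, rate: float, origin: str = "synthetic") -> SampledSignal:
    """Read a one- or two-column numeric text file into a :class:`SampledSignal`.

    Accepts comma- or whitespace-delimited rows; a single leading header line is
    auto-detected (first row non-numeric) and skipped.  Two-column files are
    interpreted as (time, amplitude) and only the second column is kept — the
    caller supplies the sample rate explicitly.
    """
    path = Path(path)
    values: list[float] = []
    header_allowed = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            try:
                row = [float(f) for f in fields]
            except ValueError:
                if header_allowed:
                    header_allowed = False
                    continue
                raise SignalReadError(
                    f"{path}: non-numeric row at line {lineno}: {line!r}"
                ) from None
            header_allowed = False
            if len(row) == 1:
                values.append(row[0])
            elif len(row) >= 2:
                values.append(row[1])
    if not values:
        raise SignalReadError(f"{path}: no numeric samples found")
    return SampledSignal(np.asarray(values), rate=rate, origin=origin)


def write_signal_csv(signal: SampledSignal, path: str | Path, include_time: bool = True) -> None:
    """Write a signal as ``time,amplitude`` (or single-column amplitude) CSV."""
    path = Path(path)
    with path.open("w") as fh:
        if include_time:
            fh.write("time_s,amplitude\n")
            for t, x in zip(signal.times, signal.samples):
                fh.write(f"{t:.6f},{x:.8g}\n")
        else:
            fh.write("amplitude\n")
            for x in signal.samples:
                fh.write(f"{x:.8g}\n")


def zero_phase_lowpass(signal: SampledSignal, cutoff: float, order: int = ANTIALIAS_ORDER) -> SampledSignal:
    """Forward-backward Butterworth low-pass filtering.

    The filter is applied twice — once forward, once on the time-reversed
    signal — which cancels the phase response, so breathing peaks are not
    shifted in time.  The effective magnitude response is the squared
    single-pass Butterworth response.  Edges use odd-symmetric padding of
    length ``3 * order``.
    """
    if not 0 < cutoff < signal.rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist)=(0, {signal.rate / 2}); got {cutoff}"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    b, a = sps.butter(order, cutoff, btype="low", fs=signal.rate)
    padlen = min(3 * order, len(signal) - 1)
    filtered = sps.filtfilt(b, a, signal.samples, padtype="odd", padlen=padlen)
    return SampledSignal(filtered, rate=signal.rate, origin=signal.origin)


def resample_to_common_rate(signal: SampledSignal, target_rate: float = COMMON_RATE) -> SampledSignal:
    """Resample a signal to the common processing rate.

    Downsampling first applies the third-order zero-phase Butterworth
    anti-aliasing filter with cutoff ``0.45 x (target_rate / 2)``, then
    polyphase decimation; upsampling uses band-limited polyphase
    interpolation.  Equal rates return the input unchanged.  Duration is
    preserved to within one output sample.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == signal.rate:
        return signal
    x = signal.samples
    if target_rate < signal.rate:
        cutoff = ANTIALIAS_GUARD * (target_rate / 2)
        x = zero_phase_lowpass(signal, cutoff, ANTIALIAS_ORDER).samples
    ratio = Fraction(target_rate / signal.rate).limit_denominator(10_000)
    resampled = sps.resample_poly(x, ratio.numerator, ratio.denominator)
    return SampledSignal(resampled, rate=target_rate, origin=signal.origin)


def frame_signal(
    signal: SampledSignal,
    frame_length: int = DEFAULT_FRAME_LENGTH,
    overlap: float = DEFAULT_OVERLAP,
) -> FrameSet:
    """Split a signal into maximal complete overlapping frames.

    ``hop = round(frame_length * (1 - overlap))`` samples (614 at the default
    4096/0.85 geometry; the nominal pre-rounding hop of 614.4 samples is
    6.144 s at 100 Sa/s).  The trailing partial window is discarded.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    n = len(signal)
    if frame_length > n:
        min_dur = frame_length / signal.rate
        raise ValueError(
            f"signal too short for one frame: need >= {frame_length} samples "
            f"({min_dur:.2f} s at {signal.rate} Sa/s), got {n}"
        )
    hop = max(1, round(frame_length * (1 - overlap)))
    n_frames = (n - frame_length) // hop + 1
    starts = np.arange(n_frames) * hop
    frames = np.stack([signal.samples[s : s + frame_length] for s in starts])
    return FrameSet(frames=frames, frame_length=frame_length, hop=hop, rate=signal.rate)
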