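"""Comparison estimators: the naive variant and time-domain peak counting.

The naive Euclidean-only estimator is the tracking pipeline's ``variant
= "naive"`` switch (stage-1 selection, no heuristics).  The second baseline
here emulates a generic time-domain peak detector: band-pass the signal to
the respiration band, pick inspiration peaks by prominence and minimum
separation, and read the rate off the mean inter-peak interval per analysis
frame.  It is an emulation of that family of algorithms — band edges,
prominence and separation rules are this package's documented choices — not
a byte-exact re-implementation of any particular library.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.stats import iqr

from .signal_io import SampledSignal, frame_signal, resample_to_common_rate
from .tracking import RateSeries, TrackingConfig

__all__ = ["time_domain_peak_rate", "RESP_BAND_HZ", "PEAK_PROMINENCE_IQR_FACTOR", "PEAK_MIN_SEPARATION_S"]

#: Respiration band for time-domain cleaning, Hz (4.2–60 breaths/min).
RESP_BAND_HZ = (0.07, 1.0)
#: Minimum peak prominence as a fraction of the frame's amplitude IQR.
PEAK_PROMINENCE_IQR_FACTOR = 0.3
#: Minimum separation between detected inspiration peaks, seconds.
PEAK_MIN_SEPARATION_S = 1.0


def time_domain_peak_rate(
    signal: SampledSignal, config: TrackingConfig | None = None
) -> RateSeries:
    """Estimate breaths/min per frame by counting inspiration peaks.

    The signal is resampled to the common rate, band-passed to
    ``RESP_BAND_HZ`` with a zero-phase third-order Butterworth filter, and
    framed on the same grid as the tracking estimator for comparability.
    Within each frame, peaks are local maxima with prominence at least
    ``0.3 x`` the frame's amplitude IQR and separation at least 1 s; the
    frame's rate is ``60 / mean inter-peak interval``.  Frames with fewer
    than two peaks are flagged (``P``) and carry the previous frame's rate
    forward; if no frame yields a rate the result is empty (never an error).
    """
    cfg = config or TrackingConfig()
    resampled = resample_to_common_rate(signal, cfg.common_rate)
    sos = sps.butter(3, RESP_BAND_HZ, btype="bandpass", fs=cfg.common_rate, output="sos")
    cleaned = sps.sosfiltfilt(sos, resampled.samples)
    raw_frames = frame_signal(resampled, cfg.frame_length, cfg.overlap)
    frames = frame_signal(
        SampledSignal(cleaned, rate=cfg.common_rate, origin=resampled.origin),
        cfg.frame_length,
        cfg.overlap,
    )
    # degenerate-input floor: a frame that was flat before band-passing holds
    # no breaths, whatever ripple the filter edges introduce
    raw_scale = max(float(np.max(np.abs(resampled.samples))), 1.0)
    min_dist = max(1, int(PEAK_MIN_SEPARATION_S * cfg.common_rate))
    times = frames.frame_times
    rates = np.full(frames.n_frames, np.nan)
    lags = np.zeros(frames.n_frames, dtype=int)
    flags = [""] * frames.n_frames
    for l in range(frames.n_frames):
        fr = frames.frames[l]
        spread = iqr(fr)
        if spread == 0 or iqr(raw_frames.frames[l]) <= 1e-9 * raw_scale:
            flags[l] = "P"
            continue
        peaks, _ = sps.find_peaks(
            fr, prominence=PEAK_PROMINENCE_IQR_FACTOR * spread, distance=min_dist
        )
        if peaks.size < 2:
            flags[l] = "P"
            continue
        mean_interval = float(np.mean(np.diff(peaks))) / cfg.common_rate
        bpm = 60.0 / mean_interval
        if not 4.0 <= bpm <= 60.0:
            flags[l] = "P"
            continue
        rates[l] = bpm
        lags[l] = int(round(mean_interval * cfg.common_rate))
    # carry forward over flagged frames; drop everything if nothing was valid
    valid = np.where(np.isfinite(rates))[0]
    if valid.size == 0:
        return RateSeries(
            times=np.empty(0), rates=np.empty(0), lags=np.empty(0, dtype=int), flags=[]
        )
    first = valid[0]
    rates[:first] = rates[first]
    lags[:first] = lags[first]
    for l in range(first + 1, frames.n_frames):
        if not np.isfinite(rates[l]):
            rates[l] = rates[l - 1]
            lags[l] = lags[l - 1]
    return RateSeries(times=times, rates=rates, lags=lags, flags=flags)
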