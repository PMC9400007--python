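import numpy as np
import pytest

from resptrack.lattice import MaximaLattice
from resptrack.signal_io import SampledSignal


def make_sine(freq_hz: float, duration: float, rate: float, origin: str = "synthetic") -> SampledSignal:
    t = np.arange(int(round(duration * rate))) / rate
    return SampledSignal(np.sin(2 * np.pi * freq_hz * t), rate=rate, origin=origin)


def make_lattice(
    maxima_per_frame,
    amp: float = 0.9,
    rate: float = 100.0,
    frame_length: int = 4096,
    hop: int = 614,
) -> MaximaLattice:
    """Craft a lattice directly from per-frame maxima positions.

    ``maxima_per_frame`` is a list (one entry per frame) of either lag lists
    or {lag: amplitude} dicts; phi(0) is 1 in every frame, so the given
    amplitudes are already normalized.
    """
    L = len(maxima_per_frame)
    acf = np.zeros((L, frame_length))
    acf[:, 0] = 1.0
    maxima = []
    for l, ms in enumerate(maxima_per_frame):
        if isinstance(ms, dict):
            items = sorted(ms.items())
        else:
            items = [(lag, amp) for lag in sorted(ms)]
        for lag, a in items:
            acf[l, lag] = a
        maxima.append(np.array([lag for lag, _ in items], dtype=int))
    return MaximaLattice(
        acf_values=acf,
        maxima=maxima,
        central_value=acf[:, 0].copy(),
        rate=rate,
        hop=hop,
        frame_length=frame_length,
    )


@pytest.fixture
def sine_12bpm_300s():
    return make_sine(12.0 / 60.0, 300.0, 100.0)


@pytest.fixture
def sine_15bpm_300s():
    return make_sine(15.0 / 60.0, 300.0, 100.0)
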