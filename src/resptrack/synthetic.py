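"""Synthetic respiration signals and cohorts with known ground truth.

The generator emulates quasi-periodic chest-motion waveforms: a
phase-accumulated oscillator whose instantaneous rate follows a (possibly
drifting, reflected) per-breath random walk, harmonic content above the
fundamental, slow amplitude modulation, additive white noise, and — for
radar-like renders — a weak non-harmonic interferer that produces the
closely spaced spurious autocorrelation maxima characteristic of radar
clutter.  An optional periodic fade of the fundamental component creates
frames in which the second harmonic dominates, the trap that provokes
octave errors in naive trackers.

Cohorts mirror the study protocol: paced breathing at 12 and 15 breaths/min
(5 min each) and free breathing (10 min), each subject rendered twice from
the same latent breathing process — belt-like (1000 Sa/s, clean) and
radar-like (30 Sa/s, noisy with clutter) — so the two devices "measure the
same breathing".
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .signal_io import SampledSignal

__all__ = [
    "SubjectProfile",
    "CohortSpec",
    "Recording",
    "generate_breathing_signal",
    "generate_cohort",
    "truth_on_frame_grid",
    "DEVICE_PRESETS",
]

#: Per-device rendering parameters: native sample rate, additive noise SD
#: (relative to the unit fundamental) and whether radar-like clutter is on.
DEVICE_PRESETS = {
    "belt": {"rate": 1000.0, "noise_sd": 0.02, "clutter": "none"},
    "radar": {"rate": 30.0, "noise_sd": 0.10, "clutter": "radar"},
}

#: Clutter interferer: non-harmonic line at 1.35x the base breathing
#: frequency with amplitude 0.3 relative to the fundamental.
CLUTTER_FREQ_FACTOR = 1.35
CLUTTER_AMPLITUDE = 0.3

#: Reflection bounds of the free-breathing rate random walk, breaths/min.
FREE_BREATHING_BOUNDS = (8.0, 25.0)

#: Slow amplitude-modulation frequency, Hz.
AM_FREQ_HZ = 0.02

#: SD of the per-subject offset from the nominal paced rate, breaths/min.
#: Subjects track an auditory pacer imperfectly; paced-cohort medians sit a
#: fraction of a breath/min off the nominal rate with a nonzero IQR.
PACING_OFFSET_SD = 0.2


@dataclass(frozen=True)
class SubjectProfile:
    """Parameters of one synthetic subject's breathing.

    ``harmonic_weights[j]`` is the relative amplitude of harmonic ``j + 2``
    (the fundamental has weight 1).  ``fundamental_fade_depth`` > 0 makes the
    fundamental's amplitude dip periodically to ``1 - depth`` with period
    ``fundamental_fade_period_s``, leaving the harmonics untouched — a
    controlled source of octave-error traps.
    """

    base_rate: float
    rate_drift: float = 0.0  # random-walk SD, breaths/min per breath
    harmonic_weights: tuple[float, ...] = (0.3,)
    amplitude_drift: float = 0.1
    noise_sd: float = 0.05
    clutter: str = "none"  # {"none", "radar"}
    seed: int = 0
    fundamental_fade_depth: float = 0.0
    fundamental_fade_period_s: float = 150.0

    def __post_init__(self) -> None:
        if not 4.0 <= self.base_rate <= 60.0:
            raise ValueError("base_rate must lie in [4, 60] breaths/min")
        if any(w < 0 for w in self.harmonic_weights):
            raise ValueError("harmonic weights must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.clutter not in ("none", "radar"):
            raise ValueError(f"unknown clutter model {self.clutter!r}")
        if not 0.0 <= self.fundamental_fade_depth <= 1.0:
            raise ValueError("fundamental_fade_depth must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort emulating the study protocol.

    Defaults: 31 subjects, 300 s per paced condition and 600 s of free
    breathing, free-breathing rate walk SD 0.5 breaths/min per breath.
    """

    subjects: tuple[SubjectProfile, ...]
    conditions: tuple[str, ...] = ("controlled12", "controlled15", "free")
    controlled_duration: float = 300.0
    free_duration: float = 600.0

    def __post_init__(self) -> None:
        if len(self.subjects) < 1:
            raise ValueError("need at least one subject")
        for c in self.conditions:
            if c not in ("controlled12", "controlled15", "free"):
                raise ValueError(f"unknown condition {c!r}")

    @classmethod
    def default(
        cls,
        n_subjects: int = 31,
        seed: int = 0,
        conditions: tuple[str, ...] = ("controlled12", "controlled15", "free"),
        **kwargs,
    ) -> "CohortSpec":
        """Build a cohort of ``n_subjects`` with per-subject seeds derived from ``seed``."""
        rng = np.random.default_rng(seed)
        subjects = tuple(
            SubjectProfile(
                base_rate=float(rng.uniform(10.0, 18.0)),
                rate_drift=0.5,
                harmonic_weights=(float(rng.uniform(0.2, 0.5)),),
                amplitude_drift=float(rng.uniform(0.05, 0.15)),
                noise_sd=0.05,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for _ in range(n_subjects)
        )
        return cls(subjects=subjects, conditions=conditions, **kwargs)

    def duration_for(self, condition: str) -> float:
        return self.free_duration if condition == "free" else self.controlled_duration


@dataclass(frozen=True)
class Recording:
    """One rendered signal plus its latent ground truth."""

    subject: int
    condition: str
    device: str
    signal: SampledSignal
    truth_bpm: np.ndarray  # instantaneous rate per output sample
    truth_times: np.ndarray


# ---------------------------------------------------------------------------

def _breath_rate_track(profile: SubjectProfile, duration: float, rng: np.random.Generator):
    """Per-breath rates and breath-boundary times of the latent process.

    The rate performs a reflected random walk (bounds 8–25 breaths/min) with
    one step per completed breath; paced conditions use drift 0 and the track
    is constant.
    """
    lo, hi = FREE_BREATHING_BOUNDS
    rates = [profile.base_rate]
    bounds = [60.0 / profile.base_rate]
    while bounds[-1] < duration:
        r = rates[-1]
        if profile.rate_drift > 0:
            r = r + rng.normal(0.0, profile.rate_drift)
            if r < lo:
                r = 2 * lo - r
            if r > hi:
                r = 2 * hi - r
            r = float(np.clip(r, lo, hi))
        rates.append(r)
        bounds.append(bounds[-1] + 60.0 / r)
    return np.asarray(rates), np.asarray(bounds)


def _instantaneous(
    rates: np.ndarray, bounds: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous rate (bpm) and accumulated phase (rad) at times ``t``."""
    starts = np.concatenate([[0.0], bounds[:-1]])
    idx = np.clip(np.searchsorted(bounds, t, side="right"), 0, rates.size - 1)
    inst = rates[idx]
    # phase = 2*pi * (completed breaths + fraction of current breath)
    frac = (t - starts[idx]) * rates[idx] / 60.0
    phase = 2 * np.pi * (idx + frac)
    return inst, phase


def _render(
    profile: SubjectProfile,
    rates: np.ndarray,
    bounds: np.ndarray,
    duration: float,
    sample_rate: float,
    rng: np.random.Generator,
    origin: str,
) -> tuple[SampledSignal, np.ndarray]:
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    inst, phase = _instantaneous(rates, bounds, t)
    w1 = np.ones(n)
    if profile.fundamental_fade_depth > 0:
        w1 = 1.0 - profile.fundamental_fade_depth * np.sin(
            np.pi * t / profile.fundamental_fade_period_s
        ) ** 2
    x = w1 * np.sin(phase)
    for j, w in enumerate(profile.harmonic_weights):
        x = x + w * np.sin((j + 2) * phase)
    am_phase = rng.uniform(0, 2 * np.pi)
    x = x * (1.0 + profile.amplitude_drift * np.sin(2 * np.pi * AM_FREQ_HZ * t + am_phase))
    if profile.clutter == "radar":
        f_cl = CLUTTER_FREQ_FACTOR * profile.base_rate / 60.0
        x = x + CLUTTER_AMPLITUDE * np.sin(2 * np.pi * f_cl * t + rng.uniform(0, 2 * np.pi))
    if profile.noise_sd > 0:
        x = x + rng.normal(0.0, profile.noise_sd, size=n)
    return SampledSignal(x, rate=sample_rate, origin=origin), inst


def generate_breathing_signal(
    profile: SubjectProfile, duration: float, rate: float
) -> tuple[SampledSignal, np.ndarray]:
    """Generate one respiration-like signal and its ground-truth rate track.

    Returns the signal and the instantaneous breathing rate (breaths/min) at
    every output sample.  Deterministic for a fixed profile (the profile's
    ``seed`` drives all randomness).
    """
    if duration < 60.0 / profile.base_rate:
        raise ValueError("duration must cover at least one breath")
    rng = np.random.default_rng(profile.seed)
    rates, bounds = _breath_rate_track(profile, duration, rng)
    origin = "radar" if profile.clutter == "radar" else "synthetic"
    return _render(profile, rates, bounds, duration, rate, rng, origin)


def truth_on_frame_grid(
    truth_bpm: np.ndarray,
    sample_rate: float,
    frame_length: int = 4096,
    overlap: float = 0.85,
    common_rate: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average the per-sample truth over the analysis frame grid.

    Frame geometry is expressed at the common processing rate and mapped back
    to the truth track's native rate, so the returned values align with the
    frames an estimator run at default settings would produce.
    """
    hop = max(1, round(frame_length * (1 - overlap)))
    n_common = int(truth_bpm.size * common_rate / sample_rate)
    n_frames = (n_common - frame_length) // hop + 1
    if n_frames <= 0:
        raise ValueError("truth track shorter than one frame")
    times = []
    values = []
    for l in range(n_frames):
        t0 = l * hop / common_rate
        t1 = t0 + frame_length / common_rate
        i0, i1 = int(t0 * sample_rate), min(int(t1 * sample_rate), truth_bpm.size)
        times.append(t0 + (frame_length - 1) / (2 * common_rate))
        values.append(float(np.mean(truth_bpm[i0:i1])))
    return np.asarray(times), np.asarray(values)


def _condition_profile(base: SubjectProfile, condition: str) -> SubjectProfile:
    if condition.startswith("controlled"):
        nominal = 12.0 if condition == "controlled12" else 15.0
        # deterministic per-subject pacing imperfection
        rng = np.random.default_rng((base.seed, zlib.crc32(b"pacing")))
        offset = float(np.clip(rng.normal(0.0, PACING_OFFSET_SD), -0.6, 0.6))
        return replace(base, base_rate=nominal + offset, rate_drift=0.0)
    return base  # free breathing keeps the subject's own base rate and drift


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Render every subject under every condition with both device characters.

    For each (subject, condition) one latent breathing process is drawn and
    rendered twice — belt-like at 1000 Sa/s (low noise, no clutter) and
    radar-like at 30 Sa/s (higher noise, clutter on) — from the same latent
    phase, so the paired recordings share an identical ground-truth rate
    track.
    """
    recordings: list[Recording] = []
    for s_idx, base in enumerate(spec.subjects):
        for condition in spec.conditions:
            prof = _condition_profile(base, condition)
            duration = spec.duration_for(condition)
            # one latent process per (subject, condition); stable string hash
            # so reruns are byte-identical
            cond_key = zlib.crc32(condition.encode())
            latent_rng = np.random.default_rng((prof.seed, cond_key))
            rates, bounds = _breath_rate_track(prof, duration, latent_rng)
            for device, preset in DEVICE_PRESETS.items():
                dev_prof = replace(
                    prof, noise_sd=preset["noise_sd"], clutter=preset["clutter"]
                )
                dev_rng = np.random.default_rng(
                    (prof.seed, cond_key, zlib.crc32(device.encode()))
                )
                sig, inst = _render(
                    dev_prof, rates, bounds, duration, preset["rate"], dev_rng, device
                )
                recordings.append(
                    Recording(
                        subject=s_idx,
                        condition=condition,
                        device=device,
                        signal=sig,
                        truth_bpm=inst,
                        truth_times=sig.times,
                    )
                )
    return recordings
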