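# resptrack

Respiratory-rate estimation from single-channel chest-motion waveforms —
belt-worn transducers and contactless millimeter-wave radar — built for
researchers comparing contact and contactless breathing monitors.

Breathing shows up as a quasi-periodic displacement signal.  Within a long
analysis frame the autocorrelation function (ACF)

    phi(tau) = (1/N) * sum_n x(n) x(n + tau)

peaks at the fundamental breathing period P, giving the rate
f0 = 60·fs/P breaths/min.  Harmonics and radar clutter add competing ACF
maxima, and the classic failure is the *octave error*: locking onto the
half-period peak and reporting twice the true rate.  `resptrack` tracks
the fundamental maximum through the *maxima lattice* (all local ACF maxima
of all frames) with three heuristic repair stages — Euclidean selection
with a 1.8-fold / 3-of-5 voting classifier, 2-means outlier repair on the
trajectory, and sub-path split/merge along nearest-neighbour hops — then
converts the tracked lags to breaths/min.  Two baselines (the heuristic-free
naive variant and a time-domain peak counter), a synthetic belt+radar cohort
generator with known ground truth, DTW trajectory comparison, and a
Levene → Kruskal–Wallis → Dunn group-testing workflow round out the package.
See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
import resptrack as rt

# a radar-like 5-minute recording, paced at 12 breaths/min
profile = rt.SubjectProfile(base_rate=12.0, noise_sd=0.10, clutter="radar", seed=3)
signal, truth = rt.generate_breathing_signal(profile, duration=300.0, rate=30.0)

series = rt.estimate_breathing_rate(signal)          # full pipeline
naive = rt.estimate_breathing_rate(
    signal, rt.TrackingConfig(variant="naive")       # Euclidean selection only
)
print(f"frames: {len(series)}")
print(f"proposed median: {np.median(series.rates):.2f} breaths/min")
print(f"naive    median: {np.median(naive.rates):.2f} breaths/min")
```

```
frames: 43
proposed median: 12.17 breaths/min
naive    median: 12.17 breaths/min
```

Each recording yields one estimate per 40.96 s frame, hopping 6.14 s; the
median sits within ~0.2 breaths/min of the paced truth (the small excess is
the radar clutter pulling the ACF peak a few lags early, plus lag
quantization).  On clean signals the naive variant matches the full
pipeline; on harmonic-rich signals whose fundamental intermittently fades
it commits octave errors in ~30% of frames (rates near 24 instead of 12)
while the full pipeline stays on the fundamental ridge — run
`scripts/acceptance.py` below to see those numbers recomputed.

The same objects drive the evaluation utilities:

```python
spec = rt.CohortSpec.default(n_subjects=4, seed=0, conditions=("free",))
recordings = rt.generate_cohort(spec)   # paired belt + radar renders
d = rt.dtw_distance([12.0, 12.0, 12.0], [15.0, 15.0, 15.0])  # -> 9.0
```

A `resptrack` console script exposes the batch workflow:

```bash
resptrack synth --subjects 4 --condition free --seed 7 --out cohort/
resptrack estimate --rate 30 --estimator proposed cohort/subject00_free_radar.csv
resptrack eval --cohort cohort/ --report report.json
```

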