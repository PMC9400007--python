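# Methods

## Problem and model

`resptrack` estimates the respiratory rate (breaths/min) from a
single-channel chest-motion waveform, as produced by a wearable sensorized
belt (≈1000 Sa/s) or a contactless millimeter-wave radar (≈30 Sa/s).
Breathing is quasi-periodic, so within a long analysis window the
autocorrelation function (ACF)

    phi(tau) = (1/N) * sum_{n=0}^{N-1} x(n) x(n+tau),   x(m)=0 for m >= N

of a mean-removed frame has a local maximum at the fundamental breathing
period P, and the rate is 60·fs/P breaths/min.  The difficulty is that real
ACFs carry maxima from harmonics (half-period peaks → readouts at twice the
true rate, the classic *octave error*), from radar clutter (many closely
spaced maxima) and from noise.  The estimator therefore tracks the
fundamental maximum *across* frames — the collection of all local ACF
maxima of all frames forms a *maxima lattice*, and the estimate is a
trajectory through it — and repairs the trajectory in three stages:

1. **Naive Euclidean selection + voting classifier.**  Per frame, the
   maximum closest to the central peak in normalized coordinates (lag/N on
   x, phi/phi(0) on y) is selected; low spurious peaks near the center are
   far on the y axis and lose.  A selection whose lag differs by ≥1.8× from
   at least 3 of the 5 preceding (already corrected) selections is declared
   an octave error and replaced by the current frame's maximum nearest the
   previous selection.
2. **k-means outlier repair.**  Each path point is featurized as (lag,
   |Δlag| to left neighbour, |Δlag| to right neighbour, implied f0 in Hz),
   features are z-scored, and 2-means splits the points into a majority and
   a minority cluster; minority points are swept left-to-right onto the
   lattice maximum nearest the preceding repaired point until stable.
3. **Sub-path split/merge.**  The path is cut at transitions that are not
   nearest-neighbour hops between adjacent frames; fragments re-join
   left-to-right, each junction comparing the original continuation against
   a nearest-neighbour-hop alternative and keeping the shorter (cumulative
   Euclidean length, normalized coordinates).

## Preprocessing

All inputs are resampled to a common 100 Sa/s grid.  Downsampling first
applies a third-order Butterworth low-pass forward and backward (zero
phase; odd-symmetric edge padding of length 3·order) with cutoff at 0.45×
the target Nyquist — a guard band chosen because third-order roll-off is
gentle; upsampling uses polyphase band-limited interpolation.  Frames are
4096 samples (40.96 s) with overlap 0.85; the hop is rounded to an integer
614 samples, so the nominal 6.144 s resolution is the pre-rounding value.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `frame_length` | 4096 samples | ≈8 breaths at 12 breaths/min; ACF stability vs. time resolution |
| `overlap` | 0.85 | hop 614 samples ≈ 6.14 s effective resolution |
| `common_rate` | 100 Sa/s | shared processing grid for both devices |
| `voting_window / votes / ratio` | 5 / 3 / 1.8 | history length, votes needed, octave threshold |
| `voting_direction` | `both` | which lag jumps count as octave errors (see below) |
| physiologic band | 4–60 breaths/min | lags 100–1500 samples at 100 Sa/s; candidates outside are ignored during selection |
| k-means restarts / seed | 10 / 0 | deterministic clustering; best inertia kept |
| repair sweep cap | 50 | termination guarantee on adversarial lattices |

**Voting direction.**  An octave error proper is a readout at twice the
true rate, i.e. the selected lag collapsing to half.  A rule that only
fires on lag *increases* cannot catch that failure, and worse, it fires on
the legitimate recovery jump at the end of an error run, which re-entrenches
the error.  The default is therefore symmetric: a selection ≥1.8× *or*
≤1/1.8× of 3-of-5 predecessors is flagged.  Both one-sided variants remain
available via `voting_direction`.

**Coordinate normalization.**  Raw lag (≤4096) would dwarf normalized ACF
amplitude (≤1) in any Euclidean comparison, so every distance uses lag/N,
phi/phi(0), and (for path lengths) frame index divided by trajectory
length.  Likewise the k-means features are z-scored because they mix scales
(~500-sample lags, ~10-sample neighbour distances, ~0.2 Hz frequencies).

## Numerical choices and degenerate inputs

- The ACF peak of the biased (zero-padded) estimator is shifted early by the
  linear taper, by ≈ P²/(4π²N(1−P/N)) lags (≈1.8 lags at P=500, N=4096);
  tests allow ±3 lags accordingly.  The implied rate bias at 12 breaths/min
  is ≈0.04 breaths/min, negligible against the ≈0.02 breaths/min lag
  quantization step.
- Frames with no in-band maxima copy the previous frame's point and are
  flagged `F`; an empty *first* frame raises a tracking error.
- A 2-means size tie, or a feature matrix with zero variance, means "no
  outliers" and the repair stage is a no-op; re-running the repair on its
  own output changes nothing.
- Both filtering passes and all clustering are deterministic given the
  config seed; synthetic generation is deterministic given profile seeds.

## DTW comparison

Free-breathing rate series are compared by dynamic time warping with
absolute-difference local cost.  The implementation is the standard
multiresolution corridor approximation (halve, solve, project the warp path,
refine within a radius).  The default radius is 2: measured against an
exact O(n²) dynamic program on smooth rate-series-like inputs (random walks
with ≈0.3 breaths/min steps) the worst excess is ≤5%, whereas radius 1
exceeds 20%.  On white-noise-like inputs no small radius keeps the corridor
near the optimum; the accuracy statement applies to the smooth trajectories
this package produces, which is the intended domain.

Cohort structure uses three groups: same-subject cross-device distances
(n per cohort of n subjects) and cross-subject within-device distances over
ordered pairs (n·(n−1) per device).

## Group testing

Levene's test (median-centered) checks variance homogeneity, Kruskal–Wallis
checks location, and Dunn's post-hoc z tests (pooled mean-rank differences
with tie correction) localize differences.  Dunn p-values are unadjusted by
default — a Holm switch is provided — and per-group median/IQR/SD accompany
every report.

## What the synthetic generator emulates — and what it does not

The generator is a phase-accumulated oscillator: per-breath rates follow a
reflected random walk (bounds 8–25 breaths/min; SD 0.5 breaths/min per
breath for free breathing, 0 for paced), the waveform adds harmonics above
the fundamental, slow amplitude modulation (0.02 Hz), white noise, and — for
radar-like renders — a non-harmonic interferer at 1.35× the breathing
frequency with amplitude 0.3, which reproduces the closely spaced spurious
ACF maxima of radar clutter.  Paced conditions add a per-subject offset
from the nominal rate (SD 0.2, clipped ±0.6 breaths/min), because humans
track an auditory pacer imperfectly; without it, within-group variance
collapses to lag quantization and rank tests flag any systematic device
bias, however small.  Each subject×condition draws one latent breathing
process rendered twice — belt-like (1000 Sa/s, noise SD 0.02, no clutter)
and radar-like (30 Sa/s, noise SD 0.10, clutter on) — so paired recordings
share an identical ground-truth rate track.

Octave-error traps deserve a note: for a *stationary* fundamental+harmonic
mix the full-period ACF maximum always dominates the half-period one
(both components correlate fully at P), so a large second harmonic alone
never fools even the naive tracker.  Real octave errors come from epochs
where the fundamental component weakens; the generator models this with a
periodic fundamental fade (`fundamental_fade_depth`, sin² with a
`fundamental_fade_period_s` period), under which half-period maxima do
outgrow full-period ones in the faded frames.

The generator does not model chest-wall biomechanics, radar electromagnetic
propagation, large body movements, or apneas; passing tests demonstrate
correct behaviour of the tracking machinery under controlled quasi-periodic
conditions, not clinical performance on human recordings.

## Problem sizes used in the shipped checks

Paced-recovery and DTW-structure checks run 31-subject cohorts (5 min paced
at 300 s, 10 min free at 600 s per recording); the octave battery is six
300 s signals; the rank-workflow check runs 20 seeded cohorts of 10
subjects per group.  These sizes keep each check in the tens of seconds to
a few minutes on one CPU while preserving the protocol's group counts
(31 same-subject and 930 ordered cross-subject comparisons).

## Known limitations

- Rates are quantized to 60·fs/lag; at 12 breaths/min the step is ≈0.024
  breaths/min, at 60 breaths/min ≈1 breath/min.
- The first ~41 s of signal produce no estimate (one full frame is needed),
  and a corrupt first frame is fatal rather than back-filled.
- If more than half of all frames lock onto a harmonic ridge, the minority
  cluster in stage 2 is the *correct* one and repair can invert; the stage-3
  merge mitigates but does not eliminate this regime.
- The time-domain peak baseline is an emulation of generic peak-counting
  estimators (band 0.07–1 Hz, prominence 0.3× frame IQR, 1 s separation),
  intended for qualitative comparison only.
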