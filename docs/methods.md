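# Methods

`pyrpeak` implements a causal single-lead ECG R-peak detector built around
segmented high-order polynomial baseline removal, together with the
evaluation protocol (beat-by-beat matching and summary statistics) and a
seeded synthetic-ECG generator that makes every stage verifiable against
exact ground truth.

## Detection model

The detector assumes a single uniformly sampled voltage lead in millivolts.
Processing is *causal at segment granularity*: the record is consumed in
consecutive, non-overlapping 15-second segments, and the output for any
prefix of the record never changes when later data arrive.  Detection
latency is therefore bounded by one segment.

Per segment:

1. **Baseline removal.** A degree-34 polynomial is least-squares fitted to
   the segment and subtracted.  This is the Moore–Penrose (minimum-norm
   least-squares) projection; for numerical sanity at degree 34 over
   thousands of samples the time axis is rescaled to [-1, 1] and the fit is
   computed in the Legendre basis, which spans the identical polynomial
   subspace — a raw monomial Vandermonde pseudoinverse is unusable at this
   order (condition numbers beyond 1e16).  The projection removes
   sudden-movement wander, monotonic drift, sub-1-Hz respiratory
   oscillation, slow electrical transients, and most of the quasi-periodic
   P/T baseline.  The interior resolution of the fit is roughly
   `segment/degree` (~440 ms), so QRS complexes (~80 ms) pass through
   untouched away from segment edges.
2. **Polarity correction.** Large-slope events (smoothed-derivative
   magnitude above the candidate threshold) are located and the signal value
   at each is a vote; a strict majority of negative votes means the leads
   are reversed, and the segment is negated.  A tie or a flat segment is
   left unchanged.  This makes detection exactly symmetric under sign flips.
3. **Smoothed derivative.** First difference scaled to mV/s, smoothed by a
   causal unit-sum boxcar of width 1/50 s (`max(1, round(fs/50))` samples —
   5 samples at 256 Hz, 7 at 360 Hz, 10 at 500 Hz).  The boxcar width
   equals roughly one powerline period at 50–60 Hz, so mains pickup is
   strongly attenuated in the derivative domain.
4. **Candidate selection.** Contiguous runs where the smoothed derivative
   exceeds `0.4 × (99th percentile of |smoothed derivative| in the
   segment)`.  The scale is per-segment and relative, making detection
   invariant to amplitude rescaling; a percentile (rather than the maximum)
   keeps it robust to isolated extreme values.  The 99th percentile sits on
   the QRS-slope part of the derivative distribution across the 50–180 bpm
   range; lower percentiles fall into the T/P-slope mass at low heart rates
   (QRS duty cycle < 5%) and admit T waves.  A run must last at least half
   the kernel width (minimum 2 samples): a physiological QRS upstroke
   sustains its slope for tens of milliseconds, whereas an isolated
   electrical impulse survives the boxcar as a 1–2 sample derivative blip
   and is rejected here.
5. **Refinement.** Each candidate onset marks a QRS upstroke; the R apex is
   taken as the argmax of the detrended signal within 50 ms after the
   onset.  A refined sample must be a concave local maximum (negative
   second difference); duplicates collapse.
6. **Refractory rule.** After concatenating per-segment peaks, any two
   detections closer than 250 ms — beyond the physiological maximum heart
   rate — are resolved by eliminating the lower-amplitude one
   (closest-pair first, iterated to a fixpoint; an amplitude tie keeps the
   earlier peak).  Across segment boundaries already-emitted peaks are
   final: a new detection violating the gap against the emitted tail is
   dropped.  This keeps the output strictly append-only, which is what
   makes prefix results exactly stable.

### Boundary gain compensation

A least-squares polynomial has far finer resolution near the ends of its
interval than in the interior: the Legendre-root spacing shrinks like
`L/d²` at the edges, ~13 ms for degree 34 over 15 s — QRS timescale.  The
fit therefore partially absorbs a QRS complex whose apex lies within a few
samples of a segment boundary, attenuating its residual upstroke severalfold.
Within ~22 ms of either segment end the candidate threshold is scaled by
0.6 and the minimum run length drops to 2 samples, and a compensated
candidate must refine to an apex *inside* that zone (an apex deeper in the
segment is outside the attenuated region and must pass the ordinary
threshold).  The factor and window were calibrated on the synthetic suite
and cross-checked on held-out seed sets: wider windows or lower factors
admit fit-ringing false positives; the full threshold misses attenuated
boundary beats.

Because the compensation operates purely on the per-segment fit residual,
it preserves two structural properties exactly: invariance under adding any
degree-≤34 polynomial to a segment (the projection annihilates it), and
prefix causality.

Known limitation: strong artifacts the polynomial cannot represent in the
interior (e.g. mains pickup, sharp wander steps near a boundary) make the
fit ring at segment edges.  Rarely this ringing exceeds the full interior
threshold with a beat-like residual amplitude; such a transient is
indistinguishable from a genuine attenuated boundary beat using residual
features alone and costs on the order of one false positive per hundred
minute-long artifact records.

## Evaluation protocol

A detected peak within 150 ms of an unmatched reference beat is a true
positive; matching is one-to-one in a single chronological sweep that
assigns each test peak the earliest still-unmatched in-window reference
beat.  Because each test peak's admissible references form a contiguous
span of the sorted reference list, this greedy sweep is the classic convex
bipartite matching rule and attains the maximum possible pair count (a
nearest-reference variant does not: refs {0, 100}, tests {90, 240}, window
150 pairs only one).  The test suite cross-checks it against a
maximum-cardinality bipartite matching oracle on random instances.

Reported statistics: Se = TP/(TP+FN), PPV = TP/(TP+FP), F1 = their harmonic
mean, and FN/FP counts divided by the number of reference annotations (note
the FP rate under that denominator can exceed 1).  PPV is reported as
missing, not zero, when there are no detections.  Ventricular-flutter
episodes are excised from both streams before matching — during flutter
there are no discernible sinus beats to score — and group summaries are
unweighted per-record means within each group plus an overall row.

## Comparison detector

A Pan–Tompkins-style energy detector is included for head-to-head runs:
causal 3rd-order Butterworth bandpass (5–15 Hz, the classical QRS energy
band), first difference, squaring, 7-sample moving-window integration, then
a per-window adaptive threshold at 0.6 × the integrated signal's maximum
within the current 15-s window, and a 150-ms refractory rule.  Candidates
are refined to the bandpassed-signal magnitude maximum; the causal bandpass
delays the QRS by tens of milliseconds, well inside the 150-ms scoring
window.  The passband and the meaning of the 0.6 threshold are this
package's choices where the published parameterizations leave them open.

## Synthetic data

The generator is the package's ground-truth instrument, not a physiological
simulator.  Each beat is a sum of Gaussian bumps — P (0.15 mV, σ 25 ms,
180 ms before R), R (1 mV, σ = QRS width/6 with an 80-ms default), T
(0.25 mV, σ 60 ms, 250 ms after R, both offsets compressed at short RR) —
so the true apex sample is known exactly and annotated.  RR intervals are
`base·(1+ε)`, ε ~ N(0, jitter²) truncated at ±3σ; the default jitter of
0.05 approximates resting sinus variability, and 60 bpm / 60 s / 360 Hz are
the artifact-suite defaults (360 Hz matching the common benchmark sampling
rate).

Artifact classes and their defaults (magnitudes chosen at or above the
scale of a 1-mV R peak for baseline disturbances, since weaker versions are
trivially handled):

| kind | model | default |
|---|---|---|
| `movement_wander` | random smooth tanh steps, ~0.3 s transitions | 2 mV |
| `drift` | monotonic linear ramp | 1.5 mV |
| `respiration` | sinusoid < 1 Hz | 0.5 mV at 0.3 Hz |
| `powerline` | sinusoid at 50/60/100 Hz | 0.1 mV at 50 Hz |
| `spike_lowfreq` | ~1-s Gaussian transients (σ 0.25 s) | 2 mV |
| `spike_highfreq` | 1-sample impulses | 1.5 mV |
| `invert_polarity` | exact negation | — |
| `enlarged_t` | extra T bumps (σ 70 ms) raising T to ~0.85 of R | +0.6 mV |
| `pvc` / `pac` | inserted premature beats at 62% of the local RR (wide/tall without P, or near-normal), annotated as beats | 4 events |

Spikes are placed at least 250 ms from every true beat so that the expected
detector behaviour — spike rejected, beats kept — is unambiguous and the
truth annotations are unchanged by injection.  Premature beats are genuine
beats and update the truth.

What the generator does **not** emulate: realistic PQRST morphology and its
beat-to-beat variation, AF f-waves, QT/QRS adaptation to rate, broadband
myographic noise, electrode pop clusters, or correlated artifact mixtures.
Passing the synthetic suite therefore demonstrates the mechanism of each
pipeline stage against its intended artifact class, not clinical-grade
performance; benchmark claims on real recordings require running the
`benchmark` command on an annotated database such as the standard
arrhythmia benchmark (WFDB `.hea/.dat/.atr` files), for which the I/O layer
provides a self-contained format-212 codec.

## Numerical and design choices

- Indices are 0-based, times are `index/fs`, intervals half-open.
- The Legendre least-squares fit reproduces added polynomials of degree
  ≤ 34 to < 1e-6 mV; detrending is linear and idempotent at that tolerance.
- A final partial segment longer than `poly_order + 1` samples is fitted
  with the same order; a shorter tail is merged into the previous segment.
- Polarity ties do not flip (strict majority), keeping `detect(-x) =
  detect(x)` exact for any record with a decidable majority.
- The detector contains no randomness; all stochasticity lives in the
  generator's seeds, and dataset manifests record every parameter so files
  regenerate bit-identically.
- Problem sizes used by the test suite and the acceptance script (5-minute
  clean records, 60-second artifact records, 10 seeds per condition) are
  the package's standard verification conditions; they keep a full run in
  the tens of seconds while giving several thousand scored beats per
  suite.

## Known limitations

- Boundary blind spots: a beat whose apex falls on the one or two samples
  adjacent to a segment boundary may be unrecoverable (the residual
  upstroke is absorbed by the fit's edge flexibility), and edge ringing can
  rarely produce a boundary false positive (see above).
- The per-segment polarity vote assumes polarity is stable within 15 s; a
  mid-segment lead swap yields an undefined majority.
- The flutter-exclusion reading (symmetric removal of both streams inside
  annotated episodes, no margins) is one of several defensible choices.
- CSV input carries no sampling rate; the caller must supply it, and
  nothing validates that the stated rate matches the data.
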