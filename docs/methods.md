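# Methods

## Data model and units

All times are milliseconds from recording start; the beat axis starts at 0
for intervals-only input. A `BeatSeries` stores strictly increasing beat
times; BBI *i* spans `(beat_times[i], beat_times[i+1]]`, so an interval
belongs to a window only when both endpoints do, and an interval *touches*
a window when they merely intersect. Powers are absolute ms²; no normalised
units, no VLF band, no LF/HF ratio.

## Artifact screening

Two labels, applied to every BBI without ever deleting one:

* **outlier** — BBI outside `[400, 1500]` ms (bounds inclusive-clean),
  equivalently heart rate above 150 or below 40 beats/min. A pure,
  order-independent function of the values.
* **ectopic** — Malik-style relative criterion: BBI *i* is ectopic when it
  differs from the most recent *accepted* (non-outlier, non-ectopic) BBI by
  more than 20% of that reference; the first BBI is never ectopic, and a
  beat with no accepted predecessor becomes the new reference. Threshold
  and bounds are configurable (`ectopic.rel_threshold`, `outlier.low_ms`,
  `outlier.high_ms`).

Outlier takes precedence when both apply. One subtlety worth knowing: the
flag set is **not** globally monotone in the threshold. Tightening the
threshold can flag an extra beat, which freezes the reference and may
*unflag* a later beat; the rule only guarantees identical decisions up to
the first divergence. The tests assert exactly that, plus monotonicity in
the cascade-free case.

Screening labels rather than deletes because the study design compares two
window lengths of the *same* data; removing or interpolating beats would
change the statistics being compared. Only windows where nothing was
flagged are analysed.

## Window scanning and hourly selection

Candidate 5-minute windows are evaluated on a 60 s start grid
(`segment.step_ms`). A window is rejected if any flagged BBI overlaps it —
a strictly stronger condition than "every fully contained BBI is clean",
chosen so that a surviving window is unambiguous: its interior is
artifact-free and no artifact straddles its edges. A guard of ≥ 0.4
contained BBIs per second (120 per 5-minute window) protects against
malformed masks; genuinely clean windows always exceed it since a clean
BBI is at most 1.5 s.

Hourly selection is greedy and start-to-start inclusive: keep the first
candidate, then repeatedly the earliest candidate starting at least
`spacing_min` (default 60) minutes after the last kept start. The first
minute of each kept window — same start, 60 s long — inherits cleanliness
because any interval overlapping the sub-window overlaps the parent.

## Metrics

RMSSD and SDNN are computed directly on the contained BBIs (SDNN with the
n−1 divisor). Frequency metrics need an evenly sampled tachogram: each
contained BBI is a sample at its end-beat time, interpolated by a natural
cubic spline onto a uniform 4 Hz grid spanning the window (the ≤ 1.5 s
edge extrapolation is negligible for clean windows), mean-removed. The
default estimator is Welch (Hann window, `min(256, N)` samples per
segment, 50% overlap) with trapezoidal band integration over 0.04–0.15 Hz
(LF) and 0.15–0.40 Hz (HF). The alternative Lomb–Scargle path evaluates
the classical periodogram of the *uneven* (time, BBI) points on a grid
oversampled 2× relative to 1/T, scaled by 2T/N so a sinusoid of amplitude
A integrates to A²/2 over its peak; on stationary tone fixtures the two
estimators agree to within a few percent, and the test suite requires 25%.

The identical code path serves 300 s and 60 s windows. A 60 s window
covers only 2.4 cycles of the 0.04 Hz LF edge; LF there is
resolution-limited, flagged with a `ResolutionWarning` (threshold: fewer
than 5 cycles), but still computed and reported — the point of the study is
precisely to quantify how much that costs. Windows with fewer than 4
contained BBIs get NaN frequency metrics, written as empty CSV cells.

## Agreement

Pairs are structural: each 1-minute value comes from the first minute of
the very 5-minute window it is compared with, and pairs from all recordings
are pooled into one Pearson R per metric (a per-recording breakdown goes in
the report). Categories are half-open and exhaustive — excellent R ≥ 0.9,
good 0.7–0.9, moderate 0.4–0.7, low < 0.4 — closing the conventional
0.39/0.40 presentation gap at 0.4; negative R is reported as-is and falls
in "low". Constant inputs raise rather than silently return 0. No
confidence intervals or significance tests are attached; the correlation is
descriptive.

## Synthetic generator

Beats follow `t[k+1] = t[k] + m(t[k])` with

```
m(t) = base + A_tr·sin(2πt/P_tr + φ) + A_LF(t)·sin(2πf_LF t + φ₁)
            + A_HF(t)·sin(2πf_HF t + φ₂) + ε_k,    ε_k ~ N(0, σ²)
```

a beat-by-beat approximation to integral-pulse-frequency modulation that is
adequate while modulation amplitudes are small against the base interval
(here ≲ 30%). Oscillation amplitudes wander sinusoidally between 0.2× and
1.8× their nominal value; phases are drawn per recording from seeded,
per-component substreams (so toggling one injection type never perturbs
another stream).

Defaults model a healthy ambulatory adult and, deliberately, the dynamics
that make the 1-vs-5-minute comparison informative:

| parameter | default | why |
|---|---|---|
| base BBI | 850 ms | ~71 beats/min resting-ambulatory |
| HF tone | 0.25 Hz, 30 ms, wander 1700 s | respiratory sinus arrhythmia; vagal state nearly constant within any 5-min window, varying hour to hour |
| LF tone | 0.10 Hz, 30 ms, wander 1100 s | baroreflex band; LF power fluctuates on ~20-min scales with posture/arousal |
| slow trend | 230 ms, 3600 s | activity/sleep cycling of mean heart rate (~56–97 beats/min); comparable in 5-min variance to the oscillations, as slow components are in real ambulatory data |
| jitter | 8 ms | white beat-to-beat noise |
| injections | 3 ectopics/h, 1 outlier/h | plausible ambulatory artifact density |

These give RMSSD ≈ 30 ms and 5-min SDNN ≈ 40–55 ms, and keep artifact-free
BBIs within ~490–1210 ms, safely inside the screening range. Wander
periods are deliberately incommensurate with the hourly sampling so
consecutive selected segments explore the amplitude range. Ectopy is
injected as a premature beat (0.6×) plus compensatory pause (+0.4× to the
next interval), preserving cumulative time; outliers replace one interval
with a draw from outside the screening range and shift subsequent beats.

What the generator does *not* emulate: broadband (stochastic) band power —
each band is a tone with wandering amplitude — respiratory coupling to a
breathing model, heart-rate-dependent band edges, morphology of real
ectopy, or motion-artifact bursts. Consequently, passing the benchmark
shows that the pipeline reproduces the *mechanism* of ultra-short-term
(dis)agreement — stable vagal modulation survives window shortening, slow
variance does not, LF is resolution- and drift-limited — not that it
reproduces any particular cohort's numbers. On this benchmark (10 seeded
~100-hour recordings) the median pooled correlations order as
RMSSD ≈ HF (≈ 0.90) > LF (≈ 0.77) > SDNN (≈ 0.71).

## Numerical choices and degenerate inputs

* Integer-free float ms arithmetic throughout; beat-axis reconstruction
  from cumulative intervals is exact to 1e−12 relative.
* Scan grid and window bounds are half-open `[start, end)`; the greedy
  spacing comparison is inclusive (`≥`).
* Constant windows: RMSSD = SDNN = 0 and band powers 0 (the Lomb–Scargle
  path short-circuits on variance < 1e−12 rather than dividing by noise).
* Files: `#` comments and blank lines ignored; parse errors carry line
  numbers; when a time column and a stated-interval column disagree by
  more than 0.5 ms the time column wins with a `ConsistencyWarning`.
* Recordings shorter than the window, all-artifact recordings, and
  constant metric columns all produce explicit empty results or errors,
  never silent zeros.

## Problem sizes

The test suite and the acceptance script generate everything at run time:
the benchmark uses ten ~102-hour synthetic recordings (~4.3 M beats in
total, ≥ 100 hourly pairs each), which the full pipeline processes in
about a second per recording; the whole suite runs in well under a minute.

## Known limitations

* The ectopic rule is interval-based; true ectopy classification needs ECG
  morphology, which is out of scope by design.
* Band powers from 60 s windows are reported despite the LF resolution
  limit — by design, with a warning — so LF values at 1 min should be
  interpreted as noisy estimates.
* Pooled Pearson R ignores within-recording clustering; per-recording
  correlations are reported but not modelled (no ICC, Bland–Altman or
  mixed effects).
* The WFDB-style annotation reader handles plain-text sample indices, not
  binary annotation files.
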