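# hrvconcord

Ultra-short-term heart rate variability (HRV): do 1-minute windows agree
with the conventional 5-minute minimum?

HRV quantifies the variability of beat-to-beat intervals (BBIs, also called
RR/NN intervals) and is widely used as a non-invasive autonomic marker, with
particular interest in mental-health monitoring where the parasympathetic
metrics (RMSSD, HF power) matter most. Wrist wearables struggle to deliver
5 continuous artifact-free minutes because of motion, which motivates the
question this package operationalises: across many hours of recording, how
well do HRV metrics computed on 1-minute windows track the same metrics
computed on the 5-minute windows that contain them?

`hrvconcord` is a tested, reusable pipeline for that question:

1. **Screen** every BBI: out-of-range *outliers* (outside 400–1500 ms,
   i.e. heart rate above 150 or below 40 beats/min) and *ectopic* beats
   (relative change > 20% against the last accepted interval). Nothing is
   deleted — editing a series would change the very statistics being
   compared.
2. **Segment**: scan a 1-minute start grid for 5-minute windows that no
   flagged BBI touches, then greedily keep one window per hour (next
   candidate ≥ 60 min after the last selected start).
3. **Measure** each selected window and its first minute with the same code
   path:
   - RMSSD = √(mean((BBIᵢ₊₁ − BBIᵢ)²)) — short-term, vagally dominated;
   - SDNN = sample standard deviation of the BBIs — total variability;
   - LF, HF = tachogram band power (ms²) in 0.04–0.15 Hz and 0.15–0.40 Hz,
     via cubic-spline resampling at 4 Hz + Welch (Hann, 256 samples, 50%
     overlap), or a Lomb–Scargle estimator on the uneven samples.
4. **Correlate**: pool the (1-min, 5-min) pairs per metric and report
   Pearson's R, categorised as excellent (≥ 0.9), good (0.7–0.89),
   moderate (0.4–0.69) or low (< 0.4).

A seeded synthetic generator produces multi-hour BBI recordings with
respiratory-band (HF) and baroreflex-band (LF) modulation, slow
nonstationary drift, white jitter, and injectable artifacts, so every stage
is testable against ground truth without clinical data.

## Worked example

Simulate one 24-hour wear and run the concordance study:

```sh
hrvconcord simulate --out day.rr --duration-h 24 --seed 7
hrvconcord run day.rr --outdir day_out
```

which logs

```
INFO wrote 105782 intervals to day.rr (88 injections -> day.injections.json)
INFO rmssd_ms: R = 0.890 (good, n = 24)
INFO sdnn_ms: R = 0.648 (moderate, n = 24)
INFO lf_ms2: R = 0.765 (good, n = 24)
INFO hf_ms2: R = 0.895 (good, n = 24)
```

and writes `pairs.csv` (one row per selected segment and metric, 5-min and
1-min values side by side), `concordance.csv` (per-metric R, category, n)
and `report.json` (segment counts, exclusions, per-recording R, config
hash). Of the 1051 artifact-free candidate windows found in this recording,
24 hourly ones were kept — one pair per worn hour. The parasympathetic
metrics (RMSSD, HF) track their 5-minute values closely; SDNN agrees least
because slow drift dominates 5-minute total variability but is invisible to
a 1-minute window; LF sits in between, limited by the 2.4 cycles of its
0.04 Hz band edge that fit in 60 s.

The same pipeline is importable:

```python
import hrvconcord as hc

series = hc.read_rr_text("day.rr")                     # or your own RR file
pairs, results, report = hc.run_concordance_study(series)
```

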