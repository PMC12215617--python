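# kisssync

Detection and quantification of calcium signals from the kisspeptin-neuron
GnRH pulse generator, with ground-truthed simulators and the exact
nonparametric statistics used to analyze them.

Arcuate-nucleus kisspeptin (ARN^KISS) neurons intermittently coordinate
their activity into population **synchronization events (SEs)**; each SE
drives one pulse of luteinizing hormone. Their activity is measured three
ways, and this package implements the complete analysis chain for each:

1. **In-vivo fiber photometry** — dual-channel GCaMP6s recordings
   (calcium-dependent 465–490 nm, calcium-independent 405 nm) acquired at
   10 Hz in a scheduled 5-s-on / 10-s-off duty cycle. The pipeline subtracts
   the isosbestic channel, removes slow baseline drift with a 900-s
   moving-window low-percentile estimator, z-scores, detects peaks by
   topographic prominence, and classifies a peak as an SE when
   (i) its height is at least ⅓ of the highest peak of the recording, and
   (ii) it lies more than 160 s from any neighboring peak.
   SE amplitude, width at half maximum, post-injection 4-h bin counts,
   latency to the first SE, and inter-SE intervals follow.
2. **Ex-vivo slice imaging** — multi-ROI GCaMP traces at 2 Hz. Per-cell
   calcium events are maximal runs of ΔF/F above the cell's mean + 2 SD;
   a **miniature synchronization event (mSE)** is a chain of events from
   ≥ 2 neurons whose successive peaks fall within 10 s of each other. Rates
   are reported per cell per hour over 12-min baseline/drug/wash epochs
   separated by 2-min wash gaps.
3. **Patch clamp** — whole-cell ΔV_mem responses to 1-min drug
   applications (responder iff ΔV_mem ≤ −5 mV), paired NA1/NA2 application
   summaries with percent reduction against the pooled NA1 mean, and
   cell-attached firing-rate changes (pre window vs 0.5–1.5 min post
   application).

The statistics module provides the exact two-tailed Wilcoxon matched-pairs
signed-rank test (W reported as |Σ signed ranks|; full enumeration for
n ≤ 25), the exact Mann–Whitney U test with mean-rank-difference reporting
(enumeration for n₁+n₂ ≤ 20), step-down Holm–Šidák adjustment
(p̃₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(k−i+1), monotone), paired/unpaired t tests with an
F-test variance screen, one-way repeated-measures ANOVA with Holm–Šidák
post-hoc contrasts, and a leave-one-animal-out sensitivity analysis.

Because no raw traces are deposited for these experiments, every analysis
stage is validated against the `kisssync.synthetic` simulators, which plant
known SE times, event times, responder flags, and rates, and return them as
`GroundTruth` for recovery testing.

## Worked example

Simulate a 24-h photometry recording in which the SE hazard is zeroed for
3 h after an injection at t = 6 h, then run the full detection chain:

```python
import kisssync as ks

cfg = ks.PhotometrySimConfig(seed=1, injection_time=21600.0,
                             suppression_duration=10800.0,
                             suppression_factor=0.0)
trace, truth = ks.simulate_photometry(cfg)
proc, ses = ks.detect_synchronization_events(trace)
print(f"planted SEs: {len(truth.se_times)}, detected: {len(ses)}")
tl = ks.se_timeline(ses, injection_time=21600.0)
print(f"baseline (4 h pre): {tl.baseline_count} SEs; "
      f"bins post: {tl.bin_counts}; latency {tl.latency_to_first/3600:.2f} h")
for s in ses[:3]:
    print(f"  SE peak {s.peak_time:8.1f} s  amp {s.amplitude:5.2f} z  "
          f"fwhm {s.fwhm:5.1f} s")
```

prints

```
planted SEs: 17, detected: 17
baseline (4 h pre): 3 SEs; bins post: [2, 3]; latency 3.01 h
  SE peak   4534.8 s  amp 12.03 z  fwhm  30.0 s
  SE peak   7365.1 s  amp 10.46 z  fwhm  26.1 s
  SE peak  10624.4 s  amp 15.16 z  fwhm  27.7 s
```

Every planted SE is recovered, and the 3-h suppression is visible as a
3.01-h latency from injection to the next SE onset. A paired slice
comparison of six baseline vs drug rates runs through the exact Wilcoxon
test:

```python
w = ks.wilcoxon_signed_rank(ks.PairedSample(
    before=[22.9, 25.0, 19.3, 30.1, 18.2, 21.7],
    after=[5.3, 6.1, 4.0, 8.8, 3.1, 6.0]))
print(f"W = {w.statistic_value}, p = {w.p_raw}")   # W = 21.0, p = 0.03125
```

A command-line interface wraps the same operations:

```bash
kisssync simulate photometry --seed 1 --out sim/
kisssync detect-se --in sim/photometry.csv --injection-time 21600 --out out/
kisssync stats --test mannwhitney --in tidy.csv --family 4 --out result.csv
```

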