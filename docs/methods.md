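# Methods

This note documents the models, conventions, and numerical choices behind
`kisssync`, and what the simulator-based validation does and does not
establish about real recordings.

## Photometry pipeline

**Channel correction.** The calcium-independent (405-nm) channel is removed
from the calcium-dependent (465–490-nm) channel by plain subtraction, the
default, which assumes matched detector gains. An affine-fit mode
(`fit_isosbestic=True`) regresses the 405 channel onto the 465 channel by
least squares first and is preferable when gains differ; it is offered as
an option rather than the default because plain subtraction is the
convention this analysis chain follows.

**Baseline adjustment.** Slow drift (bleaching plus physiological wander)
is estimated as the 10th percentile of the corrected signal in sliding
900-s windows placed at 450-s strides, interpolated between window centers
with a shape-preserving cubic (PCHIP), and subtracted. The window length is
the published convention; the percentile, stride, and interpolant are this
package's choices — the original routine's internals beyond the window size
are unpublished, so correctness is defined behaviorally: a constant signal
maps to zero, a pure linear drift is removed to within a few percent of its
range, and fast transients (tens of seconds against a 900-s window) retain
their amplitude to within 10%. Recordings shorter than two windows fall
back to global 10th-percentile subtraction with a logged warning.

**Normalization and peaks.** The adjusted signal is z-scored over the full
recording (mean 0, SD 1). Peaks are strict local maxima with topographic
prominence ≥ 1 z (the prominence default is exposed; no published value
exists). Plateau maxima resolve to the plateau midpoint.

**SE classification.** The amplitude threshold is one third of the highest
peak over the available recording (logged when the recording is shorter
than the nominal 24 h). The >160-s spacing rule is resolved greedily,
keeping the highest candidate first with ties broken by earlier time; this
guarantees a final set satisfying both rules independent of input order and
is verified in tests against an exhaustive feasible-subset oracle.
"Neighboring peak" is read as neighboring *candidate* (threshold-passing)
peak. All temporal rules operate in wall-clock time on the gapped
duty-cycle grid; nothing is interpolated across off-duty gaps.

**SE shape and timing.** SE amplitude is z at the peak minus a local
baseline (10th percentile of the preceding 300 s). FWHM spans the
half-amplitude crossings bracketing the peak, linearly interpolated between
samples; a missing crossing within the 300-s search window flags the width
as undefined (NaN). Onset is the last upward crossing of 20% of the SE's
amplitude before the peak — the published schematic defines onsets
graphically, not by formula, and 20% is this package's operationalization.
Latency from an injection is measured to SE *onset* (not peak); bin counts
use peak times.

## Slice network analysis

ΔF/F uses F′ = F − background and F₀ = the 20th percentile of F′ (no
published F₀ definition; a low percentile is robust to sparse transients).
Non-positive F₀ marks a degenerate cell and raises. The 2-SD event
threshold uses the mean and SD of the *full* trace, events included — the
literal reading — with a baseline-window alternative exposed. mSE chaining
starts at the earliest unconsumed event and extends while successive peaks
are < 10 s apart, so chains are exactly the maximal runs of the sorted
events; an event joins at most one chain, and only chains with ≥ 2 distinct
cells are emitted (same-cell repeats may sit inside a chain but do not
satisfy the neuron requirement). Per-cell participation counts mSEs
containing the cell (not member events), per hour. Epoch plans are 720-s
baseline/drug/wash measurement windows with 120-s wash-in/out gaps aligned
to drug metadata.

## Patch quantification

Voltage traces are smoothed with a 1-s median filter (resistant to spike
and seal artifacts; the original read-off method is unstated). The pre-drug
voltage is the mean over the 60 s before application ("immediately before"
is not quantified; 60 s is the package's choice), and the drug voltage is
the smoothed minimum from application start to 120 s past its end, because
responses are transient yet outlast a 1-min application. The responder
threshold is ΔV_mem ≤ −5 mV, inclusive at the boundary. Washout recovery is
satisfied when the trace re-enters ±2 mV of the pre-drug level at any point
7–17 min after application end. Antagonist efficacy is reported as
100·(|mean NA1| − |mean NA2|)/|mean NA1| against the pooled NA1 mean. Note
that the mean of per-cell deltas and the delta of group means differ in
general; this package reports per-cell deltas and their group means
explicitly so either summary can be formed. Firing-rate changes compare
spikes/s over a 60-s pre window with spikes/s over the 30–90-s
post-application-start window; a zero pre rate flags the percent reduction
undefined.

## Statistics

* Wilcoxon matched-pairs: zero differences dropped, midranks on |d|,
  W = |Σ signed ranks| (this convention reproduces W = 21 for six pairs all
  moving one way). Exact two-sided p by full enumeration of the 2ⁿ sign
  assignments (dynamic-programming count over doubled midranks) for n ≤ 25;
  tie-corrected normal approximation beyond.
* Mann–Whitney: U = min(U₁, U₂); mean rank Δ = mean rank(group 2) − mean
  rank(group 1) on the pooled midranking. Under complete separation
  U = 0 and |Δ| = (n₁+n₂)/2 — a proved identity covered by property tests.
  Exact p = P(min(U₁,U₂) ≤ U_obs) by enumeration of all group labelings
  for n₁+n₂ ≤ 20; tie-corrected normal approximation beyond. Cutoffs are
  desk-scale enumeration limits and configurable at module level.
* Holm–Šidák: step-down, adjusted₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(k−i+1), monotone
  nondecreasing, never below raw. Family sizes are supplied by the caller —
  families are analysis-specific (e.g. k = 4 antagonist comparisons) and
  cannot be inferred from a p-value list alone.
* t tests delegate to scipy; the unpaired variant screens variance
  homogeneity with a two-sided F-test at α = 0.05 and switches to Welch
  when rejected, recording the F outcome.
* RM-ANOVA: classical sums of squares, F with (k−1, (k−1)(n−1)) df, no
  sphericity correction by default (none was applied in the source
  analyses); Holm–Šidák-adjusted pairwise paired-t post-hocs. A
  zero-between-condition matrix returns F = 0, p = 1.
* Leave-one-animal-out re-runs a caller-supplied test dropping each
  animal's full observation set; exclusions leaving too little data are
  flagged as None rather than silently skipped.

## Simulators

The simulators generate data with the statistical structure the analyses
assume, plus known ground truth. Their defaults are the study conditions
where published (10 Hz, 5 s on / 10 s off; 22.9 events/cell/h; 2-Hz slice
imaging; 40% responders with mean −9.9 mV; −50 mV resting potential;
7–17-min washout; 1.48 Hz tonic firing with ~0.14 drug scaling) and
field conventions where not:

* **SE timing** is a gamma renewal process (default mean 4000 s, shape 4,
  ~20 SEs/24 h). In-vivo SE frequency per physiological state is not a
  published number; these defaults are labeled conventions. Post-injection
  suppression multiplies the renewal hazard by a factor for a fixed
  duration, implemented exactly by time rescaling (a factor of zero freezes
  the renewal clock); rebound is not modeled. The ovariectomized mode is a
  two-state (cluster/quiescent) modulated renewal with shorter intervals
  and higher amplitudes inside clusters.
* **GCaMP6s kinetics** are a difference of exponentials (rise 1.5 s, decay
  30 s at the photometry defaults; faster for slice events), conventional
  for this indicator and configurable; transients are evaluated
  analytically at the gapped sample times, so the duty cycle clips sampled
  peak heights exactly as acquisition would.
* **Artifacts** couple additively and identically into both channels
  (gain-scaled low-pass noise), which is what makes the subtraction step
  testable. Bleaching is exponential plus slow sinusoidal wander.
* **Slice networks** superpose per-cell Poisson events with latent network
  events (default 5.3/h) recruiting each cell with probability 0.6 and
  small (SD 1.5 s) jitter, so recruited peaks chain within the 10-s rule.
* All randomness derives from one integer seed through named substreams
  (seed ⊕ CRC32 of the component name), so outputs are bit-reproducible
  and edits to one component leave the others' draws unchanged.

**What passing recovery tests show — and don't.** The simulators emulate
renewal timing, indicator kinetics, drift, duty-cycle gaps, and additive
noise; they do not emulate motion artifacts beyond linear coupling,
non-stationary noise, hemodynamic contamination, focal drift, overlapping
ROIs, or seal degradation. Recovery results (SE detection F1 ≥ 0.95,
responder classification ≥ 95%) therefore validate the *rules and code
paths* under the assumed signal model, not performance on arbitrary real
recordings.

## Problem sizes and runtime

Validation runs use 24-h photometry simulations (~288,000 on-duty samples)
across 10–20 seeds, 1-h slice recordings of 10 cells across 20 seeds, and
50-neuron patch cohorts across 3 seeds — sizes chosen to keep Monte-Carlo
error on recovered rates below ~5% while the full suite completes in well
under a minute of simulation time per module.

## Known limitations

* The ⅓-of-max SE threshold is applied to z-scored amplitudes; whether the
  original analysis thresholded before or after z-scoring is not published,
  and the two differ only by an affine map, which the rule is invariant to
  within a recording.
* Baseline estimation is behaviorally, not bit-for-bit, equivalent to the
  original moving-window routine.
* The exact Mann–Whitney enumeration is O(C(n, n₁)); beyond the default
  cutoff the normal approximation (with tie correction, no continuity
  correction) is used.
* The photometry simulator plants SEs only; it does not model sub-threshold
  population activity between SEs.
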