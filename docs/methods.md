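# Methods

This note documents the statistical procedures the package implements,
the conventions chosen where more than one was defensible, what the
synthetic generators do and do not emulate, and the package's known
limitations.

## Stimulus-aligned spike-train analysis

### Binning and the PETH

Spikes are counted in fixed-width bins (default Δ = 10 ms) aligned to
each stimulus onset, over a caller-chosen range (default [−1 s, +1 s)).
Bins are half-open on the right, `[edge, edge + Δ)`; a spike landing
exactly on an onset belongs to the first post-onset bin. This is the
standard deterministic convention and is implemented with
`searchsorted(side="left")`, so no floating-point epsilon enters the
count. The trial-averaged rate per bin is the trial-summed count divided
by `n_trials × Δ`.

The z-scored PETH uses the mean μ and *sample* standard deviation σ
(n − 1 denominator) of the trial-averaged rate over the bins covering the
1 s immediately preceding onset: `z_b = (r_b − μ)/σ`. When σ = 0 (e.g. a
silent or perfectly regular baseline) the z trace is *undefined*: the
unit is flagged, carries `z_rate = None` rather than NaNs, and is
excluded from the population-average z trace while remaining eligible for
classification and latency detection (which do not need σ).
By construction the z-scored baseline bins have mean 0 and sample SD 1;
the test suite enforces this to 1e-9.

### Modulation test and classification

For each response window (20 ms, 100 ms, 1 s after onset) the per-trial
firing rate in the window is compared with the per-trial rate in the 1 s
baseline by a two-sided paired t-test (equal trial counts by
construction). Units with p < α = 0.05 are classified *excited* or
*inhibited* by the sign of the mean rate difference; otherwise
*unmodulated*. Two degenerate cases are handled explicitly: if every
per-trial difference is zero the t statistic is undefined and the unit is
reported unmodulated with p = 1; if the differences are constant but
non-zero the evidence is unbounded and p is reported as 0 with the class
given by the sign. Per-unit tests are deliberately *not* corrected for
multiple comparisons — the classification mimics a per-unit screening
rule, not a family-wise inference — and this is the main caveat when
interpreting response-type fractions.

A note on calibration: on strongly discrete data (short windows at low
rates, e.g. 20 ms windows where most trials contain 0–1 spikes) the
paired t-test is mildly anticonservative; Monte Carlo at the default
operating point (15 Hz baseline, 100 trials) puts the 20 ms-window type-I
error near 0.057 rather than 0.050. This is a property of the procedure
itself, inherited by design.

### Modulation index

`MI = (r_resp − r_base)/(r_resp + r_base)`, bounded in [−1, 1],
antisymmetric, zero for equal rates. The 0 Hz / 0 Hz case returns 0 by
convention; callers needing to distinguish "balanced" from "silent" should
inspect the rates.

### Latency detection

The latency test operates on *trial-summed* counts per bin, for which a
Poisson law is exact under the null (a sum of independent Poisson counts
is Poisson); applying the same region to trial-averaged rates would have
no such law. The null expectation is `λ = baseline_rate × Δ × n_trials`
with the baseline rate taken from the 1 s pre-onset period. The
confidence region is the equal-tailed two-sided 97% region (1.5% per
tail): `lo` is the smallest k with CDF(k) ≥ 0.015 and `hi` the smallest k
with CDF(k) ≥ 0.985, so a count is outside when `k < lo` or `k > hi`.
The latency is reported as the **start time** of the second bin of the
earliest pair of consecutive out-of-region bins whose starts both lie
within 100 ms of onset; if no such pair exists the latency is absent
(reported as NaN in tables). Both the equal-tailed choice and the
second-bin-start convention are conventions, stated here because the
alternatives (one-sided regions; end of the second bin) are defensible;
with the step-onset generator the reported latency is the true onset
delay plus one bin width.

With ~10 search bins and ≤ 3% per-bin outside probability, the false-pair
rate on null units is well under 1% per unit; the suite checks that null
units yield an absent latency ≥ 96% of the time.

### Population summary

Response-type counts and fractions are reported per window (fractions sum
to 1). The population z trace averages only units with defined z. The
across-unit test compares each unit's mean rate in [0, 1 s) against
[−1 s, 0) with a Wilcoxon signed-rank test (zero-difference units dropped,
per the standard procedure); with fewer than two units, or all-zero
differences, p is reported as 1 rather than erroring. For display, units
sort excited → unmodulated → inhibited, each block by descending 1 s
modulation index (stable sort, so ties keep input order).

## Operant behavior

Event logs are validated on construction: ascending times within the
session, no simultaneous events (ties are rejected rather than silently
ordered), known side labels, and consecutive same-side events at least
one laser duration apart — the box cannot register a re-entry during the
laser (or the equivalent lapse on the inactive side), so a log violating
the lockout indicates corrupted data.

* **Inter-poke intervals** are onset-to-onset (poke offsets are not
  recorded in the input format); the mean is absent with < 2 pokes.
* **Bursts** are maximal runs of consecutive same-side pokes whose
  successive onset-to-onset gaps are all *strictly below* the threshold
  (2 s default, 6 s alternative); a gap exactly at the threshold
  terminates the run. Runs with ≥ 2 pokes are bursts. Maximality implies
  every poke belongs to at most one burst and every 2 s burst is contained
  in a 6 s burst; both are property-tested against an exhaustive oracle.
* **Extinction preference** is prev-active / total pokes during the
  15-min extinction session; with zero pokes it is 0.5 and flagged
  indeterminate rather than an error, so group summaries remain
  computable.
* **Exclusion QC** takes exactly four daily training sessions and flags a
  subject when day-4 active pokes < 0.5 × day-1, or when the average
  active rate over the four sessions (total pokes / total minutes) is
  below 1/min.
* **Locomotion**: per-epoch path length sums Euclidean step lengths
  between consecutive samples; a step straddling an epoch boundary is
  split linearly in time (exact for constant velocity within a step,
  which is the resolution limit of any sampled track). Same-label epochs
  pool across cycles. Group-level inferential statistics across subjects
  are out of scope; only descriptive summaries are produced.

## Synthetic generators

* **Units** are piecewise-homogeneous Poisson processes: baseline rate
  everywhere except `[onset + delay, onset + delay + effect_duration)`
  per trial, where the rate steps to the response rate. The step (rather
  than a ramp) matches the step assumptions of the analysis and makes
  latency-recovery targets sharp: recovered latency = delay + Δ. Default
  population parameters: baseline rates uniform on 8–25 Hz (tonically
  active thalamic relay range), excited units at 2–4× baseline, inhibited
  units at 0–30% of baseline, onset delays from {0, 20, 50} ms. Mixture
  class counts are assigned by largest remainder (not multinomial
  sampling), so recovery tests measure classification error only.
* **The operant agent** is a two-clock scheme: each side pokes as an
  exponential-clock process; each *logged* reinforced active poke adds
  `learning_gain` (0.05 pokes/min) to the active rate and multiplies the
  inactive rate by `inactive_decay` (0.97). Pokes attempted during a
  side's 1 s lockout are suppressed — not logged and not reinforced — so
  generated logs satisfy the lockout invariant by construction. Defaults
  (2 pokes/min per side at start) yield ~100–200 active and a handful of
  inactive pokes per 30-min reinforced session, and an unreinforced
  control at 0.7 pokes/min yields a few tens of pokes split evenly —
  qualitatively matching well-trained subjects and controls. Extinction
  replays the learned rates with reinforcement removed and learning
  frozen. This is an artifact of test design, **not** a model of animal
  learning: it has no satiety, no within-burst temporal structure beyond
  the exponential clocks, and no across-day dynamics.
* **Tracks** are constant-step-length random walks (wrapped-Gaussian
  heading increments) whose step length is the epoch's speed / sample
  rate, so realized path length per epoch equals speed × duration up to
  boundary discretization.

All generators take explicit seeds (integers or `numpy.random.Generator`
streams) and are bit-reproducible.

### What passing tests do and do not show

The generators realize exactly the assumptions the analyses make (Poisson
spiking, instantaneous rate steps, memoryless poking). Passing recovery
tests therefore demonstrates the *implementation* is correct and
calibrated under those assumptions; they say nothing about robustness to
bursty or adapting neurons, rate drift, history-dependent poking, or
tracking noise, all of which real recordings contain.

## Problem sizes and numerical choices

The calibration and recovery checks run at the protocol's native scale
(100 trials; 1000 null units for type-I calibration; 150–163 units for
mixture recovery; 40 replicates per latency condition; 200 behavioral
replicates; 1000 random logs for the burst oracle), sizes at which the
99% acceptance intervals are decisive while the whole suite runs in
seconds. Statistical acceptance bands are 99% intervals around the
nominal value, so individual checks carry ~1% seed risk by design.
Windows must be integer multiples of the bin width (validated);
window/bin arithmetic uses rounded integer bin indices so no tolerance
accumulates; CSV readers use round-trip float parsing so write→read is
bit-exact.

## Known limitations

* No spike sorting, waveform or probe-geometry handling; inputs are
  already-sorted spike times.
* Per-unit classification is uncorrected for multiple comparisons (by
  design, see above).
* The paired t-test's mild anticonservatism on very short windows at low
  rates is inherited, not corrected.
* Burst gaps are onset-to-onset; if poke durations matter,
  offset-to-onset gaps would need poke-off timestamps the input format
  does not carry.
* Group-level hypothesis testing (ANOVAs across subjects/groups) is out
  of scope; the pipeline emits per-session descriptive metrics.
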