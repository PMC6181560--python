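# selfstim

Analysis tools for optogenetic self-stimulation experiments: per-unit
classification of stimulus-evoked spike-train responses, and operant
nosepoke behavior metrics, with synthetic-data generators that make every
analysis stage testable by parameter recovery.

## Who this is for

Labs running intracranial (optogenetic) self-stimulation tasks in rodents
typically collect two kinds of data:

1. **In vivo electrophysiology** — single-unit spike trains recorded while
   stimulation is delivered repeatedly (the reference protocol here is 1 s
   of stimulation every 10 s for 100 trials), and
2. **Operant behavior** — timestamped nosepokes on an active (laser-paired)
   and an inactive port over 30-min sessions, with a 15-min extinction
   session and open-field locomotion controls.

`selfstim` packages the standard analyses of both as a tested library with
a thin CLI, instead of one-off analysis scripts.

## The statistics at the core

**Spike trains.** For each unit, spikes are binned at Δ = 10 ms aligned to
stimulus onset (half-open bins) to form a peri-event time histogram
(PETH). Writing μ, σ for the mean and sample SD of the trial-averaged rate
over the 1 s pre-onset baseline, the z-scored PETH is
`z_b = (r_b − μ)/σ` (undefined, and flagged, when σ = 0). Modulation in a
response window `w ∈ {20 ms, 100 ms, 1 s}` is decided by a two-sided
paired t-test of per-trial firing rates, window vs 1 s baseline: units with
p < 0.05 are *excited* or *inhibited* by the sign of the mean difference,
otherwise *unmodulated*. Effect size is the modulation index

    MI = (r_resp − r_base) / (r_resp + r_base) ∈ [−1, 1].

Latency to modulation is detected from trial-summed counts per bin: with
λ = baseline rate × Δ × n_trials, the latency is the start of the second
bin of the earliest pair of consecutive bins falling outside the
equal-tailed 97% Poisson region for λ, searched within 100 ms of onset.
At the population level the package reports response-type fractions per
window, the mean z-scored PETH over units, and an across-unit Wilcoxon
signed-rank test of stimulation-second vs baseline-second firing.

**Behavior.** Per session: active/inactive counts, poke rates, cumulative
response curves, inter-poke interval distributions, and burst segmentation
(maximal runs of ≥ 2 pokes with onset-to-onset gaps under a 2 s or 6 s
threshold). Across sessions: extinction preference for the previously
laser-paired side, and the exclusion rules (day-4 active count declined
below 50% of day 1, or < 1 active poke/min averaged over four sessions).
Locomotion tracks are summarized as per-epoch path length over repeated
pre / laser / post / recovery cycles.

## Worked example

```python
from selfstim import (StimulusProtocol, StimulusResponseModel,
                      OperantSessionModel, AgentSpec,
                      simulate_population, simulate_operant_session)

protocol = StimulusProtocol.regular(n_trials=100)          # 1 s stim / 10 s
trains, truth = simulate_population(60, (0.6, 0.2, 0.2), protocol, seed=7)
print(StimulusResponseModel(trains, protocol).fit().summary())

log, _ = simulate_operant_session(AgentSpec(), seed=7, session_id="m01_day1")
print(OperantSessionModel(log).fit().summary())
```

prints

```
Stimulus-response classification
================================================
Units: 60   trials: 100   bin: 10 ms   alpha: 0.05
Baseline vs stimulation (signed-rank, across units): p = 8.438e-06

  window    excited     unmod.  inhibited
    20ms    6 ( 10%)   48 ( 80%)    6 ( 10%)
   100ms   36 ( 60%)   12 ( 20%)   12 ( 20%)
  1000ms   37 ( 62%)   11 ( 18%)   12 ( 20%)

Latency (n=47): median 30 ms, range 10-70 ms

Session m01_day1 (30 min)
================================================
Active pokes:   120  (4.00/min)
Inactive pokes: 24
Mean inter-poke interval (active): 14.7 s
Bursts (<2 s gaps): 4, 2.00 pokes/burst
Bursts (<6 s gaps): 29, 2.31 pokes/burst
```

The simulated population was built 60% excited / 20% inhibited / 20%
null: the fitted 1 s-window fractions (62 / 20 / 18%) recover the mixture
within classification noise, and fewer units clear the bar in the first
20 ms because units with onset delays of 20–50 ms have no effect inside
that window yet. The behavioral session shows the signature of a
reinforced (ChR2-like) agent: responding concentrated on the active port
(120 vs 24) with clustered bursts of poking.

A CLI mirrors the library:

```
selfstim simulate-spikes --n-units 60 --seed 7 --out-dir sim
selfstim analyze-ephys --spikes sim/spikes.csv --protocol sim/protocol.csv --out-dir results
selfstim simulate-behavior --n-chr2 8 --n-eyfp 8 --seed 7 --out-dir beh
selfstim analyze-behavior --events beh/chr200_events.csv --meta beh/chr200_meta.json
```

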