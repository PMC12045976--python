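# beatsync

Circular-statistics analysis of sensorimotor beat keeping — for researchers
comparing how different subjects (humans, trained animals, or simulated
performers) synchronize repeated movements with an isochronous auditory
stimulus such as a metronome.

## What it computes

Each movement event (the low point of a head bob or arm chop) is matched to
its nearest beat of the stimulus grid and assigned a relative phase

&nbsp;&nbsp;&nbsp;&nbsp;θᵢ = 360 · (t_moveᵢ − t_beatᵢ) / dt &nbsp;&nbsp; (degrees, wrapped to (−180, 180])

where *dt* is the beat period. Negative phase means the movement precedes the
beat (negative mean asynchrony). A set of phases is summarized by its
circular mean direction θ̄ and mean resultant length

&nbsp;&nbsp;&nbsp;&nbsp;R̄ = |N⁻¹ Σₙ e^{iθₙ}| ∈ [0, 1],

with circular standard deviation √(−2 ln R̄). On top of these descriptives
the package provides:

- **Hypothesis tests** (`beatsync.circ_tests`): the Rayleigh test of
  uniformity (`z = N R̄²`, higher-order series p-value) — rejection indicates
  *entrainment*; the V-test against a specified mean angle
  (`u = R̄ cos(θ̄ − μ₀) · √(2N)`) — rejection at μ₀ = 0 indicates
  *synchronization*; and the Watson-Williams F test of homogeneity of mean
  directions across groups, with the standard `1 + 3/(8κ̂)` correction and a
  low-concentration warning.
- **Per-trial and per-subject summaries** (`beatsync.phase_metrics`):
  performed tempo (mean instantaneous 60/interval by default), interval and
  tempo SDs, circular phase means, vector lengths.
- **A Monte Carlo simulator of human beat keeping**
  (`beatsync.human_simulator`): real trials are screened (vector length
  ≥ 0.4), pooled by tempo, and summarized in sliding windows of 4 movements
  (normal fit for intervals, von Mises fit for phases; 22 windows for
  25-movement trials). Simulated trials are grown movement-by-movement with
  rejection sampling of each implied phase against its window's von Mises
  density, on a 29-beat grid starting at t = 0. An individual's per-trial
  mean interval and phase are then z-tested against the 10,000-trial cohort,
  and exceedance fractions report how much of the cohort the individual
  beats.
- **Comparison procedures** (`beatsync.comparisons`): rank tables
  (tempo error, interval SD, |phase|, vector length — ties don't count as
  wins), first-vs-last-trial learning checks, pooled first-12 vs last-12
  movement drift tests, and subject-vs-group phase tests.
- **A synthetic study generator** (`beatsync.synthetic_data`): a seeded
  generator for a full study (ten humans + one expert, 3 tempos × 4 trials ×
  25 beats) with known per-subject mean asynchrony, von Mises concentration,
  tempo bias and within-trial drift, plus a ground-truth table for
  parameter-recovery testing.

## Worked example

```python
import numpy as np
import beatsync as bs

# a 25-movement trial at 120 bpm, moving ~40 ms ahead of each beat
trial = bs.MovementTrial(
    "s01", "human", 120.0, 1,
    tuple(i * 0.5 - 0.04 + 0.005 * np.sin(i) for i in range(25)),
)
grid = bs.make_beat_grid(120.0, 25, 0.0)

s = bs.summarize_trial(trial, grid)
print(f"phase {s.mean_phase_deg:.1f}  R {s.vector_length:.3f}  "
      f"tempo {s.performed_tempo_bpm:.2f}  sd {s.sd_tempo_bpm:.2f}")

series = bs.compute_phase_series(trial, grid)
r = bs.rayleigh_test(series.phases_deg)
v = bs.v_test(series.phases_deg, 0.0)
print(f"rayleigh z {r.statistic:.2f} p {r.p_value:.2e} ; "
      f"v u {v.statistic:.2f} p {v.p_value:.2e}")
```

prints

```
phase -28.8  R 0.999  tempo 120.05  sd 0.82
rayleigh z 24.95 p 1.25e-10 ; v u 6.19 p 2.99e-10
```

The mean phase of −28.8° says the subject's movements land 40 ms before each
beat (−0.04/0.5 · 360); R̄ ≈ 1 says that asynchrony is highly repeatable. The
Rayleigh test rejects uniformity (the subject is entrained) and the V-test
rejects at μ₀ = 0 (the subject is synchronized, not merely entrained).

## Command line

```bash
beatsync --seed 3 synth --out-dir study/           # synthetic study + ground truth
beatsync summarize --trials study/trials.csv --out trial.csv --subject-out subj.csv
beatsync test --trials study/trials.csv --out tests.csv
beatsync --seed 5 simulate --trials study/trials.csv --tempo 120 --out-prefix sim
beatsync compare --trials study/trials.csv --focal expert01 --out-dir cmp/
```

Input tables are long-format CSV (one row per movement event) with columns
`subject_id, group, tempo_bpm, trial_index, event_index, time_s`; times are
seconds. Data exported from a spreadsheet of per-trial movement timings
should be melted to this layout (one row per movement, indexed within its
trial).

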