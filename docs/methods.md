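# Methods

This note documents the statistical model behind beatsync, the conventions
it fixes where the field leaves choices open, and what its synthetic data
can and cannot tell you about real recordings.

## Phase model and conventions

A trial is a sequence of movement low-point times measured against an
isochronous stimulus of period `dt = 60 / tempo`. Each event is matched to
its **nearest** beat onset and assigned the phase
`θ = 360 (t_move − t_beat) / dt`, wrapped to (−180, 180].

Three conventions are configurable through `AnalysisConfig` because the
field does not fix them:

- **Sign.** The default is movement-minus-beat, so an anticipatory movement
  has negative phase. This matches how negative mean asynchrony is described
  and reported throughout the sensorimotor-synchronization literature. The
  opposite convention (beat-minus-movement, early = positive) is available
  as `phase_sign="beat_minus_movement"`; it negates every phase and circular
  mean and leaves vector lengths and all test statistics unchanged.
- **Tie breaking.** An event exactly half a period between two onsets is
  assigned to the earlier beat by default (`nearest_beat_tie`). Ties have
  measure zero for continuous data; the rule only matters for quantized
  inputs (e.g. video frames).
- **Performed tempo.** Default is the mean of instantaneous tempos
  `60/interval`, with the SD on the same scale, so tempo variability is
  reported in bpm. The alternative `reciprocal_of_mean_interval` is exactly
  the reciprocal of the mean interval; it is unbiased under symmetric
  interval noise, whereas the instantaneous mean carries a small Jensen
  bias upward (≈ tempo · cv² of the intervals). Both are exposed; analyses
  that compare a recovered tempo against a known generating tempo should
  prefer the reciprocal form.

Events farther than half a period outside the beat grid are excluded from
the phase series (counted and logged), but still contribute to the interval
series: intervals are successive differences of all event times. Multiple
events mapping to one beat, and beats with no event, are permitted.

Angles are degrees everywhere in the public API; radians appear only inside
the math kernels. Time is seconds at arbitrary resolution — the 240 fps
(4 ms) provenance of frame-scored video data is not assumed or enforced.

## Circular tests

- **Rayleigh**: `z = N R̄²`, p-value from the standard higher-order series
  `p = e^{−z}[1 + (2z − z²)/(4N) − (24z − 132z² + 76z³ − 9z⁴)/(288N²)]`,
  clamped to [0, 1]. The simple `e^{−z}` approximation is noticeably
  anticonservative at small N; the series keeps the empirical type-I error
  at α within ±0.01 down to N = 10 (verified by simulation in the test
  suite).
- **V-test**: `V = R̄ cos(θ̄ − μ₀)`, `u = V√(2N)`, one-tailed upper normal
  p-value. Its p is minimized over μ₀ at the sample circular mean.
- **Watson-Williams**: `F = K (N−k)(ΣRⱼ − R) / ((k−1)(N − ΣRⱼ))` on the
  unnormalized resultant lengths, `K = 1 + 3/(8κ̂)` with κ̂ the ML von Mises
  concentration at the weighted mean of group R̄ⱼ, referred to
  `F(k−1, N−k)` — the df convention is stated in every result object. When
  the weighted mean resultant length falls below 0.45 the test proceeds but
  attaches a warning rather than refusing: beat-keeping data from gross
  movements can be very dispersed (trial vector lengths down to ~0.02), and
  refusing would make the comparison procedures unusable exactly where they
  are needed. At high concentration (κ ≈ 50) the statistic converges to the
  linear one-way ANOVA F on unwrapped angles (checked to 5%).
- **κ estimation** inverts `A(κ) = I₁(κ)/I₀(κ)` with Fisher's piecewise
  initial approximation plus Newton refinement (exponentially scaled Bessel
  functions for stability); round-trips through A(κ) to 1e−6. R̄ = 1 is a
  domain error; callers fitting degenerate (constant-phase) windows clip R̄
  to 1 − 1e−10, which caps κ at 1e6.

No multiple-testing correction is applied anywhere; outputs are raw
p-values, and the comparison tables document that.

## Monte Carlo simulator

The simulator deliberately avoids assuming any parametric trend in phase or
interval across a trial. Screened trials (mean vector length ≥ 0.4 — the
boundary itself is kept; only strictly smaller values are removed) are
pooled by tempo and summarized in overlapping windows of width 4: window *k*
pools the phases of movements *k..k+3* across trials, and the intervals
*ending* at those movements. Movement 1 has no interval, so window 1's
interval pool holds the intervals of movements 2–4; this is the one place
the windowing is genuinely ambiguous, and the choice is recorded here rather
than silently made. With 25-movement trials this yields 22 windows. Each
window gets a normal interval fit (mean, SD) and a von Mises phase fit
(circular mean, κ̂).

Simulated trials run on a 29-beat grid with the first onset at t = 0 (the
four extra beats absorb trials that drift past the nominal 25). Movement 1's
phase is drawn directly from window 1's von Mises (no rejection step is
needed; the draw is exact). For each subsequent movement *n*:

1. the generating window is the one whose **last** member is movement *n*
   (`window = clamp(n − width + 1, 1, n_windows)`), conditioning each
   movement on its most recent history; the alternative `clamp(n, …)`
   indexing would lead the history and is not used;
2. an interval is drawn from that window's normal (negative draws are
   rejected outright);
3. the implied phase against the nearest beat is accepted with probability
   `f_VM(θ; μ_w, κ_w) / f_VM(μ_w; μ_w, κ_w) = exp(κ_w (cos(θ − μ_w) − 1))`
   — the mode-normalized density, the standard rejection envelope; on
   rejection only the interval is redrawn, not the trial;
4. after 24 accepted movements the trial's circular mean phase, mean
   interval and vector length are recorded.

A configurable rejection budget (default 10,000 per movement) turns an
internally inconsistent model (e.g. interval means incompatible with a
tightly concentrated phase window) into an explicit `SimulationError`
naming the movement and window instead of a hang.

Cohorts are fully determined by `(models, seed)`. Aggregates report the
cohort tempo scale in bpm (mean and SD across the trial mean tempos) *and*
the mean interval in seconds, labelled unambiguously, because "interval"
columns in this literature sometimes carry bpm-scale values. The cohort SD
of tempo is the SD across trial means (≈ 1 bpm for human-like fits), not
the pooled within-trial SD.

The z-test against a cohort treats the 10,000 per-trial means as
approximately normal (phases compared on the linear degree scale after
wrapping); the exceedance fractions — the share of cohort trials with
|mean phase| larger than the observed one, and the share with mean phase
more negative — are exact counts and carry no normality assumption.

## Synthetic data generator

The generator emulates the study design the analysis targets: ten human
subjects plus one expert, three tempos (112/120/128 bpm), four trials per
tempo, 25 beats per trial — 132 trials in all.

Phases are generated **beat-anchored**: the movement for beat *k* occurs at
`onset_k + phase_k/360 · period` with
`phase_k = μ + k·δ + von Mises(0, κ) noise`. This makes the ground-truth
phase parameters exact and lets recovery tests compare against analytic
expectations. A per-subject tempo bias *b* cannot coexist with a stationary
phase in a beat-anchored world, so it is realized through its mathematically
equivalent per-beat drift `δ_bias = −360·b/(tempo + b)` (a fast subject
lands earlier each beat); the exported ground truth therefore includes the
analytically expected per-trial mean phase `μ + δ_total·(n−1)/2` and
performed tempo `tempo/(1 + δ_total/360)`, which is what the pipeline
should recover. An `interval_walk` mode (noisy intervals accumulated with
no phase correction) exists for stress tests; `interval_cv` adds optional
white timing jitter on top of the phase noise (default 0, so interval
variability derives entirely from the phase noise — e.g. κ = 8 implies an
instantaneous-tempo SD near 8 bpm at 120 bpm, inside the range gross
movements produce).

Default profiles are calibrated so the synthetic study behaves like a
gross-movement beat-keeping experiment: human mean asynchronies around
−8…−30° with concentrations from κ = 0.8 to 12 (trial vector lengths from
≈ 0.2 to ≈ 0.97, so the 0.4 screen actually removes trials), and an expert
with κ = 15 and a slight fast bias (trial R̄ ≈ 0.95, tempo ≈ +0.8 bpm). The
generator does **not** emulate several features of real data: missed or
double movements beyond a simple per-beat skip probability, serial
correlation of successive asynchronies (phase-error correction dynamics),
movement-amplitude effects, or frame quantization. Passing tests therefore
demonstrate that the pipeline is numerically correct and self-consistent,
not that any particular organism behaves like the generator.

## Problem sizes and numerical choices

The test suite simulates 10,000 replicates for the type-I-error oracles
(binomial tolerance ±0.01 around α = 0.05), 10,000 trials per tempo for the
cohort-recovery checks (cohort mean phase within 3° of the pooled screened
generating mean; window interval means within 2 SE on a 4,000-trial refit),
and 10⁵ pooled phases for the κ = 0 uniformity goodness-of-fit (36-bin
chi-square, α = 0.01). The reproduction script simulates the full
3 × 10,000-trial design. Degenerate inputs are handled explicitly: empty
phase sets and zero resultants raise domain/degenerate-direction errors
rather than returning NaN; constant-phase windows cap κ; zero cohort SD is
an error for the z-test.

## Known limitations

- The Watson-Williams correction assumes a common concentration across
  groups; with strongly unequal dispersions the test is approximate (the
  warning threshold flags only the low-concentration case).
- The Rayleigh series p-value is an asymptotic approximation; below N = 10
  its tail accuracy degrades (the exact distribution is not implemented).
- The simulator's per-window normal interval model can, for extreme fitted
  parameters, conflict with its phase model; this surfaces as a
  `SimulationError` rather than being silently repaired.
- The halves comparison pools raw phases across trials rather than
  comparing per-trial means; with strong between-trial heterogeneity the
  pooled test conflates within- and between-trial variation.
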