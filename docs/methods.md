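# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions taken where the underlying
methodology left the design open.

## Measurement model

Two instruments observe the same latent daily behavior profile:

* a **diary** reporting one label per 5-minute epoch over the 24-h day
  (sleep, sedentary, LPA, MVPA, or unannotated), and
* a **posture sensor** (criterion) producing an ordered stream of
  seated/standing/stepping events with durations and stepping cadence.

Analyses run on daily minutes per waking behavior. Sleep is excluded
everywhere, using the diary-reported sleep window on both sides (the
sensor cannot distinguish lying asleep from lying awake). MVPA is
operationalized by cadence (> 100 steps/min, strict) rather than energy
expenditure, because event streams carry cadence, not METs; a stepping
event's minutes are assigned wholly to one intensity by its cadence, with
no within-event splitting.

### Cleaning rules and their boundaries

| rule | default | boundary behavior |
|---|---|---|
| diary completion per day | > 0.80 | exactly 80% is **invalid** (strict `>`) |
| device wear per day | ≥ 10 h (validity context) | 8 h available via config |
| nonwear | waking seated run > 10 h | exactly 10 h is **wear** (strict `>`) |
| weekly average | ≥ 3 valid days | 2 valid days drop the week |

Two defensible wear thresholds (8 h and 10 h) exist in the source
methodology; both are exposed (`ClassifierConfig.wear_min_hours`), with
10 h the default. The completion boundary is likewise not specified at
exactly 80%; the strict rule is declared here and tested. The nonwear
detector breaks seated runs at the sleep window: the rule concerns
*sedentary behavior*, which is by definition waking time, and without this
the overnight seated block would merge with ordinary morning sitting and
disqualify most days. The reliability context applies the completion rule
only (it is a diary-only analysis); the validity context applies both.

Uncovered minutes (event gaps) count as neither wear nor any behavior.
Events must be whole-minute aligned and non-overlapping; parsing
proprietary binary exports is out of scope.

## Agreement statistics

* **ICC** — single-measures, absolute-agreement, two-way random effects
  (McGraw & Wong's ICC(A,1)), computed from the ANOVA mean squares, with
  the standard F-based 95% interval. The absolute-agreement form is the
  right one for method comparison because it penalizes systematic offsets.
  Interpretation bands: poor < 0.4 ≤ moderate ≤ 0.8 < strong (both
  boundaries fall in "moderate" per the band wording "0.4–0.8"). When the
  interval is numerically undefined (e.g. perfect agreement, MSE = 0) it
  collapses to the point estimate. Rows with missing cells are dropped
  listwise with a logged count. The validity ICC treats participant-days
  as rows and the two methods as raters; day-level pseudo-replication is
  accepted as the design's own choice, and per-period fitting is available
  (`icc_pooling="per_period"`).
* **δ and RMSE** — δ = mean(diary − device) with a t-based CI (undefined,
  by error, at n = 1); RMSE = √(Σd²/n). The identity
  RMSE² = δ² + (n−1)/n·Var(d) is property-tested.
* **Bland–Altman** — bias ± 2·SD(d). The multiplier is exactly 2, not
  1.96, following the formula the workflow is built around.
  Heteroscedasticity is declared when Kendall's τ(|d|, mean) > 0.1; the
  analysis then uses log₁₀ data and reports the limits as a function of
  the mean, half-width 2·mean·(10^SD − 1)/(10^SD + 1). Zeros ahead of the
  log (certain for MVPA) are replaced by half the smallest positive value
  of that variable, with a logged count; negative values are an error.
  Proportional bias is the least-squares slope of d on the pair mean
  (standard practice; the methodology names only "linear regression").
* **Stratified ICCs** — per participant and per hour of day (hourly
  minute totals from both methods, sleep excluded). Strata below 2
  complete pairs degrade to "missing with counts" rather than erroring. A
  generic OLS hook (`regress_on_covariates`) regresses per-stratum ICCs on
  covariates; no cohort-specific coefficients are reproduction targets.

## Responsiveness

Stability is classified from the **criterion** change between the two
periods: stable iff |Δ| < 30 (sedentary), 30 (LPA), 10 (MVPA) min/day,
strict. Substantial change uses the complementary inclusive directional
rule (sedentary ≤ −30, LPA ≥ +30, MVPA ≥ +10); the two rules cannot both
hold for one participant, which is property-tested. RS = |mean Δ| /
SD(Δ among stable participants), reported to 2 decimals; the SD uses each
behavior's own stable subset by default (`stable_scope="global"` uses the
intersection). MPE defaults to the aggregate form
100·(mean Δ_diary − mean Δ_device)/|mean Δ_device| because the published
analysis reports a single MPE per behavior; the per-participant mean of
relative errors is available (`mpe_mode="per_participant"`, excluding
zero-denominator participants with a logged count). The exact published
MPE formula is not recoverable from its source, so printed MPE values are
not reproduction targets.

## Synthetic-data generator

The generator is the package's test harness: it emulates the paired
measurement structure with known truth, not physiology.

**Latent truth.** Each participant-day allocates 1440 minutes. Waking
targets are `mean_minutes[b] + u_{i,b} + t_{i,d,b} (+ intervention
effect)` with participant effects `u_{i,b} ~ N(0, (σ_p·r_b)²)` and
day-level truth variation `t ~ N(0, (σ_day·r_b)²)`; sleep is the
complementary filler (sleep itself is excluded from all analyses, so its
variation is harmless). The per-behavior dispersion ratios
`r_b = sigma_scale[b]` default to {sedentary 1.0, LPA 0.8, MVPA 0.12},
matching the relative day-level SDs reported for such cohorts
(≈139/112/17 min/day on means ≈695/145/22) — a single absolute SD would be
non-physiologic for MVPA. Minutes are quantized to the 5-minute reporting
grid (largest-remainder), so with identity observation the diary recovers
the truth *exactly*; bouts alternate via a first-order chain with
geometric lengths (mean 30/15/10 min for sedentary/LPA/MVPA), sleep one
contiguous block from midnight. Truth defaults (sleep 580, sedentary 695,
LPA 145, MVPA 20 min/day; 21 participants × 7 days in study weeks 2, 3
and 7) mirror the cohort averages of the targeted validation setting.

**Diary observation.** Epoch label = majority minute label (ties to the
earlier minute), passed through a row-stochastic 4×4 misclassification
matrix (identity by default), with a Beta-distributed per-day completeness
around `annotation_completeness` (concentration 12) and unannotated epochs
placed uniformly at random. Reporting error carries the remaining variance
components: per cohort realization a method bias `v_b ~ N(0,(σ_m·r_b)²)`
and per day a residual `η_{d,b} ~ N(0,(σ_e·r_b)²)` are drawn for LPA and
MVPA and realized by relabeling epochs between that behavior and
sedentary — over-reported activity comes out of sitting, so sedentary
carries the balancing error. In heteroscedastic mode the residual SD is
multiplied by (day's true minutes / behavior mean), producing the
multiplicative error structure that the Kendall-τ screen detects.

**Device observation.** Run-length encoding of the truth: sleep and
sedentary as seated events (adjacent runs merged), LPA as standing or slow
stepping (cadence 55–95), MVPA as fast stepping (105–135). With
probability `nonwear_prob` a seated block of up to 11 h is overlaid at the
end of the day to mimic the device being taken off; such days fail the
wear rule downstream.

**Ground truth.** `true_icc = σ_p²/(σ_p² + σ_m² + σ_e²)` (the dispersion
ratios cancel; all components zero defines ICC 1). This value is *exact*
for the directly emitted participant × method two-way table (one cell per
participant × method per behavior, both method effects drawn i.i.d.),
which exists precisely for ICC oracle testing. For the event-level
pipeline it is approximate: quantization, clamping at zero, epoch-pool
exhaustion and the balancing of sedentary introduce small departures, and
the pipeline's two raters share a single method-effect draw (the device is
the reference), so a single realization's ICC converges to
σ_p²/(σ_p² + v² + σ_e²) for that realization's v. Parameter-recovery
tests therefore use the emitted table with σ_m = 0 — with only two raters,
a nonzero method variance makes the single method-effect draw dominate the
estimator's spread for *any* estimator, which is a property of the
two-way random model, not of the implementation.

**What the generator does not emulate.** Raw accelerometry, posture
transitions inside epochs, context labels, day-to-day autocorrelation,
reactivity to the intervention beyond a constant shift, and informative
missingness (unannotated epochs are missing completely at random). Passing
tests therefore demonstrate correctness of the statistics and filters
under the declared error model, not the field accuracy of any instrument.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts scaled to the statistic under test:
identity pipeline 21 × 21 days; parameter recovery n = 500 (3 seeds) and
CI coverage 200 replicates at n = 50; heteroscedasticity rates 200
replicates at n = 100 (constructed pairs) and 60 generator replicates at
15 × 7 days; limits-of-agreement coverage n = 10 000. Random state is
NumPy `default_rng` seeded from the config; per-day generators are spawned
from the master stream, so identical config + seed gives bitwise-identical
outputs. Undefined Kendall τ (fully tied input) is treated as
homoscedastic with a warning; zero total variance makes the ICC an error
rather than a silent 1.0; an empty valid-day set is an explicit error, not
empty output.

## Known limitations

* The diary-derived sleep window couples the two instruments: diary sleep
  misreporting propagates into device totals, as in the real protocol.
* Event streams crossing midnight are not split automatically; days run
  midnight-to-midnight local time with half-open [start, start+5 min)
  epochs.
* The variance-component semantics of the event-level pipeline are
  approximate for LPA/MVPA near the zero floor (clamping makes genuinely
  heteroscedastic data — which is also why the floor-adjacent behaviors
  are the ones flagged heteroscedastic in practice).
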