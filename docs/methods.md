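# Methods

## Scope and data model

The package analyses two-arm randomized trials with a delay-control design:
both arms receive the identical 12-week intervention, the immediate group (IG)
at randomization and the delay group (DG) 13 weeks later, with assessments at
weeks 0, 13 (primary endpoint), 26 and 39. The raw outcome material is
minute-epoch wearable data — per minute: a MET estimate, a step count, an
on-body flag and an asleep flag — from a device worn 24 h/day for 7 days per
assessment. Questionnaire subscales (knee symptoms/function 0–100,
self-management 0–96, depression 0–27, habit strength and planned-behaviour
constructs 1–7) are taken as bounded scores; item-level scoring is out of
scope, as are device internals (MET estimation) and recruitment logic.

## Bout detection

A bout rule has a MET cut-point and direction, a minimum duration, an
interruption allowance, and a waking-hours restriction. The defaults:
MVPA ≥3.0 MET / ≥10 min / interruption runs ≤2 min; purposeful activity
≥4.0 MET / ≥10 min / runs ≤2 min; sedentary behaviour ≤1.5 MET / ≥20 min /
no allowance, waking hours only.

*Interruption semantics.* "Up to 2 minutes below threshold" is read as a cap
on any **single run** of consecutive sub-threshold minutes inside a bout, with
multiple runs permitted — the dominant convention for tolerance-based bout
definitions, and the only reading under which the 2-minute figure is a
run length. A per-bout **total budget** alternative is selectable
(`interruption_mode="total"`). A proportional reading (interruptions ≤ some
fraction of bout duration) is *not* offered: under maximal extension the
constraint depends on the final duration being extended, so the greedy
segmentation is not well-defined for it.

*Credited time.* A bout contributes its full duration — qualifying plus
tolerated interruption minutes — to daily totals (`credit="full"`), since the
outcome is time accumulated *in bouts*; `credit="qualifying_only"` is
available.

*Algorithm.* A greedy left-to-right maximal-extension scan: start at the first
unconsumed qualifying minute, extend while the interruption tolerance holds,
trim trailing sub-threshold minutes, emit when the window reaches the minimum
duration, resume after the trimmed end. Off-body minutes terminate any
candidate; asleep minutes terminate waking-only candidates. Minutes are
half-open integer indices `[start, end)`; under the run-reading this
segmentation equals the unique set of maximal valid windows (overlapping valid
windows merge, so maximal windows are disjoint), which the test suite verifies
against two independent oracles: an exhaustive O(n²) window enumeration on
short sequences and a linear-time maximal-window construction on full days.
Bout boundaries always qualify by construction; ties are impossible.

## Wear-day and assessment validity

Missing minutes are off-body, never zero-MET — zero-filling would manufacture
sedentary bouts. A day is valid with ≥1140 on-body minutes (19 of 24 h; the
wear protocol is continuous, so a near-complete-day criterion is appropriate —
the exact cutoff is configuration, not hard-coded, because source protocols
rarely state one). An assessment is valid with ≥4 valid days, inclusive
bounds. Days are calendar days (midnight-to-midnight) by convention. Steps
count only during on-body waking minutes. The weekly guideline indicator is
mean daily bouted MVPA × 7 ≥ 150 min.

## Effect estimation

With occasion indicators T₁₃/T₂₆/T₃₉ and exposure indicators E₁₂/E₂₅/E₃₈
(weeks since program initiation: IG 0/12/25/38, DG 0/0/12/25 at the four
assessments), the longitudinal model is

y_it = β₀ + β₁·IG_i + γ_t + δ_e(i,t) + b_i + ε_it,  b_i ~ N(0, τ²), ε ~ N(0, σ²)

fitted by REML (random intercept per participant). Reference levels are
week 0 and exposure 0, so the intercept is the DG baseline mean, γ are the
secular trend and δ the intervention effects; the trend contrasts
T₂₆−T₁₃ and T₃₉−T₁₃ are emitted with delta-method SEs. The 2 arms × 4
occasions cell structure is exactly saturated by the 8 mean parameters, so
noiseless data are interpolated exactly.

*Sandwich standard errors.* The cluster-by-participant empirical covariance
A⁻¹(Σᵢ Xᵢ′Vᵢ⁻¹rᵢrᵢ′Vᵢ⁻¹Xᵢ)A⁻¹ with A = Σᵢ Xᵢ′Vᵢ⁻¹Xᵢ and
Vᵢ = σ̂²I + τ̂²J is computed directly (statsmodels does not expose it for
mixed models). No small-sample correction is applied by default; a CR1-style
G/(G−1) factor is available (`correction="cr1"`). With ~50 clusters the
uncorrected estimator's simulated type-I error at nominal 5% is ≈6.5%
(mildly anti-conservative, as expected for CR0-type estimators). CIs are
large-sample normal (±1.96·SE) for sandwich estimates.

*Boundary fits.* When the REML solution sits on the τ²=0 boundary, scipy
optimizers can fail outright ("singular matrix"); the fit then falls back to
the boundary solution itself — OLS on the fixed-effects design with τ²=0 —
after retrying lbfgs → powell → Nelder-Mead. A response that the design
interpolates exactly (zero residual) is detected first and returned as the
OLS solution with zero SEs. `random_intercept=False` forces the τ²=0 model,
which is the OLS-degeneracy check used in the tests.

*ANCOVA.* The primary-endpoint analysis regresses the week-13 value on the
arm indicator and the baseline value, complete-case at the endpoint;
t-intervals on the residual degrees of freedom. Block adjustment is a flag,
default off. Guards: ≥3 complete cases per arm, nonzero baseline variance,
full-rank design (aliased columns are named on failure).

*Missing data.* The mixed model uses all available rows (valid under missing
at random); ANCOVA is complete-case at the endpoint. Nobody is excluded by
adherence (intention-to-treat). No imputation machinery is provided — the
estimand is documented instead of guessing an imputation model.

*Power.* `power_two_sample` is the standard noncentral-t computation for the
pooled-variance two-sample t-test. For the planning-stage inputs
(75.5 (SD 54.3) vs 50.0 (SD 46.8), n=50, α=0.1 one-sided) it yields ≈68%,
not the 74% sometimes quoted for those inputs — 74% corresponds to n≈60; the
computation is implemented as standard and the discrepancy left as is.

## Synthetic-trial generator

The generator is the package's test bed: it emulates rosters (permuted
variable blocks, sizes {2,4}, 1:1 allocation, block-size draws constrained to
tile the sample so arm totals are exactly equal), minute-epoch streams,
questionnaire tables and adherence logs from known parameters, all
reproducible from one seed.

*Outcome model.* Latent mean daily bouted MVPA follows exactly the estimand
model above (arm baseline + trend + exposure effect + participant intercept).
Daily values are gamma-distributed around the latent mean — right-skewed, SD
can exceed the mean, as bouted MVPA in this population is — with shape chosen
so the 7-day assessment mean has SD `residual_sd`; an outlier mixture
(default 4%) shifts a participant's intercept by +320 min/day, mirroring the
occasional >300 min/day individuals seen in such data. Negative latent means
produce zero days (activity cannot be negative). Zero clamping makes the
observable arm contrast slightly smaller than the configured effect when
appreciable probability mass sits below zero; the effect-recovery simulations
therefore use baseline 70, participant SD 25, residual SD 20 — still the
scale of this population's activity data, with clamping mass ≈0.3% — so the
generating process matches the estimators' linear estimand. Defaults for
general use are baseline 50 / participant SD 35 / residual SD 25.

*Epoch synthesis.* Each day's integer targets (bouted MVPA, sedentary bout
minutes, steps) are realized constructively: explicit bouts ≥10 min (with
optional legal ≤2-min interruptions), sedentary runs ≥20 min, separated by
≥3 min of 2.0-MET filler so segments cannot merge, plus sub-minimum "junk"
runs that the engine must reject; sleep is 23:00–07:00 (configurable), steps
land only on waking minutes and sum exactly. Running the bout engine over a
synthesized day returns the targets exactly — the round-trip is an invariant,
not an approximation. Daily targets are snapped to feasible values (0 or ≥10
MVPA minutes; 0 or ≥20 sedentary; caps keeping MVPA + sedentary + separators
within the 960-minute waking window), so noiseless-exactness checks use
configurations whose latent values stay ≥10.

*Dropout* is monotone (per-follow-up probability, default 6%, giving ~6/12/17%
cumulative attrition). *Questionnaires* are participant-random-effect + noise
draws clipped to instrument bounds. *Steps* are a per-participant base plus
50 steps per MVPA minute plus noise — the MVPA–steps coupling is a free
parameter, as no joint distribution is established for it.

*What the generator does not emulate:* raw accelerometer signals, device MET
error, within-day autocorrelation of METs beyond the constructed bouts,
informative missingness, and floor/ceiling response styles in questionnaires.
Passing tests therefore demonstrate correctness of the pipeline's logic and
the estimators' statistical behaviour under the stated generating process,
not robustness to device artefacts or informative dropout.

## Fidelity scoring

The three criteria: education session attended; ≥3 of 4 counseling calls;
tracker use — steps recorded on ≥5 days/week ("used" is operationalized as a
recorded step count, per the data source's footnote convention) in ≥11 of the
12 enrollment-aligned program weeks. Percentages are rounded half-up, the
convention consistent with the reference tabulation's per-arm cells
(21/26 → 81, 18/25 → 72). Empty groups get blank percentages, never 0. The
packaged fixture `fixtures/table4_like.csv` is a synthetic 51-record set
constructed to reproduce the reference marginal and joint counts.

## Problem sizes used in verification

The acceptance checks run 1000 random days for bout-oracle agreement, 500
days for the generator round-trip, 2000 simulated trials (n=25/arm) for
ANCOVA recovery/coverage, 1000 null trials for sandwich type-I error, and
100 000 Monte-Carlo replicates per power grid point — sizes at which the
Monte-Carlo error of each summary is well below the decision margins used.
Recovery simulations run at the assessment-summary level; the epoch/bout
layer is exercised by the exact round-trip checks and an end-to-end noiseless
pipeline test instead, where its contribution is bit-exact rather than
statistical.
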