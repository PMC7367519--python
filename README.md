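# actitrial

Analysis pipeline for wearable-based physical-activity trials with a
delay-control (waitlist) design, built around the kind of 12-week counseling
intervention evaluated in knee-osteoarthritis populations: minute-epoch
accelerometry is reduced to bouted activity outcomes, and intervention effects
are estimated with baseline-adjusted ANCOVA and a longitudinal mixed model
that separates secular trend from intervention exposure.

The package is aimed at biostatisticians and methodologists who need a tested,
reproducible implementation of this analysis chain — including a synthetic
trial generator with known ground truth, so every stage can be validated
without access to participant data.

## What it computes

**Bouted activity outcomes.** A *bout* is a sustained episode meeting a MET
cut-point for a minimum duration, optionally tolerating brief sub-threshold
interruptions. Defaults follow the standard accelerometry conventions:

| outcome | MET rule | min duration | interruption allowance |
|---|---|---|---|
| MVPA | ≥ 3.0 | 10 min | runs ≤ 2 min |
| purposeful activity | ≥ 4.0 | 10 min | runs ≤ 2 min |
| sedentary behaviour | ≤ 1.5, waking hours | 20 min | none |

Days need ≥ 19 h on-body time to count; an assessment needs ≥ 4 valid days.
Meeting the activity guideline means ≥ 150 min/week of bouted MVPA.

**Effect estimation.** With assessments at weeks 0/13/26/39 and the delay arm
starting the program in week 14, the mixed model for participant *i* at
occasion *t* is

```
y_it = β0 + β1·IG_i + Σ_w γ_w·1[t = w] + Σ_e δ_e·1[exposure(arm_i, t) = e] + b_i + ε_it
```

with occasion indicators `w ∈ {13, 26, 39}` (secular trend), exposure
indicators `e ∈ {12, 25, 38}` weeks since program initiation (intervention
effects δ — the quantities of interest), and random intercepts
`b_i ~ N(0, τ²)`. The staggered start makes occasion and exposure separately
identifiable. Standard errors are reported model-based and via the
cluster-by-participant empirical (sandwich) estimator. The primary-endpoint
ANCOVA regresses the week-13 value on the arm indicator plus the baseline
value; the arm coefficient is the adjusted mean difference.

**Fidelity scoring.** Participants adhere to the protocol when they attended
the education session, completed ≥ 3 of 4 counseling calls, and had tracker
steps recorded ≥ 5 days/week in ≥ 11 of 12 weeks; per-arm percentages are
summarized with half-up rounding.

## Worked example

```python
import numpy as np
from actitrial import (TrialConfig, generate_trial, build_analysis_dataset,
                       ancova_adjusted_difference, fit_delay_control_lmm)

cfg = TrialConfig(
    n_per_arm=25, participant_sd=25.0, residual_sd=20.0,
    baseline_mean_by_arm={"IG": 70.0, "DG": 70.0},
    true_exposure_effects={0: 0.0, 12: 13.0, 25: 6.0, 38: 3.0},
    true_secular_trend={0: 0.0, 13: 2.0, 26: 4.0, 39: 1.0},
    seed=20260930,
)
trial = generate_trial(cfg, write_epochs=False)
ds = build_analysis_dataset(trial.summaries, trial.roster)

anc = ancova_adjusted_difference(ds, "mvpa_bout_minutes")
print(f"ANCOVA adjusted difference: {anc.estimate:.1f} "
      f"(95% CI {anc.ci_low:.1f} to {anc.ci_high:.1f})")
for e in fit_delay_control_lmm(ds, "mvpa_bout_minutes"):
    if e.term.startswith("E_"):
        print(f"{e.term}: {e.estimate:.1f} (95% CI {e.ci_low:.1f} to {e.ci_high:.1f})")
```

prints

```
ANCOVA adjusted difference: 8.1 (95% CI -2.5 to 18.8)
E_12wk: 9.1 (95% CI -1.1 to 19.3)
E_25wk: -3.6 (95% CI -21.4 to 14.2)
E_38wk: -4.6 (95% CI -32.0 to 22.7)
```

— one simulated trial whose true 12-week effect is 13 min/day of bouted MVPA:
a single n=25/arm trial recovers it only within wide sampling noise (the
estimate here is 8–9 min/day with intervals spanning ~20 min/day), and the
later exposure terms (true values 6 and 3) carry the even wider intervals
typical of a delay design, in which no never-treated arm remains after the
primary endpoint. Averaged over 2000 such trials the ANCOVA estimator is
unbiased (see the verification script below).

The same run is available from a shell:

```
actitrial run-all --config config.yaml --out run1/
```

which writes `summaries.csv`, `results.csv`, `adherence_summary.csv`, a
readable `report.md` and a `manifest.json` of content hashes (identical
config + seed ⇒ identical hashes). Subcommands `simulate`, `process`,
`analyze`, `adherence`, `report` and `recover` expose the individual stages.

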