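# goalshape

Adaptive drinking-limit goal support for text-message alcohol interventions:
a testable implementation of a just-in-time adaptive intervention (JITAI)
for weekend binge drinking in young adults, together with a synthetic cohort
simulator and the cohort-level statistical analysis battery.

## Who this is for

Researchers designing or evaluating SMS-delivered ecological momentary
assessment (EMA) interventions who need (a) a deterministic, replayable
reference implementation of an adaptive step-down goal policy and its
four-day EMA schedule, and (b) a seeded generative model of participant
behavior so that every analysis in the pipeline can be validated by
parameter recovery rather than on sensitive participant data.

## The intervention model

Participants screen in on hazardous-drinking criteria (AUDIT-C ≥ 3 for
women / ≥ 4 for men, ≥ 1 binge day in the prior month, ages 18–25), pass a
2-week assessment-only run-in (≥ 50% EMA compliance), and then opt in to up
to six voluntary 4-week intervention blocks.

Each active week follows a fixed grid: Thursday 17:00 a drinking-plan query
(a *yes* triggers a goal-commitment query), Friday/Saturday 20:00 a goal
reminder plus a 1–5 confidence query when a goal was committed (score < 4
triggers tailored support), Sunday 13:00 the weekend maximum-drinks query
with success/failure feedback.

The prompted weekend limit comes from the running average `x̄` of the
largest number of drinks reported on any occasion over the prior two
weekends:

```
x̄ > 10                      →  limit = 10           (cap)
threshold < x̄ ≤ 10           →  limit = ⌊x̄⌋ − 1      (step-down shaping)
x̄ ≤ threshold                →  limit = threshold − 1 (non-binge floor)
```

with the binge threshold at 4 drinks for women and 5 for men; a goal is met
when the reported weekend maximum does not exceed the limit.

The simulator draws each participant's weekend consumption from a Poisson
model `y_iw ~ Poisson(exp(b0_i + b1·(w−1)))` with `b0_i ~ N(μ_g, σ_g)` per
enrollment-length stratum, and the analysis module recovers `(μ_g, b1_g)`
with a Poisson random-intercept panel regression (adaptive Gauss–Hermite
maximum likelihood; GEE with exchangeable or AR(1) working correlation as
alternatives), alongside compliance tables, goal metrics, Pearson χ² 2×2
tests, exact Wilcoxon signed-rank tests, and the pooled two-sample
proportion test.

## Worked example

```python
from goalshape import SimParams, simulate_cohort
from goalshape.analysis import (
    goal_summary, response_rates, weekend_records_from_log, fit_weekend_trend,
)

params = SimParams(n_participants=50, rng_seed=42)
log, truth = simulate_cohort(params)
m = goal_summary(log)
print("commitment:", m.commitment)
print("goal success:", m.success)

records = weekend_records_from_log(log)
strata = dict(zip(truth.participants.participant_id, truth.participants.stratum))
print(fit_weekend_trend(records, strata=strata)[
    ["stratum", "n_participants", "intercept", "slope", "slope_lo", "slope_hi"]
].round(3).to_string(index=False))
```

prints

```
commitment: 96.1% (146/152)
goal success: 98.2% (111/113)
stratum  n_participants  intercept  slope  slope_lo  slope_hi
   12wk               9      2.062 -0.169    -0.224    -0.115
    4wk               4      2.557 -0.296    -0.375    -0.217
    8wk              15      1.518 -0.182    -0.222    -0.142
 gt12wk              11      0.466 -0.002    -0.037     0.033
```

Commitment and goal-success proportions are reported with their counts
(`% (x/n)`); the trend table gives, per enrollment-length stratum, the
fitted log expected weekend maximum at week 1 (intercept) and its weekly
log-rate-of-change with a 95% CI — here recovering the generative defaults
(e.g. slope −0.34 for the 4-week stratum, ≈ 0 for the longest-enrolled
stratum) from a 50-participant cohort.

The same pipeline is available from the shell:

```bash
goalshape simulate --seed 42 -o run/
goalshape run     --log run/events.jsonl -o run/replay/
goalshape analyze --log run/events.jsonl --screening run/screening.csv \
                  --followup run/followup.csv --truth run/truth_participants.csv \
                  -o run/tables/
goalshape report  --log run/events.jsonl --truth run/truth_participants.csv -o run/tables/
```

Every output file embeds the seed and a configuration hash; identical
(config, inputs) give byte-identical outputs.

## Layout

```
src/goalshape/
  goal_policy.py   adaptive limit policy, binge classification, goal evaluation
  events.py        canonical JSON-Lines event-log schema
  engine.py        deterministic EMA scheduling / tailoring state machine
  screening.py     baseline instruments and eligibility filter
  cohort_sim.py    seeded generative cohort model + screening generator
  analysis.py      compliance, goal metrics, trend models, statistical tests
  config.py        YAML run configuration with stable hashing
  cli.py           simulate / run / analyze / report subcommands
docs/methods.md    model, assumptions, numerical choices, limitations
```
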