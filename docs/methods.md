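# Methods

This note documents the models and procedures goalshape implements, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not establish about real data.

## The adaptive goal policy

The policy operates on the running average `x̄` of the two most recent
*answered* weekend maximum-drinks reports before the current week.
Unanswered weekends are skipped with no limit on look-back; a single
available report is used alone; with no reports at all no goal is prompted
that week (the plan query is still sent). Week 1 goals are based on the two
run-in Sunday reports.

Averages are kept as real numbers and the step-down branch uses
`floor(x̄) − 1`, which guarantees integer limits and, for non-increasing
maxima sequences, non-increasing limits. The policy's stated rules cover
`x̄ > threshold` only; at or below the sex-specific binge threshold
(4 drinks for women, 5 for men) the limit clamps at `threshold − 1`, the
largest non-binge amount, recorded as the `floor` basis. Goal success is
inclusive (`reported ≤ limit`); because the commitment message is worded
"drink less than [X] drinks", the displayed X is `limit + 1` while the
stored limit is the inclusive bound.

Two structural properties hold and are verified exhaustively over all
starting maxima pairs in [0,30]²: every prompted limit lies in
`[threshold − 1, 10]`, and a participant who always drinks exactly the
prompted limit reaches the floor goal in finite time. Note that limits
along such a trajectory need not be monotone when the starting history is
*increasing* (an old high report re-enters the two-weekend window);
monotonicity is guaranteed — and tested over every non-increasing triple in
[0,30]³ — only for non-increasing maxima sequences.

## The EMA engine

The engine is a deterministic state machine over a single study clock.
Prompt times: Thursday 17:00 (plan), Sunday 13:00 (maximum drinks), and
Friday/Saturday 20:00 for the goal reminder and confidence query — the
evening time is a design choice, as only the Thursday and Sunday times are
protocol-fixed. Responses count only within a 24-hour window; late replies
are logged but neither alter state nor count toward compliance. Invalid
values (negative drink counts, confidence outside 1–5) produce a re-prompt
event rather than an error. Confidence below 4 triggers the support
template, 4–5 the reinforcement template; tailored message *content* is
configurable by template id — only the five protocol-fixed assessment
strings are stored verbatim.

Run-in eligibility requires answering at least half of the four run-in
prompts; enrollment and block re-enrollment use a case-insensitive "go"
keyword. Blocks are 4 weeks; at each boundary the participant either opts
in (to a maximum of six blocks) or completes. An unanswered Thursday plan
query means no goal prompt and no weekend reminders that week.

The event log is JSON-Lines, one message or response per line with a schema
version, in a stable (participant, week, day, time, kind, seq) order.
Replay from a log is deterministic and reconstructs states, week closures,
and enrollment decisions exactly; this is the invariant the engine's
correctness tests rest on, together with conservation (every committed goal
is evaluated exactly once iff the Sunday query is answered).

## The generative cohort model

Each participant draws an enrollment-length stratum (defaults weighted
6:8:9:9 over 4-week, 8-week, 12-week and >12-week strata) and a latent
intercept `b0 ~ N(μ_g, σ_g)`; desired weekend maximum consumption in week
`w` is `Poisson(exp(b0 + b1_g (w − 1)))`. Default `(μ_g, b1_g)` are
(2.82, −0.34), (1.60, −0.17), (1.99, −0.13), (0.61, −0.03) — the study
conditions — with σ_g = 0.5 as a realistic between-person spread on the log
scale. Run-in weeks draw at the week-1 rate: extrapolating the trend
backwards would give implausible pre-intervention means under the steepest
slope. Note the week-1 expected count for the 4-week stratum,
exp(2.82) ≈ 17 drinks, reflects that stratum's very heavy drinkers.

Behavioral draws are Bernoulli with defaults at the reported rates:
plan-to-drink declining 0.78 → 0.46 over weeks 1–4 (held thereafter), goal
commitment 0.96, weekend-level high confidence 0.60, Thursday/Sunday
response 0.82, Friday/Saturday confidence response 0.58, run-in response
0.70 with enrollment opt-in 0.82 (jointly matching the ~76% run-in-to-
enrollment yield), and block re-enrollment at the observed conditional
continuation fractions (29/38, 19/29, 9/19, 6/9, 2/6, 1/2), drawn
independently at each boundary. Confidence reports are a two-point mixture:
a weekend-level high/low draw, then a uniform sub-draw within {4,5} or
{1,2,3}.

Adherence is modeled as truncation: a committed, adherent weekend reports
`min(desired, limit)` (probability 0.98 given high confidence, 0.76 given
low); otherwise the desired amount is reported unchanged. This is the
simplest mechanism consistent with inclusive goal success; it implies the
*observed* success proportion equals the adherence probability plus a small
contribution from non-adherent weekends whose desired amount happened to
fall at or under the limit. Calibration tests therefore use
high-consumption settings where that contribution is negligible.

Randomness uses one root seed with a `SeedSequence` substream per
participant, so enlarging a cohort never reshuffles existing participants,
and logs are byte-identical across runs. The simulator drives the real
engine rather than imitating it: every structural invariant of the engine
holds in simulated logs by construction of the interface, not by parallel
implementation.

What the simulator does *not* emulate: day-level drinking microstructure
within a weekend, assessment reactivity in the run-in, correlation between
drinking level and response propensity or re-enrollment, and attrition
mechanisms beyond independent per-boundary Bernoulli draws. Passing
recovery tests therefore demonstrates correctness of the pipeline under the
stated generative assumptions, not validity of those assumptions for any
real cohort.

## Analysis battery

Compliance tables count issued assessment queries and their within-window
replies (at most one per prompt), grouped by block and slot type; groups
with no prompts are absent rather than zero-filled. Goal metrics report
commitment over answered goal prompts, the above-binge share of issued goal
prompts per week, and goal success over committed-and-evaluated weekends,
stratified by the weekend's *lowest* reported confidence (< 4 vs ≥ 4; goal
weekends with no confidence report are excluded from that split only) and
by goal level (above binge threshold vs at it). Every proportion carries
its numerator and denominator.

The weekend-maxima trend model is a Poisson log-link panel regression with
a participant-level Normal random intercept, the week regressor centered at
week 1. It is fitted by adaptive Gauss–Hermite maximum likelihood: 15
Hermite nodes re-centered at each participant's posterior mode (found by
vectorized Newton steps on the strictly concave conditional), L-BFGS-B over
`(β0, β1, log σ)` with the random-intercept SD bounded in [1e-3, 10], GLM
start values, and standard errors from the numerically differentiated
observed information (profiling out the scale when it pins at the
boundary). The fit is deterministic: identical data and settings give
identical estimates. Population-averaged GEE alternatives (exchangeable or
AR(1) within-participant correlation, the autoregressive-residual
refinement) are exposed as options and serve as an independent cross-check;
under a pure random-intercept data-generating process all three agree on
the slope. Strata with fewer than 3 participants, or without repeated
weeks, are skipped with a warning.

Association tests are Pearson chi-square on 2×2 tables without continuity
correction by default (Yates switchable), undefined — with an explicit
error — on zero margins. The Wilcoxon signed-rank test drops zero
differences, midranks ties, and computes an exact two-sided p for up to 25
retained pairs by dynamic programming over the doubled midranks (doubling
makes midranks integral, so the full 2^n sign-assignment distribution is a
polynomial product; the two-sided tail uses the distribution's symmetry);
beyond 25 pairs a tie-corrected normal approximation without continuity
correction is used. The two-sample proportion test is the pooled-variance
z test. No multiple-testing adjustment is applied anywhere.

## Problem sizes in the validation suite

Recovery checks use sizes chosen to make the Monte Carlo error small
relative to the tolerance while keeping the suite quick: trend recovery
runs 20 seeded replicates of 200 participants × 4 weeks per
(intercept, slope) pair with adherence disabled so reported maxima equal
the latent draws; calibration runs a fully compliant 25-participant ×
6-block cohort (≈ 1400 prompt-weeks) against exact binomial 99% intervals;
the adherence-direction check uses 100 seeded replicates of a 14-participant
block. Exhaustive policy checks cover all maxima pairs in [0,30]² and all
non-increasing triples in [0,30]³.

## Known limitations

* The engine models a single study clock; time zones, delivery latency, and
  SMS transport are out of scope (transport is abstracted to the event log).
* One reported anomaly — a participant continuing past the six-block
  maximum — is not representable; the engine enforces the cap.
* The exact rung wording of the 10-rung motivation ladder is not
  reproduced; only the rung→stage mapping contract (two rungs per stage) is
  implemented, and the cut points are a package choice.
* "Weekend day" for the drinking-calendar maxima is Thursday–Sunday,
  matching the EMA observation window.
* Complete-case handling throughout; no imputation of missed EMA.
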