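"""Seeded generative model of a behavioral-trial cohort.

The simulator drives the EMA engine with synthetic participants so that the
resulting event log has the statistical structure the analysis battery
assumes, with full ground truth retained for parameter-recovery tests:

* each participant draws an enrollment-length stratum and a latent Poisson
  intercept ``b0 ~ Normal(mu_g, sigma_g)``; weekly desired weekend maximum
  is ``Poisson(exp(b0 + b1_g * (week - 1)))`` (run-in weeks draw at the
  week-1 rate);
* plan-to-drink, goal commitment, weekend confidence, slot-specific
  nonresponse, and block re-enrollment are Bernoulli draws with configurable
  probabilities;
* adherence is truncation: a committed, adherent weekend reports
  ``min(desired, limit)``; otherwise the desired amount is reported as is.

A single root seed with per-participant substreams makes logs byte-stable:
growing the cohort never reshuffles existing participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import engine as eng_mod
from .engine import Day, Engine, Phase
from .events import Event, MessageEvent, ResponseEvent, Template, sort_key
from .goal_policy import Sex
from .screening import AUDIT_C_CUTOFF, ScreeningRecord, eligible

__all__ = ["SimParams", "SimTruth", "simulate_cohort", "generate_screening",
           "generate_followup"]

#: Enrollment-length strata used for the latent drinking trajectories.
DEFAULT_STRATA = ("4wk", "8wk", "12wk", "gt12wk")


@dataclass
class SimParams:
    """Generative parameters; defaults are the study's reported conditions."""

    n_participants: int = 50
    stratum_labels: Sequence[str] = DEFAULT_STRATA
    stratum_weights: Sequence[float] = (6 / 32, 8 / 32, 9 / 32, 9 / 32)
    intercept_mean: Sequence[float] = (2.82, 1.60, 1.99, 0.61)
    intercept_sd: Sequence[float] = (0.5, 0.5, 0.5, 0.5)
    slope: Sequence[float] = (-0.34, -0.17, -0.13, -0.03)
    # weekly probability of planning to drink; weeks past the schedule's end
    # hold the last value (78% in week 1 declining to 46% by week 4)
    plan_prob_schedule: Sequence[float] = (0.78, 0.67, 0.57, 0.46)
    commitment_prob: float = 0.96
    high_confidence_prob: float = 0.60
    adherence_high: float = 0.98
    adherence_low: float = 0.76
    thu_sun_response_prob: float = 0.82
    confidence_response_prob: float = 0.58
    runin_response_prob: float = 0.70
    enroll_optin_prob: float = 0.82
    reenroll_probs: Sequence[float] = (29 / 38, 19 / 29, 9 / 19, 6 / 9, 2 / 6, 0.5)
    p_female: float = 0.56
    rng_seed: int = 0

    def validate(self) -> None:
        k = len(self.stratum_labels)
        for name in ("stratum_weights", "intercept_mean", "intercept_sd", "slope"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per stratum ({k})")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if abs(sum(self.stratum_weights) - 1.0) > 1e-8:
            raise ValueError("stratum_weights must sum to 1")
        if any(s < 0 for s in self.intercept_sd):
            raise ValueError("intercept_sd entries must be >= 0")
        if not self.plan_prob_schedule:
            raise ValueError("plan_prob_schedule must be non-empty")
        probs = (
            list(self.plan_prob_schedule)
            + list(self.stratum_weights)
            + list(self.reenroll_probs)
            + [
                self.commitment_prob,
                self.high_confidence_prob,
                self.adherence_high,
                self.adherence_low,
                self.thu_sun_response_prob,
                self.confidence_response_prob,
                self.runin_response_prob,
                self.enroll_optin_prob,
                self.p_female,
            ]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth behind a simulated log, for recovery tests."""

    participants: pd.DataFrame  # pid, sex, stratum, b0, slope, enrolled, ...
    weeks: pd.DataFrame  # pid, week, desired, plan, committed, limit, ...

    @property
    def sexes(self) -> Dict[str, Sex]:
        return {
            str(row.participant_id): Sex(row.sex)
            for row in self.participants.itertuples()
        }


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _plan_prob(params: SimParams, week: int) -> float:
    sched = params.plan_prob_schedule
    return sched[min(max(week, 1), len(sched)) - 1]


def simulate_cohort(params: SimParams) -> Tuple[List[Event], SimTruth]:
    """Simulate the full cohort through run-in and voluntary blocks.

    Returns the canonical event log (sorted in stable order) and the ground
    truth. Every prompt the engine emits is logged whether or not it is
    answered; replies outside the simulated response draws simply never occur.
    """
    params.validate()
    engine = Engine()
    log: List[Event] = []
    prows: List[dict] = []
    wrows: List[dict] = []

    for index in range(params.n_participants):
        pid = f"P{index:03d}"
        rng = _participant_rng(params.rng_seed, index)
        sex = Sex.FEMALE if rng.random() < params.p_female else Sex.MALE
        stratum = int(rng.choice(len(params.stratum_labels), p=list(params.stratum_weights)))
        b0 = float(rng.normal(params.intercept_mean[stratum], params.intercept_sd[stratum]))
        b1 = float(params.slope[stratum])
        state = engine.register(pid, sex)

        def desired_max(week: int) -> int:
            rate = np.exp(b0 + b1 * (max(week, 1) - 1))
            return int(rng.poisson(rate))

        def reply(prompt: MessageEvent, value) -> None:
            resp = ResponseEvent(
                participant_id=pid,
                in_reply_to=prompt.event_id,
                week_index=prompt.week_index,
                day=prompt.day,
                value=value,
                seq=prompt.seq,
            )
            log.append(resp)
            log.extend(engine.respond(resp))

        # ----- run-in: Thursday plan + Sunday max only -----
        for _ in eng_mod.RUN_IN_WEEKS:
            week = state.week_in_study
            thu = engine.emit(pid, Day.THU)
            log.extend(thu)
            if rng.random() < params.runin_response_prob:
                reply(thu[0], bool(rng.random() < _plan_prob(params, 1)))
            sun = engine.emit(pid, Day.SUN)
            log.extend(sun)
            desired = desired_max(week)
            responded_sun = rng.random() < params.runin_response_prob
            if responded_sun:
                reply(sun[0], desired)
            wrows.append(
                dict(participant_id=pid, week=week, desired=desired,
                     plan=None, committed=False, limit=None,
                     confidence_high=None, adherent=False,
                     reported=desired if responded_sun else None)
            )
            engine.close_week(pid)

        run_in_ok = (
            state.runin_prompts_issued > 0
            and state.runin_prompts_answered / state.runin_prompts_issued
            >= eng_mod.RUN_IN_COMPLIANCE
        )
        if run_in_ok:
            offer = engine.offer(pid)
            log.append(offer)
            if rng.random() < params.enroll_optin_prob:
                reply(offer, "Go")
        engine.finish_boundary(pid)

        # ----- voluntary 4-week intervention blocks -----
        while state.phase is Phase.ACTIVE:
            week = state.week_in_study
            desired = desired_max(week)
            thu = engine.emit(pid, Day.THU)
            log.extend(thu)
            plan: Optional[bool] = None
            if rng.random() < params.thu_sun_response_prob:
                plan = bool(rng.random() < _plan_prob(params, week))
                before = len(log)
                reply(thu[0], plan)
                goal_prompts = [
                    ev for ev in log[before:]
                    if isinstance(ev, MessageEvent)
                    and ev.template_id is Template.GOAL_COMMIT
                ]
                if goal_prompts:
                    reply(goal_prompts[0], bool(rng.random() < params.commitment_prob))
            committed = state.committed_goal is not None
            limit = state.committed_goal.limit if committed else None
            weekend_high = bool(rng.random() < params.high_confidence_prob)
            for day in (Day.FRI, Day.SAT):
                evening = engine.emit(pid, day)
                log.extend(evening)
                conf_prompts = [
                    m for m in evening if m.template_id is Template.CONFIDENCE
                ]
                if conf_prompts and rng.random() < params.confidence_response_prob:
                    lo, hi = (4, 6) if weekend_high else (1, 4)
                    reply(conf_prompts[0], int(rng.integers(lo, hi)))
            adherent = committed and (
                rng.random()
                < (params.adherence_high if weekend_high else params.adherence_low)
            )
            reported = min(desired, limit) if adherent else desired
            sun = engine.emit(pid, Day.SUN)
            log.extend(sun)
            responded_sun = rng.random() < params.thu_sun_response_prob
            if responded_sun:
                reply(sun[0], int(reported))
            wrows.append(
                dict(participant_id=pid, week=week, desired=desired,
                     plan=plan, committed=committed, limit=limit,
                     confidence_high=weekend_high if committed else None,
                     adherent=adherent,
                     reported=int(reported) if responded_sun else None)
            )
            engine.close_week(pid)
            if state.phase is Phase.BETWEEN_BLOCKS:
                offer = engine.offer(pid)
                log.append(offer)
                p_re = params.reenroll_probs[
                    min(state.block_index, len(params.reenroll_probs)) - 1
                ]
                if rng.random() < p_re:
                    reply(offer, "Go")
                engine.finish_boundary(pid)

        enrolled = state.phase is Phase.COMPLETED
        prows.append(
            dict(participant_id=pid, sex=sex.value,
                 stratum=params.stratum_labels[stratum], b0=b0, slope=b1,
                 run_in_eligible=run_in_ok, enrolled=enrolled,
                 phase=state.phase.value,
                 blocks_completed=state.block_index if enrolled else 0)
        )

    log.sort(key=sort_key)
    truth = SimTruth(
        participants=pd.DataFrame(prows),
        weeks=pd.DataFrame(wrows),
    )
    return log, truth


# --------------------------------------------------------------------- #
# Screening and follow-up generation

_AUDITC_ITEM_P = (0.10, 0.20, 0.30, 0.25, 0.15)  # weights over item scores 0..4
_LADDER_P = (0.19, 0.19, 0.08, 0.08, 0.12, 0.12, 0.08, 0.08, 0.03, 0.03)


def _draw_screening(rng: np.random.Generator, pid: str, want_eligible: bool,
                    p_female: float) -> ScreeningRecord:
    sex = Sex.FEMALE if rng.random() < p_female else Sex.MALE
    for _ in range(200):
        age = int(rng.integers(18, 26))
        items = [int(rng.choice(5, p=_AUDITC_ITEM_P)) for _ in range(3)]
        binge_days = 1 + int(rng.poisson(2.0))
        flags = {f: False for f in
                 ("past_substance_treatment", "psychiatric_treatment", "no_sms_phone")}
        rec = ScreeningRecord(
            participant_id=pid, age=age, sex=sex, auditc_items=items,
            binge_days_past_month=binge_days, exclusion_flags=flags,
            ladder_rung=1 + int(rng.choice(10, p=_LADDER_P)),
            byaacq_items=[bool(rng.random() < 9 / 24) for _ in range(24)],
            nm_assist={
                "cigarettes": str(rng.choice(
                    ["daily", "weekly", "monthly", "never"],
                    p=[0.26, 0.10, 0.10, 0.54])),
                "cannabis": "weekly" if rng.random() < 0.50 else "never",
                "opioids": "monthly" if rng.random() < 0.10 else "never",
            },
            ddq_typical=[int(rng.poisson(l)) for l in (1, 1, 1, 2, 4, 4, 2)],
            ddq_heavy=[int(rng.poisson(l)) for l in (1, 1, 2, 3, 6, 6, 3)],
        )
        if eligible(rec) == want_eligible:
            return rec
        if not want_eligible:
            # force a single violated criterion rather than rejection-sampling
            kind = int(rng.integers(3))
            if kind == 0:
                rec.auditc_items = [0, int(rng.integers(0, 2)), 0]
            elif kind == 1:
                rec.binge_days_past_month = 0
            else:
                rec.exclusion_flags["psychiatric_treatment"] = True
            if eligible(rec) == want_eligible:
                return rec
    raise RuntimeError("could not draw a screening record with the requested status")


def generate_screening(
    params: SimParams,
    n: int,
    eligible_fraction: float = 72 / 117,
    seed_offset: int = 1_000_000,
) -> List[ScreeningRecord]:
    """Generate ``n`` screening records with a configurable eligible mix.

    Eligibility status is drawn Bernoulli(``eligible_fraction``) per record
    and the record constructed to match, so the realized mix is binomial.
    """
    if not 0.0 <= eligible_fraction <= 1.0:
        raise ValueError("eligible_fraction must be in [0, 1]")
    rng = _participant_rng(params.rng_seed, seed_offset)
    return [
        _draw_screening(
            rng, f"S{i:03d}", bool(rng.random() < eligible_fraction), params.p_female
        )
        for i in range(n)
    ]


def generate_followup(
    records: Sequence[ScreeningRecord],
    params: SimParams,
    reduction: float = 0.3,
    seed_offset: int = 2_000_000,
) -> List[ScreeningRecord]:
    """Three-month follow-up reports: drinking and consequence items thinned
    by ``reduction`` on average, everything else carried forward."""
    rng = _participant_rng(params.rng_seed, seed_offset)
    out = []
    for rec in records:
        keep = 1.0 - reduction
        out.append(
            ScreeningRecord(
                participant_id=rec.participant_id,
                age=rec.age,
                sex=rec.sex,
                auditc_items=list(rec.auditc_items),
                binge_days_past_month=int(rng.binomial(rec.binge_days_past_month, keep)),
                exclusion_flags=dict(rec.exclusion_flags),
                ladder_rung=rec.ladder_rung,
                byaacq_items=[bool(b and rng.random() < keep) for b in rec.byaacq_items],
                nm_assist=dict(rec.nm_assist),
                ddq_typical=[int(rng.binomial(v, keep)) for v in rec.ddq_typical],
                ddq_heavy=[int(rng.binomial(v, keep)) for v in rec.ddq_heavy],
            )
        )
    return out
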