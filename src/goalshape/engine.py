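"""Deterministic state machine for the four-day EMA schedule.

Each participant moves through a 2-week assessment-only run-in, then — if at
least half of the run-in prompts were answered and the participant opts in —
through up to six voluntary 4-week intervention blocks. Active weeks follow a
fixed grid on a single study clock:

* Thursday 17:00 — drinking-plan query; a "yes" triggers a goal-commitment
  query whose limit comes from :mod:`goalshape.goal_policy`;
* Friday/Saturday 20:00 — goal reminder plus confidence query, only when a
  goal was committed; a confidence reply below 4 triggers a support message,
  4-5 a reinforcement message;
* Sunday 13:00 — weekend maximum-drinks query, answered with goal success /
  failure-reframing feedback (or plain consumption feedback when no goal was
  committed).

The engine holds no randomness: replaying an event log always reproduces the
same states and emitted messages.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .events import (
    Day,
    Event,
    MessageEvent,
    ResponseEvent,
    Template,
)
from .goal_policy import (
    GoalPrompt,
    Sex,
    WeekendRecord,
    compute_goal_limit,
    evaluate_goal,
    running_average,
)

__all__ = [
    "Phase",
    "Schedule",
    "ParticipantState",
    "emit_prompts",
    "handle_response",
    "run_in_eligibility",
    "block_transition",
    "complete_run_in",
    "close_week",
    "offer_enrollment",
    "match_optin_keyword",
    "Engine",
    "MAX_BLOCKS",
    "WEEKS_PER_BLOCK",
    "RUN_IN_WEEKS",
]

logger = logging.getLogger(__name__)

MAX_BLOCKS = 6
WEEKS_PER_BLOCK = 4
RUN_IN_WEEKS = (-2, -1)
#: Run-in eligibility: fraction of issued prompts that must be answered.
RUN_IN_COMPLIANCE = 0.5
#: Confidence scores below this value trigger tailored support.
LOW_CONFIDENCE_CUTOFF = 4


class Phase(str, enum.Enum):
    RUN_IN = "run_in"
    ACTIVE = "active"
    BETWEEN_BLOCKS = "between_blocks"
    COMPLETED = "completed"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class Schedule:
    """Prompt times on the single study clock."""

    thu_time: str = "17:00"
    evening_time: str = "20:00"  # Friday/Saturday reminders + confidence
    sun_time: str = "13:00"
    offer_time: str = "13:30"  # enrollment / re-enrollment offers


DEFAULT_SCHEDULE = Schedule()


@dataclass
class ParticipantState:
    participant_id: str
    sex: Sex
    phase: Phase = Phase.RUN_IN
    block_index: int = 1
    week_in_study: int = RUN_IN_WEEKS[0]
    committed_goal: Optional[GoalPrompt] = None
    proposed_goal: Optional[GoalPrompt] = None
    plan_to_drink: Optional[bool] = None
    confidence_reports: Dict[str, int] = field(default_factory=dict)
    history: List[WeekendRecord] = field(default_factory=list)
    runin_prompts_issued: int = 0
    runin_prompts_answered: int = 0
    pending_optin: Optional[bool] = None


def match_optin_keyword(value: object) -> bool:
    """Case-insensitive 'go' keyword match for (re-)enrollment replies."""
    return isinstance(value, str) and value.strip().lower() == "go"


def emit_prompts(
    state: ParticipantState, day: Day, schedule: Schedule = DEFAULT_SCHEDULE
) -> List[MessageEvent]:
    """Scheduled prompts for ``day`` given the participant's current state.

    Run-in weeks carry only the Thursday plan and Sunday max-drinks queries.
    Active weeks add Friday/Saturday goal reminders with a confidence query,
    but only when a drinking-limit goal was committed that week. Completed or
    excluded participants receive nothing.
    """
    day = Day(day)
    if state.phase not in (Phase.RUN_IN, Phase.ACTIVE):
        logger.warning(
            "no prompts for participant %s in phase %s",
            state.participant_id,
            state.phase.value,
        )
        return []
    week = state.week_in_study
    pid = state.participant_id
    msgs: List[MessageEvent] = []
    if day is Day.THU:
        msgs.append(
            MessageEvent(pid, week, day, schedule.thu_time, Template.PLAN)
        )
    elif day in (Day.FRI, Day.SAT):
        if state.phase is Phase.ACTIVE and state.committed_goal is not None:
            goal = state.committed_goal
            msgs.append(
                MessageEvent(
                    pid, week, day, schedule.evening_time,
                    Template.GOAL_REMINDER,
                    payload={"limit": goal.limit}, seq=0,
                )
            )
            msgs.append(
                MessageEvent(
                    pid, week, day, schedule.evening_time,
                    Template.CONFIDENCE, seq=1,
                )
            )
    elif day is Day.SUN:
        msgs.append(
            MessageEvent(pid, week, day, schedule.sun_time, Template.MAX_DRINKS)
        )
    if state.phase is Phase.RUN_IN:
        state.runin_prompts_issued += sum(
            1 for m in msgs if m.template_id.is_query
        )
    return msgs


def _reprompt(prompt: MessageEvent, reason: str) -> MessageEvent:
    return MessageEvent(
        prompt.participant_id,
        prompt.week_index,
        prompt.day,
        prompt.slot_time,
        Template.REPROMPT,
        payload={"reason": reason, "original": prompt.template_id.value},
        seq=prompt.seq + 10,
    )


def _validate(prompt: MessageEvent, value: object) -> Optional[str]:
    t = prompt.template_id
    if t in (Template.PLAN, Template.GOAL_COMMIT):
        if not isinstance(value, bool):
            return "expected yes/no"
    elif t is Template.CONFIDENCE:
        if not isinstance(value, int) or isinstance(value, bool) or not 1 <= value <= 5:
            return "confidence must be an integer 1-5"
    elif t is Template.MAX_DRINKS:
        if not isinstance(value, int) or isinstance(value, bool) or value < 0:
            return "drink count must be an integer >= 0"
    return None


def handle_response(
    state: ParticipantState,
    event: ResponseEvent,
    prompt: MessageEvent,
    schedule: Schedule = DEFAULT_SCHEDULE,
) -> Tuple[ParticipantState, List[MessageEvent]]:
    """Apply one reply to the state and return tailored follow-up messages.

    Out-of-range values yield a re-prompt instead of an exception. Replies
    outside the 24 h response window are logged upstream but do not alter
    state and trigger no feedback.
    """
    if not event.received_within_window:
        return state, []
    error = _validate(prompt, event.value)
    if error is not None:
        return state, [_reprompt(prompt, error)]

    pid = state.participant_id
    week = prompt.week_index
    day = prompt.day
    t = prompt.template_id
    out: List[MessageEvent] = []

    if state.phase is Phase.RUN_IN and t in (Template.PLAN, Template.MAX_DRINKS):
        state.runin_prompts_answered += 1

    if t is Template.PLAN:
        state.plan_to_drink = bool(event.value)
        if state.phase is Phase.RUN_IN:
            out.append(_ack(pid, week, day, prompt.slot_time))
        elif event.value:
            avg = running_average(state.history, week)
            if avg is not None:
                goal = compute_goal_limit(avg, state.sex, week_index=week)
                state.proposed_goal = goal
                out.append(
                    MessageEvent(
                        pid, week, day, prompt.slot_time, Template.GOAL_COMMIT,
                        payload={
                            "limit": goal.limit,
                            # wording is "drink less than [X]": display limit+1
                            "displayed_limit": goal.limit + 1,
                            "basis": goal.basis.value,
                            "above_binge": goal.above_binge,
                            "running_average": avg,
                        },
                        seq=prompt.seq + 1,
                    )
                )
    elif t is Template.GOAL_COMMIT:
        if bool(event.value) and state.proposed_goal is not None:
            state.committed_goal = state.proposed_goal
        else:
            state.committed_goal = None
        state.proposed_goal = None
    elif t is Template.CONFIDENCE:
        state.confidence_reports[day.value] = int(event.value)
        low = int(event.value) < LOW_CONFIDENCE_CUTOFF
        out.append(
            MessageEvent(
                pid, week, day, prompt.slot_time,
                Template.SUPPORT_LOW_CONFIDENCE if low
                else Template.REINFORCE_HIGH_CONFIDENCE,
                payload={"confidence": int(event.value)},
                seq=prompt.seq + 1,
            )
        )
    elif t is Template.MAX_DRINKS:
        reported = int(event.value)
        state.history.append(WeekendRecord(week, reported, True))
        if state.phase is Phase.RUN_IN:
            out.append(_ack(pid, week, day, prompt.slot_time))
        elif state.committed_goal is not None:
            met = evaluate_goal(state.committed_goal.limit, reported)
            out.append(
                MessageEvent(
                    pid, week, day, prompt.slot_time,
                    Template.FEEDBACK_SUCCESS if met else Template.FEEDBACK_FAILURE,
                    payload={
                        "limit": state.committed_goal.limit,
                        "reported": reported,
                        "met": met,
                    },
                    seq=prompt.seq + 1,
                )
            )
        else:
            out.append(
                MessageEvent(
                    pid, week, day, prompt.slot_time,
                    Template.FEEDBACK_CONSUMPTION,
                    payload={"reported": reported},
                    seq=prompt.seq + 1,
                )
            )
    elif t in (Template.ENROLL_OFFER, Template.REENROLL_OFFER):
        state.pending_optin = match_optin_keyword(event.value)
    return state, out


def _ack(pid: str, week: int, day: Day, time: str) -> MessageEvent:
    return MessageEvent(pid, week, day, time, Template.ACK, seq=5)


def run_in_eligibility(
    events: Iterable[Event],
    participant_id: Optional[str] = None,
    threshold: float = RUN_IN_COMPLIANCE,
) -> bool:
    """True iff at least ``threshold`` of issued run-in prompts were answered.

    Counts Thursday/Sunday query messages with week index < 1 (and their
    within-window replies) for one participant from an event log.
    """
    issued: Dict[str, MessageEvent] = {}
    answered = 0
    for ev in events:
        if participant_id is not None and ev.participant_id != participant_id:
            continue
        if ev.week_index >= 1:
            continue
        if isinstance(ev, MessageEvent):
            if ev.template_id in (Template.PLAN, Template.MAX_DRINKS):
                issued[ev.event_id] = ev
        elif ev.received_within_window and ev.in_reply_to in issued:
            answered += 1
            del issued[ev.in_reply_to]  # at most one counted reply per prompt
    total = answered + len(issued)
    if total == 0:
        return False
    return answered / total >= threshold


def close_week(state: ParticipantState) -> None:
    """End the current week: record a missing weekend report if the Sunday
    query went unanswered, reset per-weekend state, and advance the week or
    park the participant at a block boundary."""
    if state.phase not in (Phase.RUN_IN, Phase.ACTIVE):
        return
    week = state.week_in_study
    if not any(r.week_index == week for r in state.history):
        state.history.append(WeekendRecord(week, None, False))
    state.plan_to_drink = None
    state.committed_goal = None
    state.proposed_goal = None
    state.confidence_reports = {}
    if state.phase is Phase.RUN_IN:
        if week == RUN_IN_WEEKS[-1]:
            state.week_in_study = 0  # awaiting the enrollment decision
        else:
            state.week_in_study = week + 1
    else:
        if week % WEEKS_PER_BLOCK == 0:
            state.phase = Phase.BETWEEN_BLOCKS
        else:
            state.week_in_study = week + 1


def complete_run_in(state: ParticipantState, opted_in: bool) -> ParticipantState:
    """Resolve the run-in: enroll eligible opt-ins, exclude the rest."""
    if state.phase is not Phase.RUN_IN or state.week_in_study != 0:
        raise ValueError("run-in is not complete for this participant")
    eligible = (
        state.runin_prompts_issued > 0
        and state.runin_prompts_answered / state.runin_prompts_issued
        >= RUN_IN_COMPLIANCE
    )
    if eligible and opted_in:
        state.phase = Phase.ACTIVE
        state.week_in_study = 1
        state.block_index = 1
    else:
        state.phase = Phase.EXCLUDED
    state.pending_optin = None
    return state


def block_transition(state: ParticipantState, opted_in: bool) -> ParticipantState:
    """Apply the voluntary re-enrollment decision at a 4-week block boundary."""
    if state.phase is not Phase.BETWEEN_BLOCKS:
        raise ValueError(
            "block transition requested off-boundary "
            f"(phase={state.phase.value}, week={state.week_in_study})"
        )
    if opted_in and state.block_index < MAX_BLOCKS:
        state.block_index += 1
        state.phase = Phase.ACTIVE
        state.week_in_study += 1
    else:
        state.phase = Phase.COMPLETED
    state.pending_optin = None
    return state


def offer_enrollment(
    state: ParticipantState, schedule: Schedule = DEFAULT_SCHEDULE
) -> MessageEvent:
    """The (re-)enrollment offer sent after the last Sunday of a run-in or
    block; replying 'Go' within 7 days opts the participant in."""
    template = (
        Template.ENROLL_OFFER
        if state.phase is Phase.RUN_IN
        else Template.REENROLL_OFFER
    )
    return MessageEvent(
        state.participant_id,
        state.week_in_study if state.phase is not Phase.RUN_IN else RUN_IN_WEEKS[-1],
        Day.SUN,
        schedule.offer_time,
        template,
        payload={"block_index": state.block_index},
    )


class Engine:
    """Event-log driver: registers prompts, dispatches replies, closes weeks.

    Used both by the cohort simulator (which decides the replies) and by
    :meth:`replay`, which reconstructs all states and engine-emitted messages
    from a stored log. Replay is deterministic.
    """

    def __init__(self, schedule: Schedule = DEFAULT_SCHEDULE):
        self.schedule = schedule
        self.states: Dict[str, ParticipantState] = {}
        self.open_prompts: Dict[str, MessageEvent] = {}
        self.emitted: List[MessageEvent] = []

    def register(self, participant_id: str, sex: Sex) -> ParticipantState:
        state = ParticipantState(participant_id=participant_id, sex=Sex(sex))
        self.states[participant_id] = state
        return state

    def _track(self, msgs: List[MessageEvent]) -> List[MessageEvent]:
        for m in msgs:
            if m.template_id.is_query:
                self.open_prompts[m.event_id] = m
        self.emitted.extend(msgs)
        return msgs

    def emit(self, participant_id: str, day: Day) -> List[MessageEvent]:
        state = self.states[participant_id]
        return self._track(emit_prompts(state, day, self.schedule))

    def offer(self, participant_id: str) -> MessageEvent:
        state = self.states[participant_id]
        return self._track([offer_enrollment(state, self.schedule)])[0]

    def respond(self, event: ResponseEvent) -> List[MessageEvent]:
        prompt = self.open_prompts.pop(event.in_reply_to, None)
        if prompt is None:
            logger.warning("reply to unknown or closed prompt %s", event.in_reply_to)
            return []
        state = self.states[event.participant_id]
        _, out = handle_response(state, event, prompt, self.schedule)
        return self._track(out)

    def close_week(self, participant_id: str) -> None:
        state = self.states[participant_id]
        week = state.week_in_study
        close_week(state)
        # expire any unanswered prompts of the closed week
        for eid in [
            eid
            for eid, m in self.open_prompts.items()
            if m.participant_id == participant_id
            and m.week_index <= week
            and m.template_id not in (Template.ENROLL_OFFER, Template.REENROLL_OFFER)
        ]:
            del self.open_prompts[eid]

    def finish_boundary(self, participant_id: str) -> None:
        """Apply the recorded opt-in decision at a run-in end or block end."""
        state = self.states[participant_id]
        opted = bool(state.pending_optin)
        if state.phase is Phase.RUN_IN and state.week_in_study == 0:
            complete_run_in(state, opted)
        elif state.phase is Phase.BETWEEN_BLOCKS:
            block_transition(state, opted)

    # ------------------------------------------------------------------ #
    @classmethod
    def replay(
        cls,
        events: Iterable[Event],
        sexes: Mapping[str, Sex],
        schedule: Schedule = DEFAULT_SCHEDULE,
    ) -> "Engine":
        """Rebuild participant states from a stored log.

        Query messages in the log (re)open prompts; responses are dispatched
        through :func:`handle_response`; week boundaries are inferred from the
        event stream, closing weeks and applying enrollment / re-enrollment
        decisions exactly as the live engine would.
        """
        eng = cls(schedule)
        current_week: Dict[str, int] = {}

        def advance(pid: str, to_week: int) -> None:
            state = eng.states[pid]
            while (
                state.phase in (Phase.RUN_IN, Phase.ACTIVE)
                and state.week_in_study < to_week
            ):
                eng.close_week(pid)
                eng.finish_boundary(pid)

        for ev in events:
            pid = ev.participant_id
            if pid not in eng.states:
                if pid not in sexes:
                    raise KeyError(f"unknown participant {pid!r}: sex required")
                eng.register(pid, sexes[pid])
                current_week[pid] = ev.week_index
            if ev.week_index > current_week[pid]:
                advance(pid, ev.week_index)
                current_week[pid] = ev.week_index
            if isinstance(ev, MessageEvent):
                state = eng.states[pid]
                if state.phase is Phase.RUN_IN and ev.template_id in (
                    Template.PLAN,
                    Template.MAX_DRINKS,
                ):
                    state.runin_prompts_issued += 1
                if ev.template_id.is_query and ev.event_id not in eng.open_prompts:
                    eng.open_prompts[ev.event_id] = ev
            else:
                eng.respond(ev)
        for pid, state in eng.states.items():
            while state.phase in (Phase.RUN_IN, Phase.ACTIVE):
                eng.close_week(pid)
                eng.finish_boundary(pid)
            if state.phase is Phase.BETWEEN_BLOCKS:
                eng.finish_boundary(pid)
        return eng
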