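"""Canonical event-log types for the SMS intervention.

Every outbound text (``MessageEvent``) and inbound reply (``ResponseEvent``)
is one JSON object on one line of a JSON-Lines log, tagged with a schema
version. Ordering is stable by (participant, week, day, slot time, sequence).

Only the five assessment strings the intervention fixes verbatim are stored
as template text here; tailored support/feedback content is addressed by
template id with configurable text.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Union

__all__ = [
    "SCHEMA_VERSION",
    "Day",
    "Template",
    "MessageEvent",
    "ResponseEvent",
    "Event",
    "LogFormatError",
    "write_log",
    "read_log",
    "parse_event",
    "sort_key",
]

SCHEMA_VERSION = 1

DAYS = ("Thu", "Fri", "Sat", "Sun")


class Day(str, enum.Enum):
    THU = "Thu"
    FRI = "Fri"
    SAT = "Sat"
    SUN = "Sun"


class Template(str, enum.Enum):
    """Message templates. ``is_query`` marks prompts that expect a reply."""

    PLAN = "plan"
    GOAL_COMMIT = "goal_commit"
    GOAL_REMINDER = "goal_reminder"
    CONFIDENCE = "confidence"
    MAX_DRINKS = "max_drinks"
    ACK = "ack"
    SUPPORT_LOW_CONFIDENCE = "support_low_confidence"
    REINFORCE_HIGH_CONFIDENCE = "reinforce_high_confidence"
    FEEDBACK_SUCCESS = "feedback_success"
    FEEDBACK_FAILURE = "feedback_failure"
    FEEDBACK_CONSUMPTION = "feedback_consumption"
    REPROMPT = "reprompt"
    ENROLL_OFFER = "enroll_offer"
    REENROLL_OFFER = "reenroll_offer"

    @property
    def is_query(self) -> bool:
        return self in _QUERIES


_QUERIES = {
    Template.PLAN,
    Template.GOAL_COMMIT,
    Template.CONFIDENCE,
    Template.MAX_DRINKS,
    Template.ENROLL_OFFER,
    Template.REENROLL_OFFER,
}

#: Assessment wording fixed by the study protocol.
FIXED_TEXT = {
    Template.PLAN: "Do you plan on drinking this weekend?",
    Template.MAX_DRINKS: (
        "Between Thursday and today, what is the MOST drinks you had on any "
        "occasion?"
    ),
    Template.GOAL_COMMIT: (
        "Would you be willing to commit to a goal to drink less than [X] "
        "drinks on any occasion this weekend?"
    ),
    Template.CONFIDENCE: (
        "How confident are you that you will meet this goal on a scale from "
        "1 (not at all) to 5 (completely)?"
    ),
    Template.ACK: (
        "Thanks for completing this assessment. We will check in with you on "
        "[Thursday and Sunday]."
    ),
}


class LogFormatError(ValueError):
    """Raised for malformed event-log lines; carries the line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class MessageEvent:
    participant_id: str
    week_index: int
    day: Day
    slot_time: str  # "HH:MM" on the single study clock
    template_id: Template
    payload: dict = field(default_factory=dict)
    seq: int = 0  # tie-break for several messages in one slot

    @property
    def event_id(self) -> str:
        return (
            f"{self.participant_id}:w{self.week_index}:{self.day.value}:"
            f"{self.slot_time}:{self.template_id.value}:{self.seq}"
        )

    def to_dict(self) -> dict:
        return {
            "v": SCHEMA_VERSION,
            "kind": "message",
            "event_id": self.event_id,
            "participant_id": self.participant_id,
            "week": self.week_index,
            "day": self.day.value,
            "time": self.slot_time,
            "template": self.template_id.value,
            "payload": self.payload,
            "seq": self.seq,
        }


@dataclass(frozen=True)
class ResponseEvent:
    participant_id: str
    in_reply_to: str
    week_index: int
    day: Day
    value: Union[bool, int, str]
    received_within_window: bool = True
    seq: int = 0

    @property
    def event_id(self) -> str:
        return f"{self.in_reply_to}:r{self.seq}"

    def to_dict(self) -> dict:
        return {
            "v": SCHEMA_VERSION,
            "kind": "response",
            "event_id": self.event_id,
            "participant_id": self.participant_id,
            "in_reply_to": self.in_reply_to,
            "week": self.week_index,
            "day": self.day.value,
            "value": self.value,
            "in_window": self.received_within_window,
            "seq": self.seq,
        }


Event = Union[MessageEvent, ResponseEvent]

_DAY_ORDER = {d: i for i, d in enumerate(DAYS)}


def sort_key(event: Event) -> tuple:
    """Stable canonical ordering: (participant, week, day, time, kind, seq)."""
    kind = 0 if isinstance(event, MessageEvent) else 1
    time = event.slot_time if isinstance(event, MessageEvent) else "~"
    return (
        event.participant_id,
        event.week_index,
        _DAY_ORDER[event.day.value],
        time,
        kind,
        event.seq,
    )


def parse_event(obj: dict, line_number: Optional[int] = None) -> Event:
    try:
        version = obj["v"]
        if version != SCHEMA_VERSION:
            raise LogFormatError(
                f"unsupported schema version {version!r}", line_number
            )
        kind = obj["kind"]
        day = Day(obj["day"])
        if kind == "message":
            return MessageEvent(
                participant_id=str(obj["participant_id"]),
                week_index=int(obj["week"]),
                day=day,
                slot_time=str(obj["time"]),
                template_id=Template(obj["template"]),
                payload=dict(obj.get("payload", {})),
                seq=int(obj.get("seq", 0)),
            )
        if kind == "response":
            return ResponseEvent(
                participant_id=str(obj["participant_id"]),
                in_reply_to=str(obj["in_reply_to"]),
                week_index=int(obj["week"]),
                day=day,
                value=obj["value"],
                received_within_window=bool(obj.get("in_window", True)),
                seq=int(obj.get("seq", 0)),
            )
        raise LogFormatError(f"unknown event kind {kind!r}", line_number)
    except LogFormatError:
        raise
    except (KeyError, ValueError, TypeError) as exc:
        raise LogFormatError(f"malformed event: {exc}", line_number) from exc


def write_log(events: Iterable[Event], fh: IO[str], meta: Optional[dict] = None) -> None:
    """Write events as JSON-Lines; an optional meta header goes first."""
    if meta is not None:
        fh.write(json.dumps({"v": SCHEMA_VERSION, "kind": "meta", **meta}) + "\n")
    for event in events:
        fh.write(json.dumps(event.to_dict()) + "\n")


def read_log(fh: IO[str], strict: bool = True):
    """Yield events from a JSON-Lines log.

    ``strict=False`` skips malformed lines and counts them (the count is
    available on the returned iterator's ``.skipped`` after exhaustion); with
    ``strict=True`` a :class:`LogFormatError` names the offending line.
    """
    return _LogReader(fh, strict)


class _LogReader(Iterator[Event]):
    def __init__(self, fh: IO[str], strict: bool):
        self._lines = enumerate(fh, start=1)
        self._strict = strict
        self.skipped = 0
        self.meta: Optional[dict] = None

    def __iter__(self) -> "_LogReader":
        return self

    def __next__(self) -> Event:
        for number, line in self._lines:
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                if self._strict:
                    raise LogFormatError(f"invalid JSON: {exc}", number) from exc
                self.skipped += 1
                continue
            if isinstance(obj, dict) and obj.get("kind") == "meta":
                self.meta = obj
                continue
            try:
                return parse_event(obj, number)
            except LogFormatError:
                if self._strict:
                    raise
                self.skipped += 1
        raise StopIteration
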