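"""Adaptive weekend drinking-limit goal policy.

The policy shapes weekend alcohol consumption toward a low-risk target by
prompting a drinking-limit goal each week based on the running average of the
largest number of drinks the participant reported on any occasion over the
prior two weekends:

* average > 10 drinks            -> the goal is capped at 10 drinks;
* binge threshold < average <= 10 -> the goal steps down to ``floor(avg) - 1``;
* average <= binge threshold      -> the goal rests at the largest non-binge
  amount, ``binge_threshold - 1``.

The binge threshold is sex-specific: >=4 drinks on one occasion for women,
>=5 for men. A goal is "met" when the weekend's reported maximum does not
exceed the committed limit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "Sex",
    "GoalBasis",
    "WeekendRecord",
    "GoalPrompt",
    "binge_threshold",
    "binge_classify",
    "running_average",
    "compute_goal_limit",
    "evaluate_goal",
    "CAP_LIMIT",
]

#: Hard ceiling on any prompted drinking-limit goal, in standard drinks.
CAP_LIMIT = 10


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class GoalBasis(str, enum.Enum):
    """Which branch of the policy produced a prompted limit."""

    CAP = "cap"            # running average above 10: limit held at 10
    STEP_DOWN = "step_down"  # limit is floor(average) - 1
    FLOOR = "floor"        # limit rests at binge_threshold - 1


_BINGE_THRESHOLD = {Sex.FEMALE: 4, Sex.MALE: 5}


def binge_threshold(sex: Sex) -> int:
    """Sex-specific binge threshold in drinks (4 for women, 5 for men)."""
    return _BINGE_THRESHOLD[Sex(sex)]


def binge_classify(sex: Sex, drinks: int) -> bool:
    """True iff ``drinks`` on one occasion constitutes a binge episode."""
    if drinks < 0:
        raise ValueError(f"drinks must be >= 0, got {drinks}")
    return drinks >= binge_threshold(sex)


@dataclass(frozen=True)
class WeekendRecord:
    """One weekend's maximum-drinks report.

    ``week_index`` runs from -2 (first run-in week) through the final
    intervention week; ``max_drinks`` is present iff the Sunday assessment was
    answered.
    """

    week_index: int
    max_drinks: Optional[int]
    responded: bool

    def __post_init__(self) -> None:
        if self.responded != (self.max_drinks is not None):
            raise ValueError("max_drinks must be present iff responded")
        if self.max_drinks is not None and self.max_drinks < 0:
            raise ValueError("max_drinks must be >= 0")


@dataclass(frozen=True)
class GoalPrompt:
    """A prompted drinking-limit goal and how it was derived."""

    week_index: int
    limit: int
    basis: GoalBasis
    above_binge: bool


def running_average(
    history: Sequence[WeekendRecord], week: int
) -> Optional[float]:
    """Running average of the two most recent answered weekend maxima.

    Looks back over all weekends before ``week`` that were actually responded
    to (skipping unanswered ones, with no limit on how far back the two
    reports may lie). Falls back to the single available report when only one
    exists; returns ``None`` when there is no basis for a goal at all.
    """
    if week < 1:
        raise ValueError("goals are only prompted from intervention week 1 on")
    maxima = [
        r.max_drinks
        for r in sorted(history, key=lambda r: r.week_index)
        if r.responded and r.week_index < week
    ]
    if not maxima:
        return None
    recent = maxima[-2:]
    return sum(recent) / len(recent)


def compute_goal_limit(avg: float, sex: Sex, week_index: int = 0) -> GoalPrompt:
    """Map a running average of weekend maxima to a prompted limit.

    Averages above 10 are capped at a 10-drink limit; averages above the
    binge threshold step down to ``floor(avg) - 1``; anything at or below the
    threshold rests at the floor of ``binge_threshold - 1`` drinks (the
    largest non-binge amount).
    """
    if avg < 0:
        raise ValueError(f"running average must be >= 0, got {avg}")
    thr = binge_threshold(sex)
    if avg > CAP_LIMIT:
        limit, basis = CAP_LIMIT, GoalBasis.CAP
    elif avg > thr and math.floor(avg) - 1 >= thr - 1:
        limit, basis = math.floor(avg) - 1, GoalBasis.STEP_DOWN
    else:
        limit, basis = thr - 1, GoalBasis.FLOOR
    return GoalPrompt(
        week_index=week_index,
        limit=limit,
        basis=basis,
        above_binge=limit >= thr,
    )


def evaluate_goal(limit: int, reported_max: int) -> bool:
    """True (goal met) iff the weekend maximum did not exceed the limit."""
    if limit < 0 or reported_max < 0:
        raise ValueError("limit and reported_max must be >= 0")
    return reported_max <= limit
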