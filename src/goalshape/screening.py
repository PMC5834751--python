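"""Baseline instrument scoring and the study eligibility filter.

Instruments: AUDIT-C (3 items, 0-4 each), past-month binge-day count,
the 24-item brief young-adult alcohol consequences questionnaire (B-YAACQ,
dichotomous items summed), a 10-rung motivational ladder coded to stages of
change, NM-ASSIST frequency codes dichotomized for cigarettes / cannabis /
opioids, and the daily drinking questionnaire (DDQ) calendar grid used to
derive the weekend maximum.

Eligibility: age 18-25, AUDIT-C >= 3 (women) / >= 4 (men), at least one binge
day in the prior month, and none of the exclusion flags (past substance-use
treatment, current psychiatric treatment, no SMS-capable phone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Sequence, Union

import pandas as pd

from .goal_policy import Sex

__all__ = [
    "ScreeningRecord",
    "Stage",
    "audit_c_score",
    "eligible",
    "byaacq_sum",
    "ladder_to_stage",
    "ddq_weekend_max",
    "nm_assist_recode",
    "score_frame",
    "read_screening_csv",
    "write_screening_csv",
    "AUDIT_C_CUTOFF",
]

#: Sex-specific hazardous-drinking cutoffs on the AUDIT-C total.
AUDIT_C_CUTOFF = {Sex.FEMALE: 3, Sex.MALE: 4}

AGE_RANGE = (18, 25)

STAGES = (
    "precontemplation",
    "contemplation",
    "preparation",
    "action",
    "maintenance",
)
Stage = str

#: DDQ columns counted as "weekend" days, matching the Thursday-to-Sunday
#: EMA observation window. Grid is indexed Monday..Sunday.
WEEKEND_DAYS = (3, 4, 5, 6)  # Thu, Fri, Sat, Sun

EXCLUSION_FLAGS = ("past_substance_treatment", "psychiatric_treatment", "no_sms_phone")


@dataclass
class ScreeningRecord:
    participant_id: str
    age: int
    sex: Sex
    auditc_items: Sequence[int]
    binge_days_past_month: int
    exclusion_flags: Dict[str, bool] = field(default_factory=dict)
    ladder_rung: int = 1
    byaacq_items: Sequence[bool] = ()
    nm_assist: Dict[str, str] = field(default_factory=dict)
    ddq_typical: Sequence[int] = (0,) * 7
    ddq_heavy: Sequence[int] = (0,) * 7


def audit_c_score(items: Sequence[int]) -> int:
    """Sum of the three AUDIT-C items (each 0-4; total 0-12)."""
    items = list(items)
    if len(items) != 3 or any(not 0 <= int(i) <= 4 for i in items):
        raise ValueError("AUDIT-C requires 3 items each in 0..4")
    return int(sum(items))


def eligible(record: ScreeningRecord) -> bool:
    """Apply the study's full screening filter to one record."""
    score = audit_c_score(record.auditc_items)
    if not AGE_RANGE[0] <= record.age <= AGE_RANGE[1]:
        return False
    if score < AUDIT_C_CUTOFF[Sex(record.sex)]:
        return False
    if record.binge_days_past_month < 1:
        return False
    if any(record.exclusion_flags.get(flag, False) for flag in EXCLUSION_FLAGS):
        return False
    return True


def byaacq_sum(items: Sequence[bool]) -> int:
    """Count of endorsed consequence items (24 dichotomous items)."""
    items = list(items)
    if len(items) != 24:
        raise ValueError("B-YAACQ requires exactly 24 items")
    return int(sum(bool(i) for i in items))


def ladder_to_stage(rung: int) -> Stage:
    """Map a 10-rung motivation ladder to the stage-of-change continuum.

    Two rungs per stage: 1-2 precontemplation, 3-4 contemplation, 5-6
    preparation, 7-8 action, 9-10 maintenance.
    """
    if not 1 <= rung <= 10:
        raise ValueError(f"ladder rung must be in 1..10, got {rung}")
    return STAGES[(rung - 1) // 2]


def ddq_weekend_max(grid: Sequence[int]) -> int:
    """Maximum drinks over the Thursday-Sunday days of a DDQ week grid."""
    grid = list(grid)
    if len(grid) != 7 or any(int(g) < 0 for g in grid):
        raise ValueError("DDQ grid requires 7 non-negative integers Mon..Sun")
    return int(max(grid[d] for d in WEEKEND_DAYS))


_CIG_DAILY = {"daily", "almost_daily"}
_NONE = {"never", "none", ""}


def nm_assist_recode(raw: Dict[str, str]) -> Dict[str, int]:
    """Dichotomize NM-ASSIST frequency codes.

    Cigarettes: less-than-daily = 0, at-least-daily = 1. Cannabis and
    opioids: none = 0, any use = 1.
    """
    cig = str(raw.get("cigarettes", "never")).lower()
    cannabis = str(raw.get("cannabis", "never")).lower()
    opioid = str(raw.get("opioids", "never")).lower()
    return {
        "cig_daily": int(cig in _CIG_DAILY),
        "cannabis_any": int(cannabis not in _NONE),
        "opioid_any": int(opioid not in _NONE),
    }


# --------------------------------------------------------------------- #
# CSV interface

_COLUMNS = (
    ["participant_id", "age", "sex"]
    + [f"auditc_{i}" for i in range(1, 4)]
    + ["binge_days_past_month"]
    + list(EXCLUSION_FLAGS)
    + ["ladder_rung"]
    + [f"byaacq_{i}" for i in range(1, 25)]
    + ["nm_cigarettes", "nm_cannabis", "nm_opioids"]
    + [f"ddq_typical_{d}" for d in "mon tue wed thu fri sat sun".split()]
    + [f"ddq_heavy_{d}" for d in "mon tue wed thu fri sat sun".split()]
)


def record_to_row(record: ScreeningRecord) -> dict:
    row: dict = {
        "participant_id": record.participant_id,
        "age": record.age,
        "sex": Sex(record.sex).value,
        "binge_days_past_month": record.binge_days_past_month,
        "ladder_rung": record.ladder_rung,
    }
    for i, v in enumerate(record.auditc_items, start=1):
        row[f"auditc_{i}"] = int(v)
    for flag in EXCLUSION_FLAGS:
        row[flag] = int(record.exclusion_flags.get(flag, False))
    for i, v in enumerate(record.byaacq_items, start=1):
        row[f"byaacq_{i}"] = int(bool(v))
    for key in ("cigarettes", "cannabis", "opioids"):
        row[f"nm_{key}"] = record.nm_assist.get(key, "never")
    days = "mon tue wed thu fri sat sun".split()
    for d, v in zip(days, record.ddq_typical):
        row[f"ddq_typical_{d}"] = int(v)
    for d, v in zip(days, record.ddq_heavy):
        row[f"ddq_heavy_{d}"] = int(v)
    return row


def row_to_record(row: Union[dict, pd.Series]) -> ScreeningRecord:
    days = "mon tue wed thu fri sat sun".split()
    return ScreeningRecord(
        participant_id=str(row["participant_id"]),
        age=int(row["age"]),
        sex=Sex(row["sex"]),
        auditc_items=[int(row[f"auditc_{i}"]) for i in range(1, 4)],
        binge_days_past_month=int(row["binge_days_past_month"]),
        exclusion_flags={f: bool(int(row[f])) for f in EXCLUSION_FLAGS},
        ladder_rung=int(row["ladder_rung"]),
        byaacq_items=[bool(int(row[f"byaacq_{i}"])) for i in range(1, 25)],
        nm_assist={
            "cigarettes": str(row["nm_cigarettes"]),
            "cannabis": str(row["nm_cannabis"]),
            "opioids": str(row["nm_opioids"]),
        },
        ddq_typical=[int(row[f"ddq_typical_{d}"]) for d in days],
        ddq_heavy=[int(row[f"ddq_heavy_{d}"]) for d in days],
    )


def score_frame(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    """Score a batch of screening records into a tidy frame with the derived
    columns (AUDIT-C total, B-YAACQ sum, stage, weekend maxima, substance
    dichotomies, eligibility) appended."""
    rows = []
    for rec in records:
        row = record_to_row(rec)
        row["auditc_score"] = audit_c_score(rec.auditc_items)
        row["byaacq_sum"] = byaacq_sum(rec.byaacq_items) if rec.byaacq_items else 0
        row["stage"] = ladder_to_stage(rec.ladder_rung)
        row["weekend_max_typical"] = ddq_weekend_max(rec.ddq_typical)
        row["weekend_max_heavy"] = ddq_weekend_max(rec.ddq_heavy)
        row.update(nm_assist_recode(rec.nm_assist))
        row["eligible"] = int(eligible(rec))
        rows.append(row)
    return pd.DataFrame(rows)


def read_screening_csv(path: Union[str, Path]) -> list:
    frame = pd.read_csv(path, comment="#")
    return [row_to_record(row) for _, row in frame.iterrows()]


def write_screening_csv(
    records: Sequence[ScreeningRecord],
    path: Union[str, Path],
    header_comment: str = "",
) -> pd.DataFrame:
    frame = score_frame(records)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)
    return frame
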