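"""Data model for series of N-of-1 trials with daily patient-reported outcomes.

A trial is a 4-week alternating sequence of intervention (A) and control (B)
phases (ABAB or BABA, one week per phase).  Each participant reports two
outcomes daily on a 1-10 visual analog stress scale plus a flag for whether
the exercise was performed.  Missing entries are first-class: a day without a
report is kept as a record with missing outcomes, never zero-filled.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

SEQUENCES = ("ABAB", "BABA")
ARMS = ("mindfulness", "box")
OUTCOME_NAMES = ("stress_today", "stress_next")
STRESS_MIN, STRESS_MAX = 1.0, 10.0

PRO_CSV_COLUMNS = [
    "participant_id",
    "day_index",
    "phase",
    "performed",
    "stress_today",
    "stress_next",
]


class FormatError(ValueError):
    """Raised for malformed input files (wrong header, unreadable cells)."""


class ValidationError(ValueError):
    """Raised when rows violate type/range constraints; lists row numbers."""


@dataclass(frozen=True)
class TrialSchedule:
    """An alternating phase map: ``sequence`` gives the first-phase letter.

    A = intervention, B = control.  Default: 4 phases of 7 days (28 days).
    """

    sequence: str = "ABAB"
    phase_length_days: int = 7
    n_phases: int = 4

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise ValueError(f"sequence must be one of {SEQUENCES}, got {self.sequence!r}")
        if self.phase_length_days < 1 or self.n_phases < 1:
            raise ValueError("phase_length_days and n_phases must be positive")

    @property
    def total_days(self) -> int:
        return self.phase_length_days * self.n_phases

    def phase_of_day(self, day_index: int) -> str:
        """Phase letter ('A' or 'B') for a 1-based study day."""
        if not 1 <= day_index <= self.total_days:
            raise ValueError(f"day_index {day_index} outside 1..{self.total_days}")
        phase_number = (day_index - 1) // self.phase_length_days
        first = self.sequence[0]
        other = "B" if first == "A" else "A"
        return first if phase_number % 2 == 0 else other

    def to_json(self) -> str:
        return json.dumps(
            {
                "sequence": self.sequence,
                "phase_length_days": self.phase_length_days,
                "n_phases": self.n_phases,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrialSchedule":
        d = json.loads(text)
        return cls(d["sequence"], int(d["phase_length_days"]), int(d["n_phases"]))


@dataclass
class PRORecord:
    """One day's report.  ``None`` marks an explicitly missing value.

    ``check_range`` is disabled by the synthetic generator's continuous
    (unclipped) mode, whose latent-scale outcomes exist for parameter
    recovery diagnostics and may leave the 1-10 response scale; data read
    from CSV are always range-checked.
    """

    participant_id: str
    day_index: int
    phase: str
    performed: Optional[bool] = None
    stress_today: Optional[float] = None
    stress_next: Optional[float] = None
    check_range: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.phase not in ("A", "B"):
            raise ValueError(f"phase must be 'A' or 'B', got {self.phase!r}")
        if self.day_index < 1:
            raise ValueError("day_index is 1-based and must be >= 1")
        if not self.check_range:
            return
        for name in OUTCOME_NAMES:
            v = getattr(self, name)
            if v is not None and not (STRESS_MIN <= v <= STRESS_MAX):
                raise ValueError(
                    f"{name}={v} outside [{STRESS_MIN:g}, {STRESS_MAX:g}]"
                )

    def outcome(self, name: str) -> Optional[float]:
        if name not in OUTCOME_NAMES:
            raise ValueError(f"unknown outcome {name!r}")
        return getattr(self, name)


@dataclass
class ParticipantSeries:
    """All daily records of one participant under one schedule.

    ``truth`` optionally carries the simulation ground truth (intercept,
    effect, latent residuals) for cohorts produced by the synthetic module.
    """

    participant_id: str
    schedule: TrialSchedule
    records: list = field(default_factory=list)
    arm: Optional[str] = None
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.arm is not None and self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        self.records = sorted(self.records, key=lambda r: r.day_index)
        days = [r.day_index for r in self.records]
        if len(set(days)) != len(days):
            raise ValueError(f"duplicate day_index for participant {self.participant_id}")
        total = self.schedule.total_days
        for r in self.records:
            if r.day_index > total:
                raise ValueError(
                    f"day_index {r.day_index} beyond schedule length {total}"
                )
            expected = self.schedule.phase_of_day(r.day_index)
            if r.phase != expected:
                raise ValueError(
                    f"participant {self.participant_id} day {r.day_index}: phase "
                    f"{r.phase!r} contradicts schedule {self.schedule.sequence}"
                )

    def observed(self, outcome_name: str):
        """(day_indices, values, treatment_indicator) for non-missing days."""
        days, values = [], []
        for r in self.records:
            v = r.outcome(outcome_name)
            if v is not None:
                days.append(r.day_index)
                values.append(float(v))
        days_arr = np.asarray(days, dtype=int)
        x = np.asarray(
            [1.0 if self.schedule.phase_of_day(d) == "A" else 0.0 for d in days],
        )
        return days_arr, np.asarray(values, dtype=float), x


@dataclass
class CohortDataset:
    """A collection of participant series sharing one primary outcome."""

    participants: list
    outcome_name: str = "stress_today"

    def __post_init__(self) -> None:
        if self.outcome_name not in OUTCOME_NAMES:
            raise ValueError(f"outcome_name must be one of {OUTCOME_NAMES}")
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant_ids must be unique")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    def get(self, participant_id: str) -> ParticipantSeries:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            for r in p.records:
                rows.append(
                    {
                        "participant_id": r.participant_id,
                        "day_index": r.day_index,
                        "phase": r.phase,
                        "performed": r.performed,
                        "stress_today": r.stress_today,
                        "stress_next": r.stress_next,
                        "arm": p.arm,
                    }
                )
        return pd.DataFrame(rows)


def assign_sequence(enrollment_index: int) -> TrialSchedule:
    """Alternating allocation: even enrollment indices get ABAB, odd BABA."""
    if enrollment_index < 0:
        raise ValueError("enrollment_index must be >= 0")
    return TrialSchedule(SEQUENCES[enrollment_index % 2])


def phase_indicator(series: ParticipantSeries) -> np.ndarray:
    """Binary treatment indicator per study day: 1 on A-phase days, 0 on B."""
    sched = series.schedule
    return np.asarray(
        [1 if sched.phase_of_day(d) == "A" else 0 for d in range(1, sched.total_days + 1)],
        dtype=int,
    )


def _parse_optional_float(cell, row_no: int, col: str, errors: list) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    try:
        return float(cell)
    except (TypeError, ValueError):
        errors.append(f"row {row_no}: {col}={cell!r} is not a number")
        return None


def _parse_optional_bool(cell, row_no: int, errors: list) -> Optional[bool]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    s = str(cell).strip().lower()
    if s in ("true", "1", "yes", "1.0"):
        return True
    if s in ("false", "0", "no", "0.0"):
        return False
    errors.append(f"row {row_no}: performed={cell!r} is not a boolean")
    return None


def read_pro_csv(path) -> CohortDataset:
    """Read a long-format daily PRO table.

    Expected header: participant_id,day_index,phase,performed,stress_today,
    stress_next (an optional trailing ``arm`` column is accepted).  Empty
    cells are missing values.  Rows violating type or range constraints are
    collected and reported together with their 1-based data row numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[: len(PRO_CSV_COLUMNS)] != PRO_CSV_COLUMNS:
        raise FormatError(
            f"malformed header: expected {','.join(PRO_CSV_COLUMNS)}, got {','.join(cols)}"
        )
    has_arm = "arm" in cols

    errors: list = []
    by_participant: dict = {}
    order: list = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pid = row.participant_id
        try:
            day = int(row.day_index)
        except ValueError:
            errors.append(f"row {i}: day_index={row.day_index!r} is not an integer")
            continue
        phase = row.phase
        if phase not in ("A", "B"):
            errors.append(f"row {i}: phase={phase!r} must be 'A' or 'B'")
            continue
        performed = _parse_optional_bool(row.performed, i, errors)
        s_today = _parse_optional_float(row.stress_today, i, "stress_today", errors)
        s_next = _parse_optional_float(row.stress_next, i, "stress_next", errors)
        for col, v in (("stress_today", s_today), ("stress_next", s_next)):
            if v is not None and not (STRESS_MIN <= v <= STRESS_MAX):
                errors.append(f"row {i}: {col}={v:g} outside [1, 10]")
                v = None
        if errors and errors[-1].startswith(f"row {i}:"):
            continue
        arm = getattr(row, "arm", None) if has_arm else None
        if arm == "":
            arm = None
        if pid not in by_participant:
            by_participant[pid] = {"rows": [], "arm": arm}
            order.append(pid)
        by_participant[pid]["rows"].append(
            PRORecord(pid, day, phase, performed, s_today, s_next)
        )

    if errors:
        raise ValidationError("; ".join(errors))

    participants = []
    for pid in order:
        info = by_participant[pid]
        recs = sorted(info["rows"], key=lambda r: r.day_index)
        sequence = "ABAB" if recs[0].phase == "A" else "BABA"
        participants.append(
            ParticipantSeries(pid, TrialSchedule(sequence), recs, arm=info["arm"])
        )
    return CohortDataset(participants)


def write_pro_csv(dataset: CohortDataset, path) -> None:
    """Write the dataset in the long CSV format accepted by read_pro_csv.

    Round-trips exactly: missing values become empty cells, booleans
    ``true``/``false``, numbers via repr (so float precision is preserved).
    """
    include_arm = any(p.arm is not None for p in dataset.participants)
    buf = io.StringIO()
    header = PRO_CSV_COLUMNS + (["arm"] if include_arm else [])
    buf.write(",".join(header) + "\n")
    for p in dataset.participants:
        for r in p.records:
            cells = [
                r.participant_id,
                str(r.day_index),
                r.phase,
                "" if r.performed is None else ("true" if r.performed else "false"),
                "" if r.stress_today is None else repr(r.stress_today),
                "" if r.stress_next is None else repr(r.stress_next),
            ]
            if include_arm:
                cells.append(p.arm or "")
            buf.write(",".join(cells) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
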