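"""Data model and I/O for coded patient timelines.

Patient histories are sequences of coded, timestamped events (diagnoses,
procedures, medications, labs) together with admission records and basic
demographics — a deliberately minimal three-table dialect (person, event,
admission) of the OMOP common data model.

Timestamps are stored as integer **minutes since the Unix epoch** so that
calendar arithmetic ("midnight of the day after admission") is exact and
testable.  On disk all timestamps are ISO-8601 strings at minute resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

MINUTES_PER_DAY = 1440
MINUTES_PER_YEAR = 525_960  # 365.25 days

#: epoch anchor used to render integer minutes as ISO timestamps
_EPOCH = pd.Timestamp("1970-01-01")

PERSON_COLUMNS = ["patient_id", "birth_date", "sex", "site"]
EVENT_COLUMNS = ["patient_id", "time", "code", "value"]
ADMISSION_COLUMNS = ["patient_id", "admit_time", "discharge_time", "death_time"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class TimestampError(ValueError):
    """A timestamp cell could not be parsed; carries the offending row index."""


@dataclass(frozen=True)
class CodedEvent:
    """One coded clinical event.

    ``value`` is present only for numeric lab codes (units are those of the
    lab: mmol/L for electrolytes and glucose, g/L for hemoglobin, 10^9/L for
    platelets); for all other codes it is ``None``.
    """

    code: str
    time: int  # minutes since epoch
    value: float | None = None
    site: str = ""


@dataclass(frozen=True)
class AdmissionRecord:
    admit_time: int
    discharge_time: int | None = None
    death_time: int | None = None

    def __post_init__(self) -> None:
        if self.discharge_time is not None and self.discharge_time < self.admit_time:
            raise ValueError("discharge_time precedes admit_time")

    @property
    def died_in_hospital(self) -> bool:
        if self.death_time is None:
            return False
        return self.discharge_time is None or self.death_time <= self.discharge_time


@dataclass
class PatientTimeline:
    """One patient's full coded history, sorted by time."""

    patient_id: str
    birth_date: int
    sex: str
    site: str = ""
    events: list[CodedEvent] = field(default_factory=list)
    admissions: list[AdmissionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            # stable sort keeps file/input order within ties
            self.events = sorted(self.events, key=lambda e: e.time)

    def age_at(self, t: int) -> float:
        """Age in days at time ``t``."""
        return (t - self.birth_date) / MINUTES_PER_DAY

    def codes(self) -> list[str]:
        return [e.code for e in self.events]


def midnight_before(t: int) -> int:
    """00:00 of the calendar day containing minute ``t``."""
    return (t // MINUTES_PER_DAY) * MINUTES_PER_DAY


def midnight_after(t: int) -> int:
    """00:00 of the calendar day after the one containing ``t``.

    This is the "midnight on the day of admission/discharge" prediction
    time: features are frozen at the end of the calendar day.
    """
    return (t // MINUTES_PER_DAY + 1) * MINUTES_PER_DAY


def slice_history(timeline: PatientTimeline, t: int) -> PatientTimeline:
    """Return a copy of ``timeline`` restricted to events strictly before ``t``.

    Events stamped exactly at ``t`` are excluded — model input is everything
    *up to* the prediction time, never at or after it, which rules out label
    leakage through same-minute events.  Admissions and demographics are
    retained untouched.
    """
    if not math.isfinite(t):
        raise ValueError("slice time must be finite")
    kept = [e for e in timeline.events if e.time < t]
    return replace(timeline, events=kept)


# ---------------------------------------------------------------------------
# I/O


def _minutes_to_iso(m: int | None) -> str:
    if m is None:
        return ""
    return (_EPOCH + pd.Timedelta(minutes=int(m))).strftime("%Y-%m-%dT%H:%M")


def _iso_to_minutes(s: object, row: int, column: str, required: bool) -> int | None:
    if s is None or (isinstance(s, float) and math.isnan(s)) or s == "":
        if required:
            raise TimestampError(f"{column}: missing timestamp at row {row}")
        return None
    ts = pd.to_datetime(s, errors="coerce")
    if pd.isna(ts):
        raise TimestampError(f"{column}: unparseable timestamp {s!r} at row {row}")
    return int((ts - _EPOCH).total_seconds() // 60)


def _require_columns(df: pd.DataFrame, needed: Sequence[str], table: str) -> None:
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"{table} is missing required column {col!r}")


def read_omop_lite(path: str | Path) -> list[PatientTimeline]:
    """Read a directory of ``person.csv`` / ``event.csv`` / ``admission.csv``.

    Returns one :class:`PatientTimeline` per person row (persons with no
    events get an empty timeline).  Events are returned time-sorted, stable
    within ties by file order.
    """
    path = Path(path)
    person = pd.read_csv(path / "person.csv", dtype={"patient_id": str})
    event = pd.read_csv(
        path / "event.csv", dtype={"patient_id": str, "code": str},
        float_precision="round_trip",
    )
    admission = pd.read_csv(path / "admission.csv", dtype={"patient_id": str})
    _require_columns(person, PERSON_COLUMNS, "person.csv")
    _require_columns(event, EVENT_COLUMNS, "event.csv")
    _require_columns(admission, ADMISSION_COLUMNS, "admission.csv")

    timelines: dict[str, PatientTimeline] = {}
    for i, row in enumerate(person.itertuples(index=False)):
        bd = _iso_to_minutes(row.birth_date, i, "person.birth_date", required=True)
        timelines[row.patient_id] = PatientTimeline(
            patient_id=row.patient_id, birth_date=bd, sex=str(row.sex), site=str(row.site)
        )

    for i, row in enumerate(event.itertuples(index=False)):
        t = _iso_to_minutes(row.time, i, "event.time", required=True)
        value = None if pd.isna(row.value) else float(row.value)
        tl = timelines.get(row.patient_id)
        if tl is None:
            raise SchemaError(f"event.csv row {i}: unknown patient_id {row.patient_id!r}")
        tl.events.append(CodedEvent(code=row.code, time=t, value=value, site=tl.site))

    for i, row in enumerate(admission.itertuples(index=False)):
        tl = timelines.get(row.patient_id)
        if tl is None:
            raise SchemaError(f"admission.csv row {i}: unknown patient_id {row.patient_id!r}")
        tl.admissions.append(
            AdmissionRecord(
                admit_time=_iso_to_minutes(row.admit_time, i, "admission.admit_time", True),
                discharge_time=_iso_to_minutes(row.discharge_time, i, "admission.discharge_time", False),
                death_time=_iso_to_minutes(row.death_time, i, "admission.death_time", False),
            )
        )

    out = []
    for tl in timelines.values():
        tl.events = sorted(tl.events, key=lambda e: e.time)  # stable
        tl.admissions = sorted(tl.admissions, key=lambda a: a.admit_time)
        out.append(tl)
    out.sort(key=lambda tl: tl.patient_id)
    return out


def write_omop_lite(timelines: Iterable[PatientTimeline], path: str | Path) -> None:
    """Write timelines as the three-table CSV set; deterministic byte-for-byte.

    Rows are ordered by (patient_id, time, input order); writing the same
    input twice produces identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tls = sorted(timelines, key=lambda tl: tl.patient_id)

    person_rows, event_rows, adm_rows = [], [], []
    for tl in tls:
        person_rows.append(
            {"patient_id": tl.patient_id, "birth_date": _minutes_to_iso(tl.birth_date),
             "sex": tl.sex, "site": tl.site}
        )
        for e in sorted(tl.events, key=lambda e: e.time):
            event_rows.append(
                {"patient_id": tl.patient_id, "time": _minutes_to_iso(e.time),
                 "code": e.code, "value": "" if e.value is None else repr(float(e.value))}
            )
        for a in sorted(tl.admissions, key=lambda a: a.admit_time):
            adm_rows.append(
                {"patient_id": tl.patient_id, "admit_time": _minutes_to_iso(a.admit_time),
                 "discharge_time": _minutes_to_iso(a.discharge_time),
                 "death_time": _minutes_to_iso(a.death_time)}
            )

    pd.DataFrame(person_rows, columns=PERSON_COLUMNS).to_csv(path / "person.csv", index=False)
    pd.DataFrame(event_rows, columns=EVENT_COLUMNS).to_csv(path / "event.csv", index=False)
    pd.DataFrame(adm_rows, columns=ADMISSION_COLUMNS).to_csv(path / "admission.csv", index=False)
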