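"""Shared fixtures: hand-built timelines exercising the cohort rules."""

from __future__ import annotations

import pytest

from ehrfm.timeline_store import (
    MINUTES_PER_DAY,
    AdmissionRecord,
    CodedEvent,
    PatientTimeline,
)


def day(d: int, hour: int = 0, minute: int = 0) -> int:
    return d * MINUTES_PER_DAY + hour * 60 + minute


@pytest.fixture
def hand_cohort_timelines() -> list[PatientTimeline]:
    """Six index admissions covering every exclusion and threshold rule.

    * p1, p6 — under the 28-day age floor (excluded).
    * p2 — discharged before midnight of the admission day (excluded).
    * p3 — 7-day stay (long-LOS boundary, label 1), glucose 2.9 in-window
      (hypoglycemia 1) plus a boundary 3.0 that must not fire, sodium
      124.5 (hyponatremia 1), platelets exactly 50.0 (no fire).
    * p4 — 6-day stay (long-LOS 0), glucose 2.9 between admission and
      prediction time (hypoglycemia excluded), hemoglobin 69 in-window
      (anemia 1), readmitted exactly 30 days after discharge
      (readmission boundary, label 1; the readmission itself is a
      same-day stay, ineligible as an index admission).
    * p5 — in-hospital death on day 3 (mortality 1), potassium exactly
      7.0 (no fire, strict >), platelets 49.9 (thrombocytopenia 1).
    """
    mk = CodedEvent
    p1 = PatientTimeline(
        "p1", birth_date=day(90), sex="F", site="T",
        admissions=[AdmissionRecord(day(100, 12), day(105, 12))],
    )
    p6 = PatientTimeline(
        "p6", birth_date=day(80), sex="M", site="T",
        admissions=[AdmissionRecord(day(100, 12), day(104, 12))],
    )
    p2 = PatientTimeline(
        "p2", birth_date=day(0), sex="M", site="T",
        admissions=[AdmissionRecord(day(100, 12), day(100, 20))],
    )
    p3 = PatientTimeline(
        "p3", birth_date=day(0), sex="F", site="T",
        events=[
            mk("DX/001", day(95, 10)),
            mk("LAB/GLU", day(102, 6), 2.9),
            mk("LAB/GLU", day(103, 6), 3.0),
            mk("LAB/NA", day(104, 6), 124.5),
            mk("LAB/PLT", day(101, 6), 50.0),
        ],
        admissions=[AdmissionRecord(day(100, 12), day(107, 12))],
    )
    p4 = PatientTimeline(
        "p4", birth_date=day(0), sex="M", site="T",
        events=[
            mk("LAB/GLU", day(100, 13), 2.9),  # before the prediction time
            mk("LAB/HGB", day(105, 10), 69.0),
        ],
        admissions=[
            AdmissionRecord(day(100, 12), day(106, 12)),
            AdmissionRecord(day(136, 12), day(136, 20)),  # +30 days exactly
        ],
    )
    p5 = PatientTimeline(
        "p5", birth_date=day(0), sex="F", site="T",
        events=[
            mk("LAB/K", day(102, 6), 7.0),
            mk("LAB/PLT", day(101, 6), 49.9),
        ],
        admissions=[AdmissionRecord(day(100, 12), day(103, 18), death_time=day(103, 18))],
    )
    return [p1, p2, p3, p4, p5, p6]
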