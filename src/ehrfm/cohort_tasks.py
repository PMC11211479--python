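"""Inpatient cohort construction, task labeling, and patient-level splits.

Eight binary clinical prediction tasks are defined over one randomly
selected admission per eligible patient: three operational outcomes
(in-hospital mortality, long length of stay of at least 7 days, 30-day
readmission) and five anticipated abnormal lab results (hypoglycemia,
hyponatremia, hyperkalemia, thrombocytopenia, anemia), each fired by a
strict threshold on the measured lab value.

Prediction times: midnight at the end of the admission day for all tasks
except 30-day readmission, which uses midnight at the end of the
discharge day.  The observation window is everything strictly before the
prediction time; the prediction window runs from the prediction time to
discharge (readmission: 30 days post-discharge).  Admissions where the
outcome — or death/discharge — occurs between admission and prediction
time are excluded rather than labeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .timeline_store import (
    MINUTES_PER_DAY,
    AdmissionRecord,
    PatientTimeline,
    midnight_after,
)

LAB_TASK_CODES = {
    "hypoglycemia": ("LAB/GLU", 3.0, "<"),
    "hyponatremia": ("LAB/NA", 125.0, "<"),
    "hyperkalemia": ("LAB/K", 7.0, ">"),
    "thrombocytopenia": ("LAB/PLT", 50.0, "<"),
    "anemia": ("LAB/HGB", 70.0, "<"),
}


@dataclass(frozen=True)
class TaskSpec:
    name: str
    prediction_time_rule: str  # "admission-midnight" | "discharge-midnight"
    window_rule: str  # "until-discharge" | "30-days-post-discharge"
    lab_code: str | None = None
    threshold: float | None = None
    direction: str | None = None  # "<" fires strictly below, ">" strictly above

    def crosses(self, value: float) -> bool:
        if self.direction == "<":
            return value < self.threshold
        if self.direction == ">":
            return value > self.threshold
        raise ValueError(f"{self.name} is not a lab task")


def _canonical_tasks() -> dict[str, TaskSpec]:
    tasks = {
        "mortality": TaskSpec("mortality", "admission-midnight", "until-discharge"),
        "long_los": TaskSpec("long_los", "admission-midnight", "until-discharge"),
        "readmission_30d": TaskSpec(
            "readmission_30d", "discharge-midnight", "30-days-post-discharge"
        ),
    }
    for name, (code, thr, direction) in LAB_TASK_CODES.items():
        tasks[name] = TaskSpec(
            name, "admission-midnight", "until-discharge",
            lab_code=code, threshold=thr, direction=direction,
        )
    return tasks


#: the eight canonical task specifications
TASKS: dict[str, TaskSpec] = _canonical_tasks()

LONG_LOS_MINUTES = 7 * MINUTES_PER_DAY
READMISSION_WINDOW_MINUTES = 30 * MINUTES_PER_DAY


@dataclass(frozen=True)
class CohortExample:
    patient_id: str
    admission_idx: int
    task: str
    prediction_time: int
    label: int


@dataclass(frozen=True)
class CohortRow:
    """One (patient, selected admission) pair in the inpatient cohort."""

    patient_id: str
    admission_idx: int


def prediction_time(adm: AdmissionRecord, rule: str) -> int:
    if rule == "admission-midnight":
        return midnight_after(adm.admit_time)
    if rule == "discharge-midnight":
        if adm.discharge_time is None:
            raise ValueError("discharge-midnight rule needs a discharge time")
        return midnight_after(adm.discharge_time)
    raise ValueError(f"unknown prediction time rule {rule!r}")


def build_inpatient_cohort(
    timelines: Sequence[PatientTimeline],
    min_age_days: float,
    seed: int,
    one_per_patient: bool = True,
) -> list[CohortRow]:
    """Select one eligible admission per patient, uniformly at random.

    Eligibility: patient at least ``min_age_days`` old at admission, and
    neither death nor discharge before the earliest prediction time
    (midnight at the end of the admission day).  ``one_per_patient=False``
    keeps every eligible admission instead — the per-admission view used
    when checking outcome rates against the generator's closed forms.
    """
    rng = np.random.default_rng(seed)
    rows: list[CohortRow] = []
    for tl in sorted(timelines, key=lambda t: t.patient_id):
        eligible = []
        for idx, adm in enumerate(tl.admissions):
            if tl.age_at(adm.admit_time) < min_age_days:
                continue
            pt = midnight_after(adm.admit_time)
            if adm.death_time is not None and adm.death_time <= pt:
                continue
            if adm.discharge_time is not None and adm.discharge_time <= pt:
                continue
            eligible.append(idx)
        if not eligible:
            continue
        if one_per_patient:
            pick = eligible[0] if len(eligible) == 1 else int(rng.choice(eligible))
            rows.append(CohortRow(tl.patient_id, pick))
        else:
            rows.extend(CohortRow(tl.patient_id, i) for i in eligible)
    return rows


def _lab_label(
    task: TaskSpec, tl: PatientTimeline, adm: AdmissionRecord, pt: int
) -> int | None:
    """Label for a lab task, or ``None`` if the admission is excluded.

    The first qualifying threshold crossing determines timing: a crossing
    between admission and prediction time excludes the admission; one in
    the prediction window labels it 1.  Pre-admission crossings are
    history, not outcomes.
    """
    end = adm.discharge_time if adm.discharge_time is not None else np.inf
    label = 0
    for e in tl.events:
        if e.code != task.lab_code or e.value is None:
            continue
        if not task.crosses(e.value):
            continue
        if adm.admit_time <= e.time <= pt:
            return None  # outcome before prediction time → excluded
        if pt < e.time <= end:
            label = 1
    return label


def label_task(
    cohort: Sequence[CohortRow],
    task: TaskSpec,
    timelines: Sequence[PatientTimeline],
) -> list[CohortExample]:
    """Label every cohort admission for one task, applying its exclusions."""
    if task.name not in TASKS:
        raise ValueError(f"unknown task {task.name!r}")
    by_id = {tl.patient_id: tl for tl in timelines}
    out: list[CohortExample] = []
    for row in cohort:
        tl = by_id[row.patient_id]
        adm = tl.admissions[row.admission_idx]
        if task.prediction_time_rule == "discharge-midnight" and adm.discharge_time is None:
            continue
        pt = prediction_time(adm, task.prediction_time_rule)

        if task.name == "mortality":
            label = int(adm.died_in_hospital)
        elif task.name == "long_los":
            if adm.discharge_time is None:
                continue
            label = int(adm.discharge_time - adm.admit_time >= LONG_LOS_MINUTES)
        elif task.name == "readmission_30d":
            if adm.died_in_hospital:
                label = 0  # death precludes readmission; kept as a negative
            else:
                label = 0
                excluded = False
                for later in tl.admissions[row.admission_idx + 1 :]:
                    dt = later.admit_time - adm.discharge_time
                    if 0 < dt <= READMISSION_WINDOW_MINUTES:
                        if later.admit_time <= pt:
                            excluded = True  # readmitted before prediction time
                        else:
                            label = 1
                        break
                if excluded:
                    continue
        else:
            lab = _lab_label(task, tl, adm, pt)
            if lab is None:
                continue
            label = lab
        out.append(CohortExample(row.patient_id, row.admission_idx, task.name, pt, label))
    return out


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitAssignment:
    fold_of: dict[str, str]  # patient_id -> train | valid | test

    def patients(self, fold: str) -> list[str]:
        return sorted(p for p, f in self.fold_of.items() if f == fold)


def make_global_splits(patient_ids: Iterable[str], seed: int) -> SplitAssignment:
    """Patient-level 70/15/15 partition with largest-remainder rounding."""
    ids = sorted(set(patient_ids))
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    props = {"train": 0.70, "valid": 0.15, "test": 0.15}
    counts = {k: int(np.floor(n * p)) for k, p in props.items()}
    remainders = {k: n * p - counts[k] for k, p in props.items()}
    short = n - sum(counts.values())
    for k in sorted(props, key=lambda k: (-remainders[k], ["train", "valid", "test"].index(k))):
        if short == 0:
            break
        counts[k] += 1
        short -= 1
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    fold_of: dict[str, str] = {}
    i = 0
    for fold in ("train", "valid", "test"):
        for p in order[i : i + counts[fold]]:
            fold_of[p] = fold
        i += counts[fold]
    return SplitAssignment(fold_of)


def derive_task_splits(
    examples: Sequence[CohortExample], global_split: SplitAssignment
) -> dict[str, list[CohortExample]]:
    """Partition task examples by their patient's global fold."""
    out: dict[str, list[CohortExample]] = {"train": [], "valid": [], "test": []}
    for ex in examples:
        fold = global_split.fold_of.get(ex.patient_id)
        if fold is None:
            raise KeyError(f"patient {ex.patient_id} missing from the global split")
        out[fold].append(ex)
    return out


def examples_to_frame(examples: Sequence[CohortExample], fold_of: Mapping[str, str] | None = None):
    """Tabular view (pandas) of labeled examples, for the CSV interface."""
    import pandas as pd

    rows = [
        {
            "patient_id": ex.patient_id,
            "admission_idx": ex.admission_idx,
            "task": ex.task,
            "prediction_time": ex.prediction_time,
            "label": ex.label,
            "fold": fold_of.get(ex.patient_id, "") if fold_of else "",
        }
        for ex in examples
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "admission_idx", "task", "prediction_time", "label", "fold"]
    )
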