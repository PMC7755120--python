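"""Cohort-level clinical summaries for tic-disorder screening studies.

Per-subject records (sex, onset age band, DSM-V tic-disorder category,
symptom set, prior medication count) are tabulated into a
variable/level/count/rate table.  Exclusive variables (sex, age band,
category, prior drugs) partition the cohort; symptoms are multi-label.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SEXES = ("male", "female")
ONSET_BANDS = ("0-5", "6-11", "12-18")
DIAGNOSES = ("TS", "CTD", "PTD")
SYMPTOMS = ("blinking", "grimacing", "throat_clearing", "shrug",
            "head_shake", "spit")
DRUG_LEVELS = ("0", "1", "2", "3", "4+")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    sex: str
    age_years: float
    onset_band: str
    diagnosis: str
    symptoms: frozenset[str] = field(default_factory=frozenset)
    prior_drugs: str = "0"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"{self.subject_id}: sex must be one of {SEXES}")
        if self.age_years < 0:
            raise ValueError(f"{self.subject_id}: negative age")
        if self.onset_band not in ONSET_BANDS:
            raise ValueError(f"{self.subject_id}: bad onset band {self.onset_band!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"{self.subject_id}: bad diagnosis {self.diagnosis!r}")
        bad = set(self.symptoms) - set(SYMPTOMS)
        if bad:
            raise ValueError(f"{self.subject_id}: unknown symptoms {sorted(bad)}")
        if self.prior_drugs not in DRUG_LEVELS:
            raise ValueError(f"{self.subject_id}: bad drug level {self.prior_drugs!r}")


def _rate(count: int, n: int) -> float:
    return round(100 * count / n, 2)


def summarize(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Variable/level/count/rate summary table.

    Every level of every variable is present even at count zero; rates are
    percentages of the cohort size to 2 decimals.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    rows = []

    def add(variable: str, level: str, count: int) -> None:
        rows.append({"variable": variable, "level": level,
                     "count": count, "rate_percent": _rate(count, n)})

    for sex in SEXES:
        add("sex", sex, sum(1 for s in cohort if s.sex == sex))
    for band in ONSET_BANDS:
        add("onset_band", band, sum(1 for s in cohort if s.onset_band == band))
    for dx in DIAGNOSES:
        add("diagnosis", dx, sum(1 for s in cohort if s.diagnosis == dx))
    for sym in SYMPTOMS:
        add("symptom", sym, sum(1 for s in cohort if sym in s.symptoms))
    for lvl in DRUG_LEVELS:
        add("prior_drugs", lvl, sum(1 for s in cohort if s.prior_drugs == lvl))
    return pd.DataFrame(rows)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "sex", "age_years", "onset_band", "diagnosis"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    subjects = []
    for row in frame.itertuples(index=False):
        symptoms = getattr(row, "symptoms", "") or ""
        if isinstance(symptoms, float):  # NaN from an empty cell
            symptoms = ""
        subjects.append(SubjectRecord(
            subject_id=row.subject_id,
            sex=row.sex,
            age_years=float(row.age_years),
            onset_band=row.onset_band,
            diagnosis=row.diagnosis,
            symptoms=frozenset(s for s in symptoms.split(",") if s),
            prior_drugs=str(getattr(row, "prior_drugs", "0")),
        ))
    return subjects


def write_subjects(subjects: Iterable[SubjectRecord], path: str | Path) -> None:
    rows = [{
        "subject_id": s.subject_id, "sex": s.sex, "age_years": s.age_years,
        "onset_band": s.onset_band, "diagnosis": s.diagnosis,
        "symptoms": ",".join(sorted(s.symptoms)), "prior_drugs": s.prior_drugs,
    } for s in subjects]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
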