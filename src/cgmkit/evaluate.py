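"""Clinician-grading rubric scoring and chance-corrected inter-rater agreement.

Two independent raters answer five yes/no rubric questions per case x task:
accuracy, completeness, safety, patient suitability, clinician suitability.
For accuracy and the two suitability questions "yes" is the good answer and
scores 1; for completeness and safety the question asks whether a flaw is
present, so "yes" scores 0 and "no" scores 1.

Agreement between the raters is summarized with Gwet's AC1, a
chance-corrected coefficient that, unlike Cohen's kappa, stays stable when
one answer dominates (prevalence extremes are the norm for rubric data
where most items are graded "good").  For two raters and binary answers:

    pa  = fraction of items the raters answer identically
    pi  = (prevalence under rater A + prevalence under rater B) / 2
    pe  = 2 * pi * (1 - pi)          (chance agreement; at most 1/2)
    AC1 = (pa - pe) / (1 - pe)
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass

import numpy as np

CATEGORIES = (
    "accuracy",
    "completeness",
    "safety",
    "patient_suitability",
    "clinician_suitability",
)

#: Points awarded for a "yes" answer per category ("no" scores the complement).
#: Completeness and safety ask whether a flaw is present, hence the inversion.
YES_POINTS = {
    "accuracy": 1,
    "completeness": 0,
    "safety": 0,
    "patient_suitability": 1,
    "clinician_suitability": 1,
}

TASKS = ("data_quality", "hyperglycemia", "hypoglycemia", "variability", "main_concern")


@dataclass(frozen=True)
class RatingRecord:
    """One rater's five yes/no rubric answers for one case x task."""

    case_id: str
    task: str
    rater_id: str
    answers: dict  # category -> bool (True = "yes")

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.answers]
        if missing:
            raise ValueError(f"rating record missing answers for {missing}")


@dataclass(frozen=True)
class AgreementResult:
    category: str
    pa: float
    pe: float
    ac1: float
    n_items: int


@dataclass(frozen=True)
class ScoreSummary:
    """Per-rater point totals for one task x category and their mean."""

    task: str
    category: str
    per_rater_totals: dict  # rater_id -> int
    mean_total: float
    n_cases: int


def score_record(record: RatingRecord) -> tuple[int, int, int, int, int]:
    """Map yes/no answers to rubric points, in CATEGORIES order."""
    return tuple(
        YES_POINTS[c] if record.answers[c] else 1 - YES_POINTS[c] for c in CATEGORIES
    )


def aggregate_scores(
    records: list[RatingRecord], allow_incomplete: bool = False
) -> dict[tuple[str, str], ScoreSummary]:
    """Total points per rater over cases, per (task, category), and the
    cross-rater mean total (the headline "x / n-cases" figure).

    Requires a complete case x task x rater grid unless ``allow_incomplete``.
    """
    seen = Counter((r.case_id, r.task, r.rater_id) for r in records)
    dupes = [k for k, v in seen.items() if v > 1]
    if dupes:
        raise ValueError(f"duplicate rating records: {dupes[:3]}")
    cases = sorted({r.case_id for r in records})
    tasks = sorted({r.task for r in records})
    raters = sorted({r.rater_id for r in records})
    if not allow_incomplete:
        missing = [
            (c, t, r)
            for c in cases for t in tasks for r in raters
            if (c, t, r) not in seen
        ]
        if missing:
            raise ValueError(
                f"incomplete rating grid ({len(missing)} missing, e.g. {missing[:3]}); "
                "pass allow_incomplete=True to aggregate anyway"
            )
    out: dict[tuple[str, str], ScoreSummary] = {}
    for t in tasks:
        for ci, cat in enumerate(CATEGORIES):
            totals = {
                rater: sum(
                    score_record(r)[ci]
                    for r in records
                    if r.task == t and r.rater_id == rater
                )
                for rater in raters
            }
            out[(t, cat)] = ScoreSummary(
                task=t,
                category=cat,
                per_rater_totals=totals,
                mean_total=float(np.mean(list(totals.values()))),
                n_cases=len(cases),
            )
    return out


def gwet_ac1(answers_a, answers_b, category: str = "") -> AgreementResult:
    """Gwet's AC1 for two raters' binary answers over the same items."""
    a = np.asarray(answers_a, dtype=bool)
    b = np.asarray(answers_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"rater vectors differ in length: {a.shape} vs {b.shape}")
    n = len(a)
    if n == 0:
        raise ValueError("gwet_ac1 of empty rating vectors")
    pa = float(np.mean(a == b))
    pi = (float(np.mean(a)) + float(np.mean(b))) / 2.0
    pe = 2.0 * pi * (1.0 - pi)  # <= 1/2, so 1 - pe >= 1/2: never degenerate
    ac1 = (pa - pe) / (1.0 - pe)
    return AgreementResult(category=category, pa=pa, pe=pe, ac1=ac1, n_items=n)


def agreement_by_category(
    records: list[RatingRecord],
) -> dict[str, AgreementResult]:
    """AC1 per rubric category across all case x task items, for exactly
    two raters."""
    raters = sorted({r.rater_id for r in records})
    if len(raters) != 2:
        raise ValueError(f"expected exactly 2 raters, got {raters}")
    ra, rb = raters
    key = lambda r: (r.case_id, r.task)
    by_a = {key(r): r for r in records if r.rater_id == ra}
    by_b = {key(r): r for r in records if r.rater_id == rb}
    items = sorted(set(by_a) & set(by_b))
    if not items:
        raise ValueError("no case x task items rated by both raters")
    out = {}
    for cat in CATEGORIES:
        va = [by_a[i].answers[cat] for i in items]
        vb = [by_b[i].answers[cat] for i in items]
        out[cat] = gwet_ac1(va, vb, category=cat)
    return out


_YES = {"yes", "y", "true", "1"}
_NO = {"no", "n", "false", "0"}


def read_ratings_csv(path) -> list[RatingRecord]:
    """Read rating records from a flat CSV with columns
    case_id, task, rater_id, accuracy, completeness, safety,
    patient_suitability, clinician_suitability (yes/no answers)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"case_id", "task", "rater_id", *CATEGORIES}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: ratings CSV must have columns {sorted(expected)}"
            )
        for i, row in enumerate(reader, start=2):
            answers = {}
            for cat in CATEGORIES:
                token = row[cat].strip().lower()
                if token in _YES:
                    answers[cat] = True
                elif token in _NO:
                    answers[cat] = False
                else:
                    raise ValueError(f"{path}:{i}: unrecognized yes/no answer {row[cat]!r}")
            records.append(
                RatingRecord(
                    case_id=row["case_id"].strip(),
                    task=row["task"].strip(),
                    rater_id=row["rater_id"].strip(),
                    answers=answers,
                )
            )
    return records
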