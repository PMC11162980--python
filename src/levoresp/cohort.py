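"""Clinical records, levodopa-response labeling, inclusion filtering, and
participant-grouped train/test splitting.

The levodopa challenge test (LCT) compares MDS-UPDRS III motor scores before
(OFF) and after (ON) a levodopa dose. The improvement rate

    rate = (OFF - ON) / OFF * 100%

summarises the response; a rate at or above the 30% threshold labels the
record a "good" responder, otherwise "bad". Because participants can
contribute several visits, train/test splits are made at the participant
level so no subject appears on both sides.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalRecord",
    "ResponseLabel",
    "CohortSplit",
    "improvement_rate",
    "classify_response",
    "apply_inclusion_filters",
    "grouped_split",
    "read_clinical_csv",
    "write_clinical_csv",
    "write_split_csv",
]

GOOD = "good"
BAD = "bad"

#: machine-readable exclusion reason codes
MISSING_LEDD = "MISSING_LEDD"
DUPLICATE_VISIT = "DUPLICATE_VISIT"
OFF_LT_5 = "OFF_LT_5"
LEDD_GT_5000 = "LEDD_GT_5000"

CLINICAL_COLUMNS = [
    "subject_id",
    "visit_id",
    "age",
    "sex",
    "duration_months",
    "ledd",
    "updrs3_off",
    "updrs3_on",
]


@dataclass(frozen=True)
class ClinicalRecord:
    """One visit's demographics, medication dose, and LCT motor scores."""

    subject_id: str
    visit_id: str
    age: float
    sex: str  # "M" or "F"
    disease_duration: float  # months
    ledd: float | None  # mg/day; None when not calculable
    updrs3_off: float
    updrs3_on: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("updrs3_off", "updrs3_on"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.visit_id)


@dataclass(frozen=True)
class ResponseLabel:
    improvement_rate: float  # percent; may be negative
    response_class: str  # GOOD or BAD


@dataclass
class CohortSplit:
    train_ids: set[tuple[str, str]]
    test_ids: set[tuple[str, str]]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        train_subj = {s for s, _ in self.train_ids}
        test_subj = {s for s, _ in self.test_ids}
        if train_subj & test_subj:
            raise ValueError("train and test subject sets overlap")
        if self.train_ids & self.test_ids:
            raise ValueError("train and test record sets overlap")


def improvement_rate(updrs3_off: float, updrs3_on: float) -> float:
    """Percent motor improvement of the LCT; negative when the patient worsens."""
    if updrs3_off <= 0:
        raise ValueError(f"updrs3_off must be > 0 for a defined rate, got {updrs3_off}")
    return 100.0 * (updrs3_off - updrs3_on) / updrs3_off


def classify_response(rate: float, threshold: float = 30.0) -> str:
    """Good responder iff the improvement rate reaches the threshold (>=)."""
    if not math.isfinite(rate):
        raise ValueError(f"rate must be finite, got {rate}")
    return GOOD if rate >= threshold else BAD


def label_record(rec: ClinicalRecord, threshold: float = 30.0) -> ResponseLabel:
    rate = improvement_rate(rec.updrs3_off, rec.updrs3_on)
    return ResponseLabel(rate, classify_response(rate, threshold))


def apply_inclusion_filters(
    records: list[ClinicalRecord],
) -> tuple[list[ClinicalRecord], list[tuple[ClinicalRecord, str]]]:
    """Apply the cohort inclusion rules.

    Kept records have a known LEDD, a unique (subject, visit) pair, an OFF
    motor score of at least 5, and LEDD at most 5000 mg/day. Inequalities are
    strict as stated (OFF < 5 and LEDD > 5000 are excluded), so boundary
    values are kept. Returns (kept, excluded) with one reason code per
    excluded record; the first failing rule wins.
    """
    kept: list[ClinicalRecord] = []
    excluded: list[tuple[ClinicalRecord, str]] = []
    key_counts: dict[tuple[str, str], int] = {}
    for rec in records:
        key_counts[rec.key] = key_counts.get(rec.key, 0) + 1
    for rec in records:
        if rec.ledd is None or (isinstance(rec.ledd, float) and math.isnan(rec.ledd)):
            excluded.append((rec, MISSING_LEDD))
        elif key_counts[rec.key] > 1:
            excluded.append((rec, DUPLICATE_VISIT))
        elif rec.updrs3_off < 5:
            excluded.append((rec, OFF_LT_5))
        elif rec.ledd > 5000:
            excluded.append((rec, LEDD_GT_5000))
        else:
            kept.append(rec)
    return kept, excluded


def grouped_split(
    records: list[ClinicalRecord], ratio: float = 0.8, seed: int = 0
) -> CohortSplit:
    """Participant-grouped train/test split.

    Subjects are shuffled by the seed and assigned whole to the training set
    until the training record count reaches ``ratio`` of the total; the rest
    form the test set. All records of one subject always land on one side.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    subjects: dict[str, list[tuple[str, str]]] = {}
    for rec in records:
        subjects.setdefault(rec.subject_id, []).append(rec.key)
    if len(subjects) < 2:
        raise ValueError("need at least 2 distinct subjects to split")
    order = sorted(subjects)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    total = len(records)
    train_ids: set[tuple[str, str]] = set()
    test_ids: set[tuple[str, str]] = set()
    count = 0
    for subj in order:
        if count < ratio * total:
            train_ids.update(subjects[subj])
            count += len(subjects[subj])
        else:
            test_ids.update(subjects[subj])
    if not test_ids:  # every subject fell into train; move the last one over
        last = order[-1]
        moved = set(subjects[last])
        train_ids -= moved
        test_ids |= moved
    return CohortSplit(train_ids, test_ids, ratio, seed)


# ---------------------------------------------------------------------------
# CSV interfaces


def records_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "visit_id": r.visit_id,
            "age": r.age,
            "sex": r.sex,
            "duration_months": r.disease_duration,
            "ledd": np.nan if r.ledd is None else r.ledd,
            "updrs3_off": r.updrs3_off,
            "updrs3_on": r.updrs3_on,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[ClinicalRecord]:
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        ledd = float(row.ledd)
        records.append(
            ClinicalRecord(
                subject_id=str(row.subject_id),
                visit_id=str(row.visit_id),
                age=float(row.age),
                sex=str(row.sex),
                disease_duration=float(row.duration_months),
                ledd=None if math.isnan(ledd) else ledd,
                updrs3_off=float(row.updrs3_off),
                updrs3_on=float(row.updrs3_on),
            )
        )
    return records


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    return frame_to_records(pd.read_csv(path, dtype={"subject_id": str, "visit_id": str}))


def write_clinical_csv(records: list[ClinicalRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_split_csv(split: CohortSplit, path: str | Path) -> None:
    rows = [
        {"subject_id": s, "visit_id": v, "set": name}
        for name, ids in (("train", split.train_ids), ("test", split.test_ids))
        for s, v in sorted(ids)
    ]
    pd.DataFrame(rows, columns=["subject_id", "visit_id", "set"]).to_csv(path, index=False)
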