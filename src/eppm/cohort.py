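"""Patient cohort containers, validation and CSV round-trip.

A cohort is an ordered collection of admission records for patients with
traumatic brain injury (TBI). Each record carries the demographic, clinical,
laboratory and CT-imaging variables the early-prognosis prediction model
(EPPM) consumes, plus an optional binary 14-day outcome label (poor/good).

CSV conventions: comma-separated UTF-8 with a header row; booleans are
written ``yes``/``no``; the Marshall CT class is written as a Roman numeral
I–VI; optional cells are left empty. Any column beyond the canonical set is
read into ``PatientRecord.extra_labs`` as a named serum analyte.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "RowReject",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "split_cohort",
    "SEXES",
    "MECHANISMS",
    "DAMAGED_AREAS",
    "MARSHALL_CLASSES",
    "OUTCOMES",
    "COMORBIDITY_FLAGS",
]

SEXES = ("male", "female")
MECHANISMS = ("traffic", "striking", "fall", "other")
DAMAGED_AREAS = ("frontal", "temporal", "parietal", "occipital")
MARSHALL_CLASSES = ("I", "II", "III", "IV", "V", "VI")
OUTCOMES = ("poor", "good")
COMORBIDITY_FLAGS = ("smoking", "alcohol", "hypertension", "diabetes")

COHORT_LABELS = (
    "training_part1",
    "training_part2",
    "validation",
    "testing",
    "unlabeled",
)

AGE_MIN, AGE_MAX = 15, 75  # study inclusion window, years
GCS_MIN, GCS_MAX = 3, 15

#: canonical CSV columns, in writing order (before any extra-lab columns)
CANONICAL_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "mechanism",
    "damaged_area",
    "gcs",
    "apoe_e4_carrier",
    "crp",
    "il8",
    "marshall",
    "outcome",
    "smoking",
    "alcohol",
    "hypertension",
    "diabetes",
)

MANDATORY_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "mechanism",
    "damaged_area",
    "gcs",
    "apoe_e4_carrier",
    "crp",
    "il8",
    "marshall",
)


class SchemaError(ValueError):
    """The CSV header cannot be resolved to the mandatory columns."""


class CohortValidationError(ValueError):
    """Strict read requested and at least one row failed validation."""

    def __init__(self, rejects: list["RowReject"]):
        self.rejects = rejects
        lines = "; ".join(f"row {r.row_index}: {', '.join(r.reasons)}" for r in rejects[:5])
        more = "" if len(rejects) <= 5 else f" (+{len(rejects) - 5} more)"
        super().__init__(f"{len(rejects)} invalid row(s): {lines}{more}")


@dataclass
class PatientRecord:
    """One TBI admission.

    Mandatory fields are the seven EPPM predictors plus identifiers; the
    outcome label, comorbidity flags and additional serum analytes are
    optional.
    """

    patient_id: str
    age: int
    sex: str
    mechanism: str
    damaged_area: str
    gcs: int
    apoe_e4_carrier: bool
    crp: float
    il8: float
    marshall: str
    extra_labs: dict[str, float] = field(default_factory=dict)
    outcome: str | None = None
    comorbidities: dict[str, bool] = field(default_factory=dict)

    def violations(self) -> list[str]:
        """Return every invariant violation (empty list means valid)."""
        v: list[str] = []
        if not self.patient_id:
            v.append("patient_id is empty")
        if not (AGE_MIN <= self.age <= AGE_MAX):
            v.append(f"age {self.age} outside [{AGE_MIN}, {AGE_MAX}]")
        if self.sex not in SEXES:
            v.append(f"sex {self.sex!r} not in {SEXES}")
        if self.mechanism not in MECHANISMS:
            v.append(f"mechanism {self.mechanism!r} not in {MECHANISMS}")
        if self.damaged_area not in DAMAGED_AREAS:
            v.append(f"damaged_area {self.damaged_area!r} not in {DAMAGED_AREAS}")
        if not (GCS_MIN <= self.gcs <= GCS_MAX):
            v.append(f"gcs {self.gcs} outside [{GCS_MIN}, {GCS_MAX}]")
        if not (np.isfinite(self.crp) and self.crp >= 0):
            v.append(f"crp {self.crp} is not a non-negative real")
        if not (np.isfinite(self.il8) and self.il8 >= 0):
            v.append(f"il8 {self.il8} is not a non-negative real")
        if self.marshall not in MARSHALL_CLASSES:
            v.append(f"marshall {self.marshall!r} not in {MARSHALL_CLASSES}")
        if self.outcome is not None and self.outcome not in OUTCOMES:
            v.append(f"outcome {self.outcome!r} not in {OUTCOMES}")
        for name in self.comorbidities:
            if name not in COMORBIDITY_FLAGS:
                v.append(f"unknown comorbidity flag {name!r}")
        return v

    def is_valid(self) -> bool:
        return not self.violations()


@dataclass
class RowReject:
    """A CSV row that failed parsing or validation, with its reasons."""

    row_index: int  # 0-based data-row index (header excluded)
    reasons: list[str]


@dataclass
class Cohort:
    """Ordered collection of patient records with a set label.

    ``rejects`` records rows that failed validation during a read; they are
    reported, never silently dropped into the record list.
    """

    records: list[PatientRecord] = field(default_factory=list)
    label: str = "unlabeled"
    rejects: list[RowReject] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in COHORT_LABELS:
            raise ValueError(f"cohort label {self.label!r} not in {COHORT_LABELS}")
        ids = [r.patient_id for r in self.records]
        dup = [pid for pid, k in Counter(ids).items() if k > 1]
        if dup:
            raise ValueError(f"duplicate patient_id within cohort: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def outcome_counts(self) -> dict[str, int]:
        """Counts of poor/good/unlabelled outcomes, recomputed from records."""
        c = Counter(r.outcome if r.outcome is not None else "unlabelled" for r in self.records)
        return {"poor": c.get("poor", 0), "good": c.get("good", 0), "unlabelled": c.get("unlabelled", 0)}

    def subset(self, indices: Sequence[int], label: str = "unlabeled") -> "Cohort":
        return Cohort(records=[self.records[i] for i in indices], label=label)

    def to_dataframe(self) -> pd.DataFrame:
        return _records_to_frame(self.records)


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_bool(cell: str, what: str) -> bool:
    s = cell.strip().lower()
    if s in ("yes", "true", "1"):
        return True
    if s in ("no", "false", "0"):
        return False
    raise ValueError(f"{what}: cannot parse boolean from {cell!r}")


def _parse_int(cell: str, what: str) -> int:
    try:
        return int(float(cell)) if float(cell) == int(float(cell)) else int(cell)
    except (TypeError, ValueError):
        raise ValueError(f"{what}: cannot parse integer from {cell!r}") from None


def _parse_float(cell: str, what: str) -> float:
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise ValueError(f"{what}: cannot parse number from {cell!r}") from None


def _fmt_bool(b: bool | None) -> str:
    return "" if b is None else ("yes" if b else "no")


def _records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    records = list(records)
    extra_names: list[str] = []
    for r in records:
        for name in r.extra_labs:
            if name not in extra_names:
                extra_names.append(name)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "mechanism": r.mechanism,
            "damaged_area": r.damaged_area,
            "gcs": r.gcs,
            "apoe_e4_carrier": _fmt_bool(r.apoe_e4_carrier),
            "crp": r.crp,
            "il8": r.il8,
            "marshall": r.marshall,
            "outcome": r.outcome if r.outcome is not None else "",
        }
        for flag in COMORBIDITY_FLAGS:
            row[flag] = _fmt_bool(r.comorbidities.get(flag)) if r.comorbidities else ""
        for name in extra_names:
            row[name] = r.extra_labs.get(name, "")
        rows.append(row)
    columns = list(CANONICAL_COLUMNS) + extra_names
    return pd.DataFrame(rows, columns=columns)


def _row_to_record(row: Mapping[str, str], extra_names: Sequence[str]) -> PatientRecord:
    """Parse one raw (string-valued) CSV row; raises ValueError on bad cells."""
    comorbidities: dict[str, bool] = {}
    for flag in COMORBIDITY_FLAGS:
        cell = row.get(flag, "")
        if cell is not None and str(cell).strip() != "":
            comorbidities[flag] = _parse_bool(str(cell), flag)
    extra_labs: dict[str, float] = {}
    for name in extra_names:
        cell = row.get(name, "")
        if cell is not None and str(cell).strip() != "":
            extra_labs[name] = _parse_float(str(cell), name)
    outcome_cell = str(row.get("outcome", "") or "").strip()
    return PatientRecord(
        patient_id=str(row["patient_id"]).strip(),
        age=_parse_int(str(row["age"]), "age"),
        sex=str(row["sex"]).strip().lower(),
        mechanism=str(row["mechanism"]).strip().lower(),
        damaged_area=str(row["damaged_area"]).strip().lower(),
        gcs=_parse_int(str(row["gcs"]), "gcs"),
        apoe_e4_carrier=_parse_bool(str(row["apoe_e4_carrier"]), "apoe_e4_carrier"),
        crp=_parse_float(str(row["crp"]), "crp"),
        il8=_parse_float(str(row["il8"]), "il8"),
        marshall=str(row["marshall"]).strip().upper(),
        extra_labs=extra_labs,
        outcome=outcome_cell.lower() if outcome_cell else None,
        comorbidities=comorbidities,
    )


# ---------------------------------------------------------------------------
# operations

def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    label: str = "unlabeled",
    strict: bool = False,
) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping ``canonical field name -> column name in the file``
        for files with nonstandard headers. Unmapped canonical names are
        looked up verbatim.
    label
        Set label to attach to the cohort.
    strict
        If True, raise :class:`CohortValidationError` when any row fails
        validation; otherwise invalid rows are collected in
        ``Cohort.rejects``.

    Rows violating record invariants are never silently dropped: they are
    returned in ``Cohort.rejects`` with the 0-based data-row index and the
    reasons.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {src: canonical for canonical, src in schema.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    known = set(CANONICAL_COLUMNS)
    extra_names = [c for c in raw.columns if c not in known]

    records: list[PatientRecord] = []
    rejects: list[RowReject] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(raw.to_dict(orient="records")):
        try:
            rec = _row_to_record(row, extra_names)
        except ValueError as exc:
            rejects.append(RowReject(i, [str(exc)]))
            continue
        reasons = rec.violations()
        if rec.patient_id in seen_ids:
            reasons.append(f"duplicate patient_id {rec.patient_id!r}")
        if reasons:
            rejects.append(RowReject(i, reasons))
        else:
            seen_ids.add(rec.patient_id)
            records.append(rec)
    if strict and rejects:
        raise CohortValidationError(rejects)
    cohort = Cohort(records=records, label=label)
    cohort.rejects = rejects
    return cohort


def write_cohort(cohort: Cohort, path) -> object:
    """Write a cohort to CSV and return the path.

    The written file round-trips: categorical and integer fields compare
    bit-identically after ``read_cohort``, and real-valued fields are written
    with ``repr`` precision so they re-read to the same float.
    """
    frame = cohort.to_dataframe()
    frame.to_csv(path, index=False)
    return path


def split_cohort(
    cohort: Cohort,
    sizes: Sequence[int] = (168, 300, 100, 64),
    seed: int = 0,
) -> tuple[Cohort, Cohort, Cohort, Cohort]:
    """Randomly partition a cohort into the four study sets.

    The default sizes reproduce the study layout: a two-part training set of
    168 and 300 patients (part1 : part2 ≈ 1 : 2), a 100-patient validation
    set and a 64-patient testing set. Assignment is a seeded uniform
    permutation; records beyond ``sum(sizes)`` are left out of all four sets.

    Returns ``(training_part1, training_part2, validation, testing)``,
    pairwise disjoint and deterministic for a fixed seed.
    """
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) != 4 or any(s < 0 for s in sizes):
        raise ValueError(f"sizes must be four non-negative integers, got {sizes}")
    if sum(sizes) > len(cohort):
        raise ValueError(f"requested {sum(sizes)} records but cohort has {len(cohort)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    out: list[Cohort] = []
    start = 0
    for size, lab in zip(sizes, COHORT_LABELS[:4]):
        idx = sorted(int(i) for i in order[start : start + size])
        out.append(cohort.subset(idx, label=lab))
        start += size
    return tuple(out)  # type: ignore[return-value]
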