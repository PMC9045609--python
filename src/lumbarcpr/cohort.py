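"""Cohort substrate: patients, variable dictionaries, delimited-text I/O.

A cohort is one row per patient — demographics, Oswestry Disability Index
(ODI, 0–100 %) and numeric pain rating (NPRS, 0–10) at up to four assessment
times, and an open-ended set of named candidate predictors.  Each predictor
carries analytic metadata in a sidecar *variable dictionary*: its class
(A = treatment-specific / lumbar-stability related, B = adherence related,
C = not treatment specific), its measurement scale, and a hint about which
direction of the scale is expected to predict treatment success.

Files are UTF-8 delimited text; European-style decimal commas are supported
through an explicit :class:`Dialect` (internally everything is point-decimal
floats).  Missing values are empty cells and stay missing through a
write/read round trip.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AssessmentTime",
    "VariableClass",
    "Scale",
    "DirectionHint",
    "DropoutStage",
    "VariableSpec",
    "PatientRecord",
    "Cohort",
    "Dialect",
    "CohortFormatError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "complete_case_subset",
    "default_variables_path",
]

ODI_ELIGIBILITY_FLOOR = 12.0  # minimum baseline ODI (%) for inclusion


class AssessmentTime(IntEnum):
    """Assessment occasions, ordered by week relative to program start."""

    T0 = 0
    T4 = 4
    T8 = 8
    T34 = 34

    @property
    def week(self) -> int:
        return int(self.value)


class VariableClass(Enum):
    A = "A"
    B = "B"
    C = "C"


class Scale(Enum):
    CONTINUOUS = "continuous"
    ORDINAL = "ordinal"
    BINARY = "binary"


class DirectionHint(Enum):
    HIGH_IS_POSITIVE = "high_is_positive"
    LOW_IS_POSITIVE = "low_is_positive"
    UNKNOWN = "unknown"


class DropoutStage(Enum):
    COMPLETED_T34 = "completed_T34"
    LOST_AFTER_T8 = "lost_after_T8"
    LOST_IN_PROGRAM = "lost_in_program"


class CohortFormatError(ValueError):
    """Malformed cohort or variable-dictionary file."""


class CohortValidationError(ValueError):
    """Cohort content violates a domain invariant."""


@dataclass(frozen=True)
class VariableSpec:
    """Analytic metadata for one candidate predictor."""

    name: str
    var_class: VariableClass
    scale: Scale
    direction_hint: DirectionHint = DirectionHint.UNKNOWN


@dataclass
class PatientRecord:
    """One participant.

    ``odi`` / ``nprs`` map assessment times to scores; absent keys are
    missing measurements.  ``predictors`` maps variable names to values
    (``None`` = missing).
    """

    id: str
    sex: str  # "M" | "F"
    age: float
    bmi: float
    odi: dict[AssessmentTime, float] = field(default_factory=dict)
    nprs: dict[AssessmentTime, float] = field(default_factory=dict)
    predictors: dict[str, float | None] = field(default_factory=dict)
    dropout_stage: DropoutStage = DropoutStage.COMPLETED_T34


@dataclass
class Cohort:
    patients: list[PatientRecord]
    variables: list[VariableSpec]
    provenance: str = ""

    @property
    def n(self) -> int:
        return len(self.patients)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def validate(self) -> "Cohort":
        names = self.variable_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CohortValidationError(f"duplicate variable names: {dupes}")
        by_name = {v.name: v for v in self.variables}
        seen_ids: set[str] = set()
        for p in self.patients:
            if p.id in seen_ids:
                raise CohortValidationError(f"duplicate patient id {p.id!r}")
            seen_ids.add(p.id)
            if p.sex not in ("M", "F"):
                raise CohortValidationError(f"patient {p.id}: sex must be M or F")
            for t, v in p.odi.items():
                if not 0.0 <= v <= 100.0:
                    raise CohortValidationError(
                        f"patient {p.id}: ODI at {t.name} = {v} outside [0, 100]"
                    )
            for t, v in p.nprs.items():
                if not 0.0 <= v <= 10.0:
                    raise CohortValidationError(
                        f"patient {p.id}: NPRS at {t.name} = {v} outside [0, 10]"
                    )
            if AssessmentTime.T0 not in p.odi:
                raise CohortValidationError(f"patient {p.id}: baseline ODI missing")
            if p.odi[AssessmentTime.T0] < ODI_ELIGIBILITY_FLOOR:
                raise CohortValidationError(
                    f"patient {p.id}: baseline ODI {p.odi[AssessmentTime.T0]} "
                    f"below eligibility floor {ODI_ELIGIBILITY_FLOOR}"
                )
            for name, value in p.predictors.items():
                if name not in by_name:
                    raise CohortValidationError(
                        f"patient {p.id}: predictor {name!r} not in variable dictionary"
                    )
                spec = by_name[name]
                if (
                    spec.scale is Scale.BINARY
                    and value is not None
                    and value not in (0, 1, 0.0, 1.0)
                ):
                    raise CohortValidationError(
                        f"patient {p.id}: binary variable {name!r} has value {value}"
                    )
        return self

    def to_frame(self) -> pd.DataFrame:
        """Analysis view: one row per patient, NaN for missing cells."""
        rows = []
        for p in self.patients:
            row: dict[str, object] = {
                "id": p.id,
                "sex": p.sex,
                "age": p.age,
                "bmi": p.bmi,
                "dropout_stage": p.dropout_stage.value,
            }
            for t in AssessmentTime:
                row[f"odi_{t.name}"] = p.odi.get(t, math.nan)
                row[f"nprs_{t.name}"] = p.nprs.get(t, math.nan)
            for v in self.variables:
                val = p.predictors.get(v.name)
                row[v.name] = math.nan if val is None else val
            rows.append(row)
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df.set_index("id", drop=False)
        return df


@dataclass(frozen=True)
class Dialect:
    """Delimited-text conventions for cohort files."""

    delimiter: str = ","
    decimal: str = "."

    def __post_init__(self) -> None:
        if self.decimal not in (".", ","):
            raise ValueError("decimal must be '.' or ','")
        if self.decimal == self.delimiter:
            raise ValueError("decimal separator cannot equal the field delimiter")


_FIXED_COLUMNS = ["id", "sex", "age", "bmi", "dropout_stage"]
_TIME_COLUMNS = [f"{m}_{t.name}" for m in ("odi", "nprs") for t in AssessmentTime]


def _fmt(value: float | None, dialect: Dialect) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    text = repr(float(value))
    if dialect.decimal == ",":
        text = text.replace(".", ",")
    return text


def _parse(cell: str, column: str, dialect: Dialect) -> float | None:
    cell = cell.strip()
    if not cell:
        return None
    if dialect.decimal == ",":
        cell = cell.replace(",", ".")
    try:
        return float(cell)
    except ValueError as exc:
        raise CohortFormatError(f"column {column!r}: cannot parse {cell!r}") from exc


def default_variables_path(path: Path | str) -> Path:
    """Sidecar dictionary path: cohort.csv -> cohort.variables.csv."""
    path = Path(path)
    return path.with_name(path.stem + ".variables" + path.suffix)


def write_cohort(
    cohort: Cohort,
    path: Path | str,
    variables_path: Path | str | None = None,
    dialect: Dialect = Dialect(),
) -> None:
    """Write a validated cohort plus its sidecar variable dictionary.

    The written form round-trips exactly through :func:`read_cohort`
    (values via ``repr``, missing cells as blanks).
    """
    cohort.validate()
    path = Path(path)
    variables_path = Path(variables_path) if variables_path else default_variables_path(path)

    header = _FIXED_COLUMNS + _TIME_COLUMNS + cohort.variable_names
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        w.writerow(header)
        for p in cohort.patients:
            row = [p.id, p.sex, _fmt(p.age, dialect), _fmt(p.bmi, dialect), p.dropout_stage.value]
            for measure in ("odi", "nprs"):
                store = getattr(p, measure)
                for t in AssessmentTime:
                    row.append(_fmt(store.get(t), dialect))
            for name in cohort.variable_names:
                row.append(_fmt(p.predictors.get(name), dialect))
            w.writerow(row)

    with open(variables_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        w.writerow(["name", "class", "scale", "direction_hint"])
        for v in cohort.variables:
            w.writerow([v.name, v.var_class.value, v.scale.value, v.direction_hint.value])


def _read_variables(path: Path, dialect: Dialect) -> list[VariableSpec]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise CohortFormatError(f"{path}: empty variable dictionary") from exc
        expected = ["name", "class", "scale", "direction_hint"]
        if [h.strip() for h in header] != expected:
            raise CohortFormatError(
                f"{path}: variable dictionary header must be {expected}, got {header}"
            )
        specs = []
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            name, klass, scale, hint = (cell.strip() for cell in row[:4])
            try:
                var_class = VariableClass(klass)
            except ValueError as exc:
                raise CohortValidationError(
                    f"variable {name!r}: unknown class {klass!r} (expected A, B or C)"
                ) from exc
            try:
                specs.append(
                    VariableSpec(name, var_class, Scale(scale), DirectionHint(hint))
                )
            except ValueError as exc:
                raise CohortFormatError(f"variable {name!r}: {exc}") from exc
    return specs


def read_cohort(
    path: Path | str,
    variables_path: Path | str | None = None,
    dialect: Dialect = Dialect(),
) -> Cohort:
    """Read and validate a cohort file written by :func:`write_cohort`."""
    path = Path(path)
    variables_path = Path(variables_path) if variables_path else default_variables_path(path)
    variables = _read_variables(variables_path, dialect)

    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise CohortFormatError(f"{path}: empty file") from exc
        header = [h.strip() for h in header]
        prefix = _FIXED_COLUMNS + _TIME_COLUMNS
        if header[: len(prefix)] != prefix:
            missing = [c for c in prefix if c not in header]
            raise CohortFormatError(
                f"{path}: malformed header; expected leading columns {prefix}"
                + (f" (missing {missing})" if missing else "")
            )
        predictor_cols = header[len(prefix):]
        known = {v.name for v in variables}
        unknown = [c for c in predictor_cols if c not in known]
        if unknown:
            raise CohortFormatError(
                f"{path}: predictor columns {unknown} absent from variable dictionary"
            )

        patients = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise CohortFormatError(
                    f"{path}:{lineno}: expected {len(header)} cells, got {len(row)}"
                )
            cells = dict(zip(header, row))
            try:
                stage = DropoutStage(cells["dropout_stage"].strip())
            except ValueError as exc:
                raise CohortFormatError(
                    f"{path}:{lineno}: unknown dropout_stage {cells['dropout_stage']!r}"
                ) from exc
            odi: dict[AssessmentTime, float] = {}
            nprs: dict[AssessmentTime, float] = {}
            for t in AssessmentTime:
                for measure, store in (("odi", odi), ("nprs", nprs)):
                    v = _parse(cells[f"{measure}_{t.name}"], f"{measure}_{t.name}", dialect)
                    if v is not None:
                        store[t] = v
            age = _parse(cells["age"], "age", dialect)
            bmi = _parse(cells["bmi"], "bmi", dialect)
            patients.append(
                PatientRecord(
                    id=cells["id"].strip(),
                    sex=cells["sex"].strip(),
                    age=math.nan if age is None else age,
                    bmi=math.nan if bmi is None else bmi,
                    odi=odi,
                    nprs=nprs,
                    predictors={c: _parse(cells[c], c, dialect) for c in predictor_cols},
                    dropout_stage=stage,
                )
            )

    return Cohort(patients=patients, variables=variables, provenance=str(path)).validate()


def complete_case_subset(
    cohort: Cohort,
    variables: Sequence[str],
    time: AssessmentTime,
) -> Cohort:
    """Patients with non-missing values for all named variables and for ODI
    at baseline and ``time``.

    Complete-case filtering is applied per analysis (each stage logs its own
    exclusions); the operation is idempotent.
    """
    known = set(cohort.variable_names)
    bad = [v for v in variables if v not in known]
    if bad:
        raise KeyError(f"unknown variables: {bad}")
    kept = []
    for p in cohort.patients:
        if AssessmentTime.T0 not in p.odi or time not in p.odi:
            continue
        if any(p.predictors.get(v) is None for v in variables):
            continue
        kept.append(p)
    removed = cohort.n - len(kept)
    if removed:
        log.info(
            "complete_case_subset: removed %d of %d patients (variables=%s, time=%s)",
            removed, cohort.n, list(variables), time.name,
        )
    return Cohort(patients=kept, variables=list(cohort.variables),
                  provenance=cohort.provenance)
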