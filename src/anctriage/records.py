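"""Domain records and file I/O for participants, visits and assessments.

Files are CSV or JSON-lines (chosen by extension: ``.jsonl``/``.ndjson`` for
JSON-lines, anything else CSV). Dates are ISO-8601 strings, missing optional
numerics are empty fields (CSV) / ``null`` (JSON); invalid rows are collected
and reported together rather than aborting on the first error.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import pydantic
from pydantic import BaseModel, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "Arm",
    "VisitType",
    "ParticipantRecord",
    "VisitRecord",
    "RowError",
    "SchemaError",
    "RecordValidationError",
    "ReadResult",
    "read_participants",
    "read_visits",
    "write_participants",
    "write_visits",
    "write_assessments",
    "read_assessments",
    "PARTICIPANT_COLUMNS",
    "VISIT_COLUMNS",
    "ASSESSMENT_COLUMNS",
]


class Arm(str, Enum):
    intervention = "intervention"
    control = "control"


class VisitType(str, Enum):
    antenatal = "antenatal"
    postpartum_week1 = "postpartum_week1"
    postpartum_week6 = "postpartum_week6"


class ParticipantRecord(BaseModel):
    """One enrolled woman: identity, arm, cluster, dates, anthropometry."""

    participant_id: str
    cluster_id: str
    arm: Arm
    date_of_birth: date
    registration_date: date
    height: float  # metres
    weight: float  # kilograms, at booking
    lmp_date: date
    delivery_date: Optional[date] = None
    schooling_years: int = pydantic.Field(ge=0)
    household_size: int = pydantic.Field(ge=1)
    booking_hb: Optional[float] = None  # g/dL

    @model_validator(mode="after")
    def _invariants(self) -> "ParticipantRecord":
        if self.registration_date <= self.date_of_birth:
            raise ValueError("registration_date must be after date_of_birth")
        if self.lmp_date >= self.registration_date:
            raise ValueError("lmp_date must be before registration_date")
        if self.delivery_date is not None and self.delivery_date <= self.lmp_date:
            raise ValueError("delivery_date must be after lmp_date")
        if not (0.5 < self.height < 2.5):
            raise ValueError("height out of (0.5, 2.5) m")
        if not (25 < self.weight < 200):
            raise ValueError("weight out of (25, 200) kg")
        if self.booking_hb is not None and not (2 <= self.booking_hb <= 20):
            raise ValueError("booking_hb out of [2, 20] g/dL")
        return self


class VisitRecord(BaseModel):
    """One home-visit measurement set plus ANC-practice and entry flags."""

    participant_id: str
    visit_type: VisitType
    visit_date: date
    sbp: float  # mmHg
    dbp: float  # mmHg
    heart_rate: float  # bpm
    hb: float  # g/dL
    ogtt_2h_glucose: Optional[float] = None  # mg/dL
    gdm_screened: bool = False
    ogtt_done: bool = False
    ifa_supplied: bool = False
    entry_complete: bool = True
    entry_on_time: bool = True

    @model_validator(mode="after")
    def _invariants(self) -> "VisitRecord":
        if not (30 <= self.sbp <= 300):
            raise ValueError("sbp out of [30, 300] mmHg")
        if not (0 <= self.dbp <= 300):
            raise ValueError("dbp out of [0, 300] mmHg")
        if self.sbp <= self.dbp:
            raise ValueError("sbp > dbp violated")
        if not (20 <= self.heart_rate <= 250):
            raise ValueError("heart_rate out of [20, 250] bpm")
        if not (2 <= self.hb <= 20):
            raise ValueError("hb out of [2, 20] g/dL")
        if self.ogtt_2h_glucose is not None and not (30 <= self.ogtt_2h_glucose <= 600):
            raise ValueError("ogtt_2h_glucose out of [30, 600] mg/dL")
        return self


PARTICIPANT_COLUMNS = [
    "participant_id", "cluster_id", "arm", "date_of_birth", "registration_date",
    "height_m", "weight_kg", "lmp_date", "delivery_date", "schooling_years",
    "household_size", "booking_hb",
]

VISIT_COLUMNS = [
    "participant_id", "visit_type", "visit_date", "sbp", "dbp", "heart_rate",
    "hb", "ogtt_2h_glucose", "gdm_screened", "ogtt_done", "ifa_supplied",
    "entry_complete", "entry_on_time",
]

ASSESSMENT_COLUMNS = [
    "participant_id", "visit_type", "bp_color", "hb_color", "gdm_color",
    "overall_color", "recommendations", "missing_practices",
    "age", "bmi", "gestational_age_days", "edd", "shock_index", "postpartum_day",
]

_PARTICIPANT_OPTIONAL = {"delivery_date", "booking_hb"}
_VISIT_OPTIONAL = {"ogtt_2h_glucose"}
_VISIT_BOOLS = {"gdm_screened", "ogtt_done", "ifa_supplied", "entry_complete", "entry_on_time"}


class SchemaError(ValueError):
    """A required column/key is missing from an input file."""


@dataclass(frozen=True)
class RowError:
    """One diagnostic for one rejected input row."""

    row_index: int  # 0-based data-row index
    record_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row_index} (id={self.record_id}): {self.field}: {self.message}"


class RecordValidationError(ValueError):
    """Raised when one or more rows violate record invariants."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        lines = "; ".join(str(e) for e in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


@dataclass
class ReadResult:
    """Records plus collected row diagnostics; ``dialect`` notes variants
    such as a ``height_cm`` column being converted to metres."""

    records: list = field(default_factory=list)
    errors: list[RowError] = field(default_factory=list)
    dialect: str = "standard"


# ---------------------------------------------------------------------------
# low-level row transport


def _is_jsonl(path: Path) -> bool:
    return path.suffix.lower() in {".jsonl", ".ndjson", ".json"}


def _iter_rows(path: Path, required: Sequence[str], optional_alias: dict[str, str] | None = None):
    """Yield (row_index, dict) rows; raise SchemaError on missing columns.

    ``optional_alias`` maps an alternative column name to the canonical one
    (the CSV header may carry either). Returns also the dialect label.
    """
    optional_alias = optional_alias or {}
    if _is_jsonl(path):
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                for canon, alias in optional_alias.items():
                    if canon not in obj and alias in obj:
                        obj[canon] = obj.pop(alias)
                missing = [c for c in required if c not in obj]
                if missing:
                    raise SchemaError(f"missing required column {missing[0]!r} (row {i})")
                rows.append((i, obj))
        dialect = "standard"
        return rows, dialect
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        dialect = "standard"
        alias_used = {}
        for canon, alias in optional_alias.items():
            if canon not in header and alias in header:
                alias_used[alias] = canon
                dialect = alias
        missing = [c for c in required if c not in header and c not in alias_used.values()]
        if missing:
            raise SchemaError(f"missing required column {missing[0]!r}")
        rows = []
        for i, row in enumerate(reader):
            row = {alias_used.get(k, k): v for k, v in row.items() if k is not None}
            rows.append((i, row))
    return rows, dialect


def _cell(value: Any) -> Any:
    """CSV empty-string -> None."""
    if value is None:
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return value


def _parse_bool(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {value!r}")


# ---------------------------------------------------------------------------
# participants


def load_participants(path: str | Path) -> ReadResult:
    """Read participant records, collecting per-row diagnostics."""
    path = Path(path)
    required = [c for c in PARTICIPANT_COLUMNS if c not in {"delivery_date", "booking_hb"}]
    rows, dialect = _iter_rows(path, required, optional_alias={"height_m": "height_cm"})
    result = ReadResult(dialect=dialect)
    for i, row in rows:
        rid = str(row.get("participant_id", "?"))
        try:
            height = float(_cell(row["height_m"]))
            if dialect == "height_cm":
                height = height / 100.0
            rec = ParticipantRecord(
                participant_id=str(row["participant_id"]),
                cluster_id=str(row["cluster_id"]),
                arm=row["arm"],
                date_of_birth=row["date_of_birth"],
                registration_date=row["registration_date"],
                height=height,
                weight=float(_cell(row["weight_kg"])),
                lmp_date=row["lmp_date"],
                delivery_date=_cell(row.get("delivery_date")),
                schooling_years=int(_cell(row["schooling_years"])),
                household_size=int(_cell(row["household_size"])),
                booking_hb=_maybe_float(_cell(row.get("booking_hb"))),
            )
            result.records.append(rec)
        except pydantic.ValidationError as exc:
            for err in exc.errors():
                fld = str(err["loc"][0]) if err["loc"] else "record"
                result.errors.append(RowError(i, rid, fld, err["msg"]))
        except (TypeError, ValueError) as exc:
            result.errors.append(RowError(i, rid, "record", str(exc)))
    if dialect != "standard":
        logger.info("read %s using dialect %r", path, dialect)
    return result


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read participants; raise :class:`RecordValidationError` listing every
    invalid row if any fails its invariants."""
    result = load_participants(path)
    if result.errors:
        raise RecordValidationError(result.errors)
    return result.records


def _maybe_float(value: Any) -> Optional[float]:
    return None if value is None else float(value)


def write_participants(path: str | Path, records: Iterable[ParticipantRecord]) -> None:
    path = Path(path)
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "cluster_id": r.cluster_id,
            "arm": r.arm.value,
            "date_of_birth": r.date_of_birth.isoformat(),
            "registration_date": r.registration_date.isoformat(),
            "height_m": repr(r.height),
            "weight_kg": repr(r.weight),
            "lmp_date": r.lmp_date.isoformat(),
            "delivery_date": "" if r.delivery_date is None else r.delivery_date.isoformat(),
            "schooling_years": r.schooling_years,
            "household_size": r.household_size,
            "booking_hb": "" if r.booking_hb is None else repr(r.booking_hb),
        })
    _write_rows(path, PARTICIPANT_COLUMNS, rows)


# ---------------------------------------------------------------------------
# visits


def load_visits(path: str | Path) -> ReadResult:
    """Read visit records, collecting per-row diagnostics."""
    path = Path(path)
    required = [c for c in VISIT_COLUMNS if c not in _VISIT_OPTIONAL]
    rows, dialect = _iter_rows(path, required)
    result = ReadResult(dialect=dialect)
    for i, row in rows:
        rid = str(row.get("participant_id", "?"))
        try:
            rec = VisitRecord(
                participant_id=str(row["participant_id"]),
                visit_type=row["visit_type"],
                visit_date=row["visit_date"],
                sbp=float(_cell(row["sbp"])),
                dbp=float(_cell(row["dbp"])),
                heart_rate=float(_cell(row["heart_rate"])),
                hb=float(_cell(row["hb"])),
                ogtt_2h_glucose=_maybe_float(_cell(row.get("ogtt_2h_glucose"))),
                **{k: _parse_bool(_cell(row[k])) for k in _VISIT_BOOLS},
            )
            result.records.append(rec)
        except pydantic.ValidationError as exc:
            for err in exc.errors():
                fld = str(err["loc"][0]) if err["loc"] else "record"
                result.errors.append(RowError(i, rid, fld, err["msg"]))
        except (TypeError, ValueError) as exc:
            result.errors.append(RowError(i, rid, "record", str(exc)))
    return result


def read_visits(path: str | Path) -> list[VisitRecord]:
    result = load_visits(path)
    if result.errors:
        raise RecordValidationError(result.errors)
    return result.records


def write_visits(path: str | Path, records: Iterable[VisitRecord]) -> None:
    path = Path(path)
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "visit_type": r.visit_type.value,
            "visit_date": r.visit_date.isoformat(),
            "sbp": repr(r.sbp),
            "dbp": repr(r.dbp),
            "heart_rate": repr(r.heart_rate),
            "hb": repr(r.hb),
            "ogtt_2h_glucose": "" if r.ogtt_2h_glucose is None else repr(r.ogtt_2h_glucose),
            **{k: str(getattr(r, k)).lower() for k in _VISIT_BOOLS},
        })
    _write_rows(path, VISIT_COLUMNS, rows)


# ---------------------------------------------------------------------------
# assessments (serialization lives here; the Assessment type is defined in
# rules_engine to avoid a circular import)


def write_assessments(path: str | Path, assessments: Iterable) -> None:
    """Write assessments with a deterministic column order (re-readable)."""
    path = Path(path)
    rows = []
    for a in assessments:
        d = a.derived
        rows.append({
            "participant_id": a.participant_id,
            "visit_type": a.visit_type.value if a.visit_type is not None else "",
            "bp_color": a.bp_color.name.lower(),
            "hb_color": a.hb_color.name.lower(),
            "gdm_color": "" if a.gdm_color is None else a.gdm_color.name.lower(),
            "overall_color": a.overall_color.name.lower(),
            "recommendations": ";".join(rec.code for rec in a.recommendations),
            "missing_practices": ";".join(a.missing_practices),
            "age": "" if d is None else d.age,
            "bmi": "" if d is None else repr(d.bmi),
            "gestational_age_days": "" if d is None else d.gestational_age_days,
            "edd": "" if d is None else d.edd.isoformat(),
            "shock_index": "" if d is None else repr(d.shock_index),
            "postpartum_day": "" if d is None or d.postpartum_day is None else d.postpartum_day,
        })
    _write_rows(path, ASSESSMENT_COLUMNS, rows)


def read_assessments(path: str | Path, catalogue: dict[str, str] | None = None) -> list:
    """Read assessments back; recommendation texts are re-attached from the
    catalogue (text is presentation, codes are the data)."""
    from . import rules_engine as re_mod
    from .derived import DerivedVars

    if catalogue is None:
        from ._config import load_recommendations

        catalogue = load_recommendations()
    path = Path(path)
    rows, _ = _iter_rows(path, ["participant_id", "overall_color"])
    out = []
    for _, row in rows:
        codes = [c for c in str(row.get("recommendations") or "").split(";") if c]
        missing = [m for m in str(row.get("missing_practices") or "").split(";") if m]
        age = _cell(row.get("age"))
        derived = None
        if age is not None:
            derived = DerivedVars(
                age=int(age),
                bmi=float(_cell(row["bmi"])),
                gestational_age_days=int(_cell(row["gestational_age_days"])),
                edd=date.fromisoformat(str(_cell(row["edd"]))),
                shock_index=float(_cell(row["shock_index"])),
                postpartum_day=(None if _cell(row.get("postpartum_day")) is None
                                else int(_cell(row["postpartum_day"]))),
            )
        vt = _cell(row.get("visit_type"))
        out.append(re_mod.Assessment(
            participant_id=str(row["participant_id"]),
            visit_type=None if vt is None else VisitType(vt),
            bp_color=re_mod.TrafficLight[str(row["bp_color"]).upper()],
            hb_color=re_mod.TrafficLight[str(row["hb_color"]).upper()],
            gdm_color=(None if _cell(row.get("gdm_color")) is None
                       else re_mod.TrafficLight[str(row["gdm_color"]).upper()]),
            overall_color=re_mod.TrafficLight[str(row["overall_color"]).upper()],
            recommendations=tuple(
                re_mod.Recommendation(code=c, text=catalogue.get(c, "")) for c in codes
            ),
            missing_practices=tuple(missing),
            derived=derived,
        ))
    return out


def _write_rows(path: Path, columns: Sequence[str], rows: list[dict]) -> None:
    if _is_jsonl(path):
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps({c: _json_cell(row.get(c)) for c in columns}) + "\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns))
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def _json_cell(value: Any) -> Any:
    if isinstance(value, str):
        if value == "":
            return None
        try:
            f = float(value)
        except ValueError:
            return value
        return int(f) if f.is_integer() and "." not in value and "e" not in value else f
    return value
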