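"""Claims data model: table schemas, readers/writers, and covariate derivation.

The pipeline works on five flat claims tables (patients, facilities,
consultations, diagnoses, prescriptions) held together in a
:class:`ClaimsBundle`.  This module also owns the covariate conventions used
by every downstream stage: nine age bins, in/out-of-hours visit
classification, the April-to-March fiscal year, and the five-level facility
category.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "IntegrityError",
    "ClaimsParseError",
    "ReadConfig",
    "ClaimsBundle",
    "AGE_BINS",
    "AGE_GROUP_LABELS",
    "FACILITY_CATEGORIES",
    "SPECIALTIES",
    "MAX_AGE",
    "read_claims",
    "derive_age_group",
    "classify_visit_hours",
    "fiscal_year",
    "facility_category",
    "ym_index",
]


class SchemaError(ValueError):
    """A table is missing a required column or has an invalid header."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


class ClaimsParseError(ValueError):
    """A field value could not be parsed (reports the offending row)."""


# Age bins: (low, high) in completed years, inclusive.  The database covers
# ages strictly below 75, so the open-ended top bin is capped at 74.
AGE_BINS: tuple[tuple[int, int, str], ...] = (
    (0, 3, "0-3"),
    (4, 6, "4-6"),
    (7, 12, "7-12"),
    (13, 18, "13-18"),
    (19, 29, "19-29"),
    (30, 39, "30-39"),
    (40, 49, "40-49"),
    (50, 59, "50-59"),
    (60, 74, "60-"),
)
AGE_GROUP_LABELS: tuple[str, ...] = tuple(b[2] for b in AGE_BINS)
MAX_AGE = 74

FACILITY_CATEGORIES: tuple[str, ...] = (
    "clinic_without_beds",
    "clinic_with_beds",
    "other_hospital",
    "university_hospital",
    "public_hospital",
)

SPECIALTIES: tuple[str, ...] = ("internal_medicine", "paediatrics", "ENT", "others")

SEXES = ("male", "female")
INSURED_STATUSES = ("member", "family_member")
VISIT_HOURS = ("in_hours", "out_of_hours")

TABLE_NAMES = ("patients", "facilities", "consultations", "diagnoses", "prescriptions")

REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "patients": ("patient_id", "sex", "birth_year_month", "insured_status"),
    "facilities": ("facility_id", "bed_count", "is_university", "is_public", "specialty"),
    "consultations": ("patient_id", "facility_id", "date", "visit_slot"),
    "diagnoses": ("patient_id", "facility_id", "code", "diagnosis_date"),
    "prescriptions": ("patient_id", "facility_id", "date", "atc_code"),
}

_YM_RE = re.compile(r"^(\d{4})-(\d{2})$")
_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2})$")


@dataclass(frozen=True)
class ReadConfig:
    """Parsing options for :func:`read_claims`.

    delimiter: field separator of the five tables.
    visit_slot_dialect: ``"clock"`` when ``visit_slot`` holds an HH:MM time,
        ``"flag"`` when it is pre-coded as in_hours/out_of_hours.
    holidays: extra non-working dates on top of weekends (ISO date strings
        or :class:`datetime.date`); default is weekends only.
    """

    delimiter: str = ","
    visit_slot_dialect: str = "clock"
    holidays: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.visit_slot_dialect not in ("clock", "flag"):
            raise ValueError(f"unknown visit_slot_dialect: {self.visit_slot_dialect!r}")
        parsed = frozenset(
            d if isinstance(d, dt.date) else dt.date.fromisoformat(str(d))
            for d in self.holidays
        )
        object.__setattr__(self, "holidays", parsed)


@dataclass
class ClaimsBundle:
    """The five validated claims tables plus reader warnings."""

    patients: pd.DataFrame
    facilities: pd.DataFrame
    consultations: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    config: ReadConfig = field(default_factory=ReadConfig)
    warnings: list = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the five tables as delimited text; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = {}
        for name in TABLE_NAMES:
            df = self.table(name).copy()
            for col in ("date", "diagnosis_date"):
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
            path = directory / f"{name}.csv"
            df.to_csv(path, sep=self.config.delimiter, index=False)
            out[name] = path
        return out

    def __eq__(self, other: object) -> bool:  # table-wise equality, warnings ignored
        if not isinstance(other, ClaimsBundle):
            return NotImplemented
        return all(
            self.table(n).reset_index(drop=True).equals(other.table(n).reset_index(drop=True))
            for n in TABLE_NAMES
        )


def ym_index(ym: str) -> int:
    """Months since year 0 for a ``YYYY-MM`` string (monotone month counter)."""
    m = _YM_RE.match(str(ym))
    if not m:
        raise ClaimsParseError(f"invalid year-month: {ym!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ClaimsParseError(f"invalid year-month: {ym!r}")
    return year * 12 + (month - 1)


def derive_age_group(birth_year_month: str, consultation_date) -> str:
    """Age bin at consultation, on year-month granularity.

    Age is completed years with the birth day treated as the 1st of the
    month, i.e. ``(consultation_ym - birth_ym) // 12``.
    """
    b = ym_index(birth_year_month)
    d = pd.Timestamp(consultation_date)
    c = d.year * 12 + (d.month - 1)
    age = (c - b) // 12
    if age < 0:
        raise IntegrityError(
            f"birth {birth_year_month} is after consultation {d.date()}"
        )
    if age > MAX_AGE:
        raise IntegrityError(f"age {age} exceeds database coverage (< 75 years)")
    for lo, hi, label in AGE_BINS:
        if lo <= age <= hi:
            return label
    raise AssertionError("unreachable: bins partition 0..74")


def _parse_clock(slot: str) -> dt.time:
    m = _CLOCK_RE.match(str(slot).strip())
    if not m:
        raise ClaimsParseError(f"unparseable clock time in visit_slot: {slot!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh > 23 or mm > 59:
        raise ClaimsParseError(f"unparseable clock time in visit_slot: {slot!r}")
    return dt.time(hh, mm)


def classify_visit_hours(date, visit_slot, holidays: Iterable = ()) -> str:
    """Classify a visit as ``in_hours`` or ``out_of_hours``.

    In-hours means [08:00, 18:00) on a weekday that is not a holiday;
    everything else (evenings, nights, weekends, holidays) is out-of-hours.
    A pre-coded flag value is returned as-is.
    """
    slot = str(visit_slot).strip()
    if slot in VISIT_HOURS:
        return slot
    t = _parse_clock(slot)
    d = pd.Timestamp(date).date()
    hols = {
        h if isinstance(h, dt.date) else dt.date.fromisoformat(str(h)) for h in holidays
    }
    if d.weekday() >= 5 or d in hols:
        return "out_of_hours"
    return "in_hours" if dt.time(8, 0) <= t < dt.time(18, 0) else "out_of_hours"


def fiscal_year(date) -> int:
    """April-to-March fiscal year, labelled by the calendar year of April."""
    d = pd.Timestamp(date)
    return d.year if d.month >= 4 else d.year - 1


def facility_category(bed_count: int, is_university: bool = False, is_public: bool = False) -> str:
    """Five-level facility category.

    The university flag wins over bed counts, then the public
    (national-or-municipal) flag; otherwise 0 beds is a clinic without beds,
    1-19 a clinic with beds, and >= 20 another hospital.
    """
    if is_university and is_public:
        raise IntegrityError("facility flagged both university and public")
    if is_university:
        return "university_hospital"
    if is_public:
        return "public_hospital"
    bed_count = int(bed_count)
    if bed_count < 0:
        raise IntegrityError(f"negative bed_count: {bed_count}")
    if bed_count == 0:
        return "clinic_without_beds"
    if bed_count <= 19:
        return "clinic_with_beds"
    return "other_hospital"


def _check_columns(name: str, df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS[name]:
        if col not in df.columns:
            raise SchemaError(f"table {name!r} is missing required column {col!r}")


def _parse_dates(name: str, df: pd.DataFrame, col: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ClaimsParseError(
            f"table {name!r}, column {col!r}: unparseable date {df[col][bad].iloc[0]!r} at row {row}"
        )
    if df[col].isna().any():
        row = int(df[col].isna().idxmax())
        raise ClaimsParseError(f"table {name!r}, column {col!r}: missing date at row {row}")
    return parsed


def _as_bool(name: str, s: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False, "": False,
        "yes": True, "no": False,
    }
    def conv(v):
        if isinstance(v, (bool,)):
            return v
        if pd.isna(v):
            return False
        key = str(v).strip().lower()
        if key not in mapping:
            raise ClaimsParseError(f"table {name!r}: unparseable boolean {v!r}")
        return mapping[key]
    return s.map(conv)


def read_claims(
    paths: Mapping[str, str | Path] | str | Path,
    config: ReadConfig | None = None,
) -> ClaimsBundle:
    """Read and validate the five claims tables.

    ``paths`` is either a mapping from table name to file path or a directory
    containing ``patients.csv`` ... ``prescriptions.csv``.  Validation covers
    the column schema, date parsing, referential integrity (every
    consultation/diagnosis/prescription patient resolves; consultation and
    diagnosis facilities resolve), the birth-before-consultation invariant,
    and collapses duplicate (patient, facility, date) consultations to one
    row with a logged warning.
    """
    config = config or ReadConfig()
    if not isinstance(paths, Mapping):
        directory = Path(paths)
        paths = {name: directory / f"{name}.csv" for name in TABLE_NAMES}
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(f"missing claims table file: {path}")
        df = pd.read_csv(path, sep=config.delimiter, dtype=str, keep_default_na=False)
        df = df.replace({"": None}) if name == "prescriptions" else df
        _check_columns(name, df)
        tables[name] = df

    warnings: list[str] = []

    patients = tables["patients"].copy()
    if patients["patient_id"].duplicated().any():
        dups = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise IntegrityError(f"duplicate patient_id values: {dups}")
    for ym in patients["birth_year_month"]:
        ym_index(ym)  # raises on malformed values
    bad_sex = ~patients["sex"].isin(SEXES)
    if len(patients) and bad_sex.any():
        raise ClaimsParseError(f"invalid sex value: {patients['sex'][bad_sex].iloc[0]!r}")
    bad_ins = ~patients["insured_status"].isin(INSURED_STATUSES)
    if len(patients) and bad_ins.any():
        raise ClaimsParseError(
            f"invalid insured_status value: {patients['insured_status'][bad_ins].iloc[0]!r}"
        )

    facilities = tables["facilities"].copy()
    if facilities["facility_id"].duplicated().any():
        dups = facilities.loc[facilities["facility_id"].duplicated(), "facility_id"].tolist()
        raise IntegrityError(f"duplicate facility_id values: {dups}")
    facilities["bed_count"] = pd.to_numeric(facilities["bed_count"], errors="raise").astype(int)
    facilities["is_university"] = _as_bool("facilities", facilities["is_university"])
    facilities["is_public"] = _as_bool("facilities", facilities["is_public"])
    bad_spec = ~facilities["specialty"].isin(SPECIALTIES)
    if len(facilities) and bad_spec.any():
        raise ClaimsParseError(
            f"invalid specialty value: {facilities['specialty'][bad_spec].iloc[0]!r}"
        )

    consultations = tables["consultations"].copy()
    consultations["date"] = _parse_dates("consultations", consultations, "date")
    diagnoses = tables["diagnoses"].copy()
    diagnoses["diagnosis_date"] = _parse_dates("diagnoses", diagnoses, "diagnosis_date")
    if len(diagnoses) and (diagnoses["code"].astype(str).str.strip() == "").any():
        raise ClaimsParseError("table 'diagnoses': empty diagnosis code")
    prescriptions = tables["prescriptions"].copy()
    prescriptions["date"] = _parse_dates("prescriptions", prescriptions, "date")
    if len(prescriptions):
        atc = prescriptions["atc_code"].astype(str)
        bad_atc = ~atc.str.match(r"^[A-Z][0-9A-Z]*$")
        if bad_atc.any():
            raise ClaimsParseError(
                f"invalid atc_code (must be uppercase, letter-initial): {atc[bad_atc].iloc[0]!r}"
            )

    known_patients = set(patients["patient_id"])
    known_facilities = set(facilities["facility_id"])
    for name, df, fk, known in (
        ("consultations", consultations, "patient_id", known_patients),
        ("consultations", consultations, "facility_id", known_facilities),
        ("diagnoses", diagnoses, "patient_id", known_patients),
        ("diagnoses", diagnoses, "facility_id", known_facilities),
        ("prescriptions", prescriptions, "patient_id", known_patients),
    ):
        if not len(df):
            continue
        missing = ~df[fk].isin(known)
        if missing.any():
            offenders = sorted(set(df.loc[missing, fk]))
            raise IntegrityError(
                f"table {name!r}: {fk} values with no matching record: {offenders}"
            )

    n_before = len(consultations)
    consultations = consultations.drop_duplicates(
        subset=["patient_id", "facility_id", "date"], keep="first"
    ).reset_index(drop=True)
    n_dup = n_before - len(consultations)
    if n_dup:
        msg = f"collapsed {n_dup} duplicate (patient, facility, date) consultation rows"
        warnings.append(msg)
        logger.warning(msg)

    if len(consultations):
        birth = patients.set_index("patient_id")["birth_year_month"]
        b_idx = consultations["patient_id"].map(birth).map(ym_index)
        c_idx = consultations["date"].dt.year * 12 + (consultations["date"].dt.month - 1)
        late = b_idx > c_idx
        if late.any():
            offenders = sorted(set(consultations.loc[late, "patient_id"]))
            raise IntegrityError(
                f"patients born after a linked consultation: {offenders}"
            )

    return ClaimsBundle(
        patients=patients,
        facilities=facilities,
        consultations=consultations,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        config=config,
        warnings=warnings,
    )
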