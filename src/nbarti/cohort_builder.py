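"""Build the analysis cohort of non-bacterial ARTI consultations.

Pipeline stages, run in order by :func:`build_cohort`:

1. link each consultation to the diagnoses made for the same patient within
   the lookback window (default 30 days, both endpoints and the same day
   inclusive);
2. keep consultations whose active codes include at least one acute
   respiratory tract infection class (ICD-10 J00-J06, J20-J22);
3. drop consultations carrying any active code judged to require
   antibiotics;
4. label each remaining consultation with its diagnosis category;
5. link same-date J01 prescriptions and derive the antibiotic-class outcome.

Covariates (age group, visit hours, fiscal year, facility category, ...) are
attached via :mod:`nbarti.claims_model` conventions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import claims_model as cm
from .appropriateness import AppropriatenessTable, classify_antibiotic

logger = logging.getLogger(__name__)

__all__ = [
    "ARTI_CLASSES",
    "DIAGNOSIS_CATEGORIES",
    "LinkageWindow",
    "Cohort",
    "link_active_diagnoses",
    "select_arti_consultations",
    "exclude_bacterial",
    "label_diagnosis_category",
    "link_prescriptions",
    "build_cohort",
]

ARTI_CLASSES = frozenset(
    {"J00", "J01", "J02", "J03", "J04", "J05", "J06", "J20", "J21", "J22"}
)

_SINGLE_CATEGORIES = frozenset({"J20", "J06", "J02", "J00", "J03"})
_PAIR_CATEGORIES = frozenset(
    {
        frozenset({"J06", "J20"}),
        frozenset({"J02", "J20"}),
        frozenset({"J02", "J06"}),
        frozenset({"J00", "J20"}),
        frozenset({"J00", "J06"}),
    }
)
DIAGNOSIS_CATEGORIES: tuple[str, ...] = (
    "J20",
    "J06",
    "J02",
    "J00",
    "J06 & J20",
    "J02 & J20",
    "J03",
    "J02 & J06",
    "J00 & J20",
    "J00 & J06",
    "others",
)

COHORT_COLUMNS = (
    "patient_id",
    "facility_id",
    "date",
    "active_codes",
    "diagnosis_category",
    "sex",
    "age_group",
    "insured_status",
    "specialty",
    "facility_category",
    "visit_hours",
    "fiscal_year",
    "month",
    "prescribed",
    "antibiotic_classes",
)


@dataclass(frozen=True)
class LinkageWindow:
    """Maximum diagnosis-to-consultation gap, in days."""

    days: int = 30

    def __post_init__(self) -> None:
        if int(self.days) != self.days or self.days < 0:
            raise ValueError(f"linkage window must be a non-negative integer, got {self.days!r}")


@dataclass
class Cohort:
    """One row per non-bacterial ARTI consultation, plus the attrition report."""

    data: pd.DataFrame
    attrition: dict
    window: LinkageWindow = field(default_factory=LinkageWindow)
    # ARTI-stage consultations before the bacterial exclusion (dates only);
    # needed for the diagnosis-rate-per-ARTI-consultation regression.
    arti_consultations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame({"date": pd.Series(dtype="datetime64[ns]")})
    )

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.data.copy()
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
        df["active_codes"] = df["active_codes"].map(lambda s: ";".join(sorted(s)))
        df["antibiotic_classes"] = df["antibiotic_classes"].map(lambda s: ";".join(sorted(s)))
        df.to_csv(path, index=False)
        return path

    def write_attrition(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.attrition, indent=2, sort_keys=True) + "\n")
        return path


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})
    df["date"] = pd.Series(dtype="datetime64[ns]")
    df["prescribed"] = pd.Series(dtype=bool)
    return df


def link_active_diagnoses(
    consultations: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window: LinkageWindow | int = LinkageWindow(),
    match_facility: bool = False,
) -> pd.Series:
    """Active diagnosis-code set per consultation row.

    A diagnosis is active for a consultation when it belongs to the same
    patient (and, with ``match_facility``, the same facility) and its date
    lies in ``[consultation_date - window, consultation_date]`` inclusive.
    Returns a Series of frozensets aligned with ``consultations.index``.
    """
    if isinstance(window, int):
        window = LinkageWindow(window)
    sets = pd.Series([frozenset()] * len(consultations), index=consultations.index, dtype=object)
    if not len(consultations) or not len(diagnoses):
        return sets
    keys = ["patient_id", "facility_id"] if match_facility else ["patient_id"]
    cons = consultations[keys + ["date"]].reset_index(names="_cid")
    dx = diagnoses[keys + ["code", "diagnosis_date"]]
    merged = cons.merge(dx, on=keys, how="inner")
    delta = (merged["date"] - merged["diagnosis_date"]).dt.days
    merged = merged[(delta >= 0) & (delta <= window.days)]
    grouped = merged.groupby("_cid")["code"].agg(frozenset)
    sets.loc[grouped.index] = grouped
    return sets


def _class3(code: str) -> str:
    return str(code)[:3].upper()


def select_arti_consultations(
    consultations: pd.DataFrame, active_sets: pd.Series
) -> pd.DataFrame:
    """Keep consultations with at least one active ARTI-class code."""
    keep = active_sets.map(lambda s: any(_class3(c) in ARTI_CLASSES for c in s))
    out = consultations.loc[keep].copy()
    out["active_codes"] = active_sets.loc[keep]
    return out


def exclude_bacterial(
    arti_consultations: pd.DataFrame, table: AppropriatenessTable
) -> tuple[pd.DataFrame, dict]:
    """Drop consultations whose active set holds any antibiotic-requiring code."""
    def any_requiring(codes: frozenset) -> bool:
        return any(table.requires_antibiotics(c) for c in codes)

    requiring = arti_consultations["active_codes"].map(any_requiring)
    kept = arti_consultations.loc[~requiring].copy()
    report = {
        "before_exclusion": int(len(arti_consultations)),
        "excluded_bacterial": int(requiring.sum()),
        "after_exclusion": int(len(kept)),
    }
    return kept, report


def label_diagnosis_category(active_codes: Iterable[str]) -> str:
    """Collapse active ARTI codes to the Table-1 diagnosis category.

    Exactly one of the five listed single classes or five listed pairs gets
    its own label; every other non-empty combination is ``others``.
    """
    classes = frozenset(_class3(c) for c in active_codes if _class3(c) in ARTI_CLASSES)
    if not classes:
        raise ValueError("no ARTI code in active set; cannot label diagnosis category")
    if len(classes) == 1:
        (only,) = classes
        return only if only in _SINGLE_CATEGORIES else "others"
    if classes in _PAIR_CATEGORIES:
        return " & ".join(sorted(classes))
    return "others"


def link_prescriptions(
    nbarti: pd.DataFrame,
    prescriptions: pd.DataFrame,
    match_facility: bool = False,
) -> pd.DataFrame:
    """Attach the same-date J01 prescription outcome.

    ``prescribed`` is true when at least one J01 prescription exists for the
    same patient on the consultation date; ``antibiotic_classes`` is the set
    of class labels over all such prescriptions (a consultation still counts
    once in the overall numerator however many drugs were given).
    """
    out = nbarti.copy()
    if len(prescriptions):
        rx = prescriptions.loc[
            prescriptions["atc_code"].astype(str).str.upper().str.startswith("J01")
        ].copy()
    else:
        rx = prescriptions
    if not len(out) or not len(rx):
        out["antibiotic_classes"] = [frozenset()] * len(out)
        out["prescribed"] = False
        return out
    rx = rx.copy()
    rx["_class"] = rx["atc_code"].map(lambda c: classify_antibiotic(c).label)
    keys = ["patient_id", "facility_id", "date"] if match_facility else ["patient_id", "date"]
    classes = rx.groupby(keys)["_class"].agg(frozenset)
    idx = pd.MultiIndex.from_frame(out[keys])
    linked = classes.reindex(idx)
    out["antibiotic_classes"] = [
        v if isinstance(v, frozenset) else frozenset() for v in linked
    ]
    out["prescribed"] = out["antibiotic_classes"].map(bool)
    return out


def _attach_covariates(df: pd.DataFrame, bundle: cm.ClaimsBundle) -> pd.DataFrame:
    out = df.copy()
    patients = bundle.patients.set_index("patient_id")
    facilities = bundle.facilities.set_index("facility_id")
    out["sex"] = out["patient_id"].map(patients["sex"])
    out["insured_status"] = out["patient_id"].map(patients["insured_status"])
    birth = out["patient_id"].map(patients["birth_year_month"])
    out["age_group"] = [
        cm.derive_age_group(b, d) for b, d in zip(birth, out["date"])
    ]
    out["specialty"] = out["facility_id"].map(facilities["specialty"])
    fac_cat = {
        fid: cm.facility_category(row["bed_count"], row["is_university"], row["is_public"])
        for fid, row in facilities.iterrows()
    }
    out["facility_category"] = out["facility_id"].map(fac_cat)
    holidays = bundle.config.holidays
    out["visit_hours"] = [
        cm.classify_visit_hours(d, slot, holidays)
        for d, slot in zip(out["date"], out["visit_slot"])
    ]
    out["fiscal_year"] = out["date"].map(cm.fiscal_year)
    out["month"] = pd.to_datetime(out["date"]).dt.month
    return out


def build_cohort(
    bundle: cm.ClaimsBundle,
    table: AppropriatenessTable,
    window: LinkageWindow | int = LinkageWindow(),
    match_facility_prescriptions: bool = False,
    match_facility_diagnoses: bool = False,
) -> Cohort:
    """Run all five stages and return the cohort with an attrition report."""
    if isinstance(window, int):
        window = LinkageWindow(window)
    cons = bundle.consultations
    attrition: dict = {"consultations_in": int(len(cons))}
    active = link_active_diagnoses(
        cons, bundle.diagnoses, window, match_facility=match_facility_diagnoses
    )
    arti = select_arti_consultations(cons, active)
    attrition["arti_consultations"] = int(len(arti))
    arti_dates = arti[["date"]].reset_index(drop=True)
    nbarti, excl = exclude_bacterial(arti, table)
    attrition["excluded_bacterial"] = excl["excluded_bacterial"]
    attrition["nbarti_consultations"] = int(len(nbarti))
    if not len(nbarti):
        attrition["prescribed_consultations"] = 0
        return Cohort(_empty_frame(), attrition, window, arti_dates)
    nbarti = nbarti.copy()
    nbarti["diagnosis_category"] = nbarti["active_codes"].map(label_diagnosis_category)
    nbarti = link_prescriptions(
        nbarti, bundle.prescriptions, match_facility=match_facility_prescriptions
    )
    nbarti = _attach_covariates(nbarti, bundle)
    attrition["prescribed_consultations"] = int(nbarti["prescribed"].sum())
    data = nbarti[list(COHORT_COLUMNS)].reset_index(drop=True)
    return Cohort(data, attrition, window, arti_dates)
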