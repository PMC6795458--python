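from __future__ import annotations

import pandas as pd
import pytest

from nbarti.appropriateness import default_appropriateness_table
from nbarti.claims_model import ClaimsBundle, ReadConfig


def make_bundle(
    patients=(),
    facilities=(),
    consultations=(),
    diagnoses=(),
    prescriptions=(),
    config: ReadConfig | None = None,
) -> ClaimsBundle:
    """Assemble an in-memory bundle from row tuples (dates parsed)."""
    p = pd.DataFrame(
        list(patients), columns=["patient_id", "sex", "birth_year_month", "insured_status"]
    )
    f = pd.DataFrame(
        list(facilities),
        columns=["facility_id", "bed_count", "is_university", "is_public", "specialty"],
    )
    c = pd.DataFrame(
        list(consultations), columns=["patient_id", "facility_id", "date", "visit_slot"]
    )
    d = pd.DataFrame(
        list(diagnoses), columns=["patient_id", "facility_id", "code", "diagnosis_date"]
    )
    r = pd.DataFrame(
        list(prescriptions), columns=["patient_id", "facility_id", "date", "atc_code"]
    )
    for df, col in ((c, "date"), (d, "diagnosis_date"), (r, "date")):
        df[col] = pd.to_datetime(df[col])
    return ClaimsBundle(p, f, c, d, r, config=config or ReadConfig())


# Hand-traced toy fixture: 10 consultation rows (one duplicate), 9 after
# dedup, 7 with an active ARTI code at the default 30-day window, 1 excluded
# for a bacterial co-diagnosis (J150 five days before), 6 in the cohort, 3
# with a same-date J01 prescription.
TOY_PATIENTS = [
    ("P1", "male", "2010-05", "family_member"),
    ("P2", "female", "1999-07", "member"),
    ("P3", "male", "1950-01", "family_member"),
    ("P4", "female", "1980-03", "member"),
    ("P5", "male", "2012-12", "family_member"),
]
TOY_FACILITIES = [
    ("F1", 0, False, False, "internal_medicine"),
    ("F2", 19, False, False, "paediatrics"),
    ("F3", 400, True, False, "ENT"),
    ("F4", 100, False, True, "others"),
    ("F5", 30, False, False, "internal_medicine"),
]
TOY_CONSULTATIONS = [
    ("P1", "F1", "2013-04-10", "10:00"),  # J06, prescribed J01DD04
    ("P1", "F1", "2013-04-10", "10:00"),  # duplicate of the row above
    ("P2", "F2", "2013-05-05", "09:00"),  # Sunday; J20 15d prior; J159 34d prior (inactive)
    ("P3", "F3", "2015-06-15", "18:30"),  # J02 + bacterial J150 5d prior -> excluded
    ("P4", "F4", "2012-04-02", "08:00"),  # J00 30d prior (boundary); J18 31d prior (inactive)
    ("P5", "F5", "2013-01-15", "12:00"),  # I10 only -> not ARTI
    ("P2", "F1", "2014-11-03", "19:00"),  # J06 same day + J20 14d prior -> "J06 & J20"
    ("P3", "F5", "2016-02-10", "09:30"),  # J21 -> "others"
    ("P4", "F2", "2017-03-01", "14:00"),  # J03, prescribed J01AA02
    ("P1", "F2", "2016-12-26", "09:00"),  # no diagnosis in window -> dropped
]
TOY_DIAGNOSES = [
    ("P1", "F1", "J069", "2013-04-10"),
    ("P2", "F2", "J200", "2013-04-20"),
    ("P2", "F2", "J159", "2013-04-01"),
    ("P3", "F3", "J029", "2015-06-15"),
    ("P3", "F3", "J150", "2015-06-10"),
    ("P4", "F4", "J00", "2012-03-03"),
    ("P4", "F4", "J18", "2012-03-02"),
    ("P5", "F5", "I10", "2013-01-15"),
    ("P2", "F1", "J069", "2014-11-03"),
    ("P2", "F1", "J209", "2014-10-20"),
    ("P3", "F5", "J219", "2016-02-10"),
    ("P4", "F2", "J039", "2017-03-01"),
    ("P1", "F2", "J06", "2017-01-05"),
]
TOY_PRESCRIPTIONS = [
    ("P1", "F1", "2013-04-10", "J01DD04"),
    ("P4", "F4", "2012-04-02", "J01FA09"),
    ("P4", "F4", "2012-04-02", "J01CA04"),
    ("P2", "F1", "2014-11-04", "J01MA02"),  # one day late -> not linked
    ("P4", "F2", "2017-03-01", "J01AA02"),
    ("P4", "F2", "2017-03-01", "N02BE01"),  # not J01 -> ignored
]


@pytest.fixture
def toy_bundle() -> ClaimsBundle:
    """The deduplicated toy bundle (10 consultations)."""
    return make_bundle(
        TOY_PATIENTS,
        TOY_FACILITIES,
        TOY_CONSULTATIONS[:1] + TOY_CONSULTATIONS[2:],
        TOY_DIAGNOSES,
        TOY_PRESCRIPTIONS,
    )


@pytest.fixture
def default_table():
    return default_appropriateness_table()


def write_toy_csvs(directory, consultations=TOY_CONSULTATIONS) -> dict:
    """Write the toy fixture (including the duplicate row) as CSV files."""
    directory.mkdir(parents=True, exist_ok=True)
    frames = {
        "patients": pd.DataFrame(
            TOY_PATIENTS, columns=["patient_id", "sex", "birth_year_month", "insured_status"]
        ),
        "facilities": pd.DataFrame(
            TOY_FACILITIES,
            columns=["facility_id", "bed_count", "is_university", "is_public", "specialty"],
        ),
        "consultations": pd.DataFrame(
            consultations, columns=["patient_id", "facility_id", "date", "visit_slot"]
        ),
        "diagnoses": pd.DataFrame(
            TOY_DIAGNOSES, columns=["patient_id", "facility_id", "code", "diagnosis_date"]
        ),
        "prescriptions": pd.DataFrame(
            TOY_PRESCRIPTIONS, columns=["patient_id", "facility_id", "date", "atc_code"]
        ),
    }
    paths = {}
    for name, df in frames.items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
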