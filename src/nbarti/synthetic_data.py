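"""Synthetic claims bundles with known ground truth.

Every consultation is generated with covariates drawn independently from the
configured mixtures and a prescription outcome drawn from a logistic model
with known coefficients, so the exact odds ratios and the exact expected
monthly prescribing-rate curve are derivable from the configuration alone
(:func:`ground_truth`, by enumeration over the finite covariate grid).  The
five claims tables are then synthesised to be consistent with those draws:
patient birth months reproduce the drawn age bin through the pipeline's own
age derivation, visit dates/times reproduce the drawn in/out-of-hours label,
and diagnosis rows reproduce the drawn diagnosis category.

Same-patient visits are kept far enough apart (``min_visit_gap_days``) that
diagnosis rows never leak across one visit's linkage window into another,
which keeps the generated per-visit truth exact under the default window.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .appropriateness import ANTIBIOTIC_CLASSES
from .claims_model import (
    AGE_BINS,
    AGE_GROUP_LABELS,
    ClaimsBundle,
    FACILITY_CATEGORIES,
    ReadConfig,
    SPECIALTIES,
)
from .cohort_builder import DIAGNOSIS_CATEGORIES

__all__ = [
    "PrescribingModel",
    "SimConfig",
    "GroundTruth",
    "Simulation",
    "generate_bundle",
    "simulate",
    "simulate_cohort",
    "ground_truth",
]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# diagnosis category -> candidate code tuples (one tuple is drawn per visit)
_CATEGORY_CODES: dict[str, tuple[tuple[str, ...], ...]] = {
    "J20": (("J200",), ("J209",)),
    "J06": (("J069",), ("J060",)),
    "J02": (("J029",),),
    "J00": (("J00",),),
    "J03": (("J039",),),
    "J06 & J20": (("J069", "J209"),),
    "J02 & J20": (("J029", "J200"),),
    "J02 & J06": (("J029", "J069"),),
    "J00 & J20": (("J00", "J209"),),
    "J00 & J06": (("J00", "J069"),),
    "others": (("J219",), ("J22",), ("J00", "J029", "J209")),
}

_BACTERIAL_CODES = ("J159", "J13", "J189")
_DECOY_CODE = "J45"  # out-of-window filler; never active at any visit

_CLASS_ATC: dict[str, tuple[str, ...]] = {
    "third_gen_cephalosporin": ("J01DD04", "J01DD08"),
    "macrolide": ("J01FA09", "J01FA10"),
    "fluoroquinolone": ("J01MA02", "J01MA12"),
    "penicillin": ("J01CA04", "J01CR02"),
    "other_J01": ("J01AA02", "J01EE01"),
}

_YOUNG_BINS = ("0-3", "4-6", "7-12")


@dataclass(frozen=True)
class PrescribingModel:
    """Logistic model for the prescribed flag.

    ``coefs`` maps factor name -> {level: log-odds coefficient}; levels not
    listed (including reference levels) have coefficient 0.  ``month`` and
    ``fiscal_year`` factors are keyed by integers.  ``trend_per_month`` adds
    a linear secular term on the study month index.
    """

    intercept: float = _logit(0.3)
    coefs: dict = field(default_factory=dict)
    trend_per_month: float = 0.0

    def coef(self, factor: str, level) -> float:
        return float(self.coefs.get(factor, {}).get(level, 0.0))


def _norm(weights: dict, levels: tuple, what: str) -> np.ndarray:
    w = np.array([float(weights.get(lv, 0.0)) for lv in levels], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError(f"{what}: weights must be non-negative and normalisable")
    return w / w.sum()


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are stylised to echo the marginal
    structure of a large outpatient claims cohort (not a reproduction)."""

    n_patients: int = 2000
    n_facilities: int = 40
    study_start: str = "2012-04"
    study_months: int = 63
    consultation_rate: float = 2.0  # mean ARTI visits per patient per year
    age_distribution: dict = field(default_factory=lambda: {
        "0-3": 28.9, "4-6": 13.2, "7-12": 11.5, "13-18": 5.6, "19-29": 7.6,
        "30-39": 11.1, "40-49": 10.5, "50-59": 7.5, "60-": 4.2,
    })
    p_male: float = 0.522
    p_member: float = 0.269
    facility_mix: dict = field(default_factory=lambda: {
        "clinic_without_beds": 88.3, "clinic_with_beds": 2.1,
        "other_hospital": 7.3, "university_hospital": 0.4, "public_hospital": 1.8,
    })
    specialty_mix: dict = field(default_factory=lambda: {
        "internal_medicine": 53.2, "paediatrics": 30.2, "ENT": 9.6, "others": 7.1,
    })
    p_out_of_hours: float = 0.10
    seasonality: tuple = (1.3, 1.2, 1.1, 0.9, 0.8, 0.8, 0.8, 0.7, 0.9, 1.0, 1.1, 1.3)
    diagnosis_category_weights: dict = field(default_factory=lambda: {
        "J20": 30.0, "J06": 29.0, "J02": 14.1, "J00": 6.0, "J06 & J20": 4.9,
        "J02 & J20": 3.4, "J03": 2.8, "J02 & J06": 1.8, "J00 & J20": 1.3,
        "J00 & J06": 1.2, "others": 5.8,
    })
    p_bacterial_codiagnosis: float = 0.05
    p_decoy_diagnosis: float = 0.10
    prescribing_model: PrescribingModel = field(default_factory=PrescribingModel)
    class_mix: dict = field(default_factory=lambda: {
        "third_gen_cephalosporin": 40.1, "macrolide": 34.1,
        "fluoroquinolone": 14.4, "penicillin": 5.0, "other_J01": 6.4,
    })
    p_second_class: float = 0.05
    age_specialty_confounding: float = 0.0
    min_visit_gap_days: int = 77  # > 2 * default window + decoy lag
    visit_slot_dialect: str = "clock"
    seed: int = 0

    def __post_init__(self) -> None:
        for p, name in (
            (self.p_male, "p_male"), (self.p_member, "p_member"),
            (self.p_out_of_hours, "p_out_of_hours"),
            (self.p_bacterial_codiagnosis, "p_bacterial_codiagnosis"),
            (self.p_decoy_diagnosis, "p_decoy_diagnosis"),
            (self.p_second_class, "p_second_class"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.study_months < 1 or self.n_patients < 1:
            raise ValueError("study_months and n_patients must be positive")
        if len(self.seasonality) != 12 or any(s < 0 for s in self.seasonality):
            raise ValueError("seasonality needs 12 non-negative multipliers")
        # trigger weight validation early
        self._mixtures()

    def _mixtures(self) -> dict[str, np.ndarray]:
        return {
            "age_group": _norm(self.age_distribution, AGE_GROUP_LABELS, "age_distribution"),
            "facility_category": _norm(self.facility_mix, FACILITY_CATEGORIES, "facility_mix"),
            "specialty": _norm(self.specialty_mix, SPECIALTIES, "specialty_mix"),
            "diagnosis_category": _norm(
                self.diagnosis_category_weights, DIAGNOSIS_CATEGORIES, "diagnosis_category_weights"
            ),
            "antibiotic_class": _norm(self.class_mix, ANTIBIOTIC_CLASSES, "class_mix"),
        }

    def specialty_probs_by_age(self) -> np.ndarray:
        """(n_age_bins, n_specialties) conditional mixture; the confounding
        toggle boosts paediatrics for young bins to make crude and adjusted
        ORs diverge."""
        base = self._mixtures()["specialty"]
        mat = np.tile(base, (len(AGE_GROUP_LABELS), 1))
        c = float(self.age_specialty_confounding)
        if c:
            j = SPECIALTIES.index("paediatrics")
            for i, label in enumerate(AGE_GROUP_LABELS):
                if label in _YOUNG_BINS:
                    mat[i, j] *= 1.0 + c
            mat = mat / mat.sum(axis=1, keepdims=True)
        return mat

    @property
    def n_visits(self) -> int:
        return max(1, round(self.n_patients * self.consultation_rate * self.study_months / 12.0))

    def month_probs(self) -> np.ndarray:
        start = pd.Period(self.study_start, freq="M")
        mult = np.array(
            [self.seasonality[(start + t).month - 1] for t in range(self.study_months)],
            dtype=float,
        )
        if mult.sum() <= 0:
            raise ValueError("seasonality multipliers sum to zero over the study window")
        return mult / mult.sum()

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        pm = raw.get("prescribing_model")
        if isinstance(pm, dict):
            raw["prescribing_model"] = PrescribingModel(
                intercept=float(pm.get("intercept", PrescribingModel().intercept)),
                coefs={k: dict(v) for k, v in (pm.get("coefs") or {}).items()},
                trend_per_month=float(pm.get("trend_per_month", 0.0)),
            )
        if "seasonality" in raw:
            raw["seasonality"] = tuple(raw["seasonality"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


@dataclass
class GroundTruth:
    """Exact quantities implied by a :class:`SimConfig`."""

    or_by_level: dict        # (factor, level) -> true OR
    monthly_rate: np.ndarray  # per 100 consultations, one entry per study month
    month_labels: list
    expected_cohort_size: float
    trend_per_month: float


@dataclass
class Simulation:
    bundle: ClaimsBundle
    visits: pd.DataFrame  # per-visit truth (covariates, outcome, flags)
    config: SimConfig


def _draw_visits(config: SimConfig, rng: np.random.Generator, n: int | None = None) -> pd.DataFrame:
    """Draw per-visit month index, covariates and the prescribed outcome."""
    mix = config._mixtures()
    n = config.n_visits if n is None else int(n)
    start = pd.Period(config.study_start, freq="M")
    t = rng.choice(config.study_months, size=n, p=config.month_probs())

    sex_i = rng.random(n) >= config.p_male  # False -> male
    insured_i = rng.random(n) >= config.p_member  # False -> member
    age_i = rng.choice(len(AGE_GROUP_LABELS), size=n, p=mix["age_group"])
    spec_cum = np.cumsum(config.specialty_probs_by_age(), axis=1)
    spec_i = (rng.random(n)[:, None] > spec_cum[age_i]).sum(axis=1)
    fac_i = rng.choice(len(FACILITY_CATEGORIES), size=n, p=mix["facility_category"])
    out_i = rng.random(n) < config.p_out_of_hours
    dx_i = rng.choice(len(DIAGNOSIS_CATEGORIES), size=n, p=mix["diagnosis_category"])

    months = np.array([(start + int(ti)).month for ti in range(config.study_months)])
    month_of_t = months[t]
    fy_of_t = np.array(
        [(start + int(ti)).year if (start + int(ti)).month >= 4 else (start + int(ti)).year - 1
         for ti in range(config.study_months)]
    )[t]

    model = config.prescribing_model
    def vec(factor: str, levels, idx) -> np.ndarray:
        coefs = np.array([model.coef(factor, lv) for lv in levels])
        return coefs[idx]

    logit = np.full(n, model.intercept, dtype=float)
    logit += vec("sex", ("male", "female"), sex_i.astype(int))
    logit += vec("insured_status", ("member", "family_member"), insured_i.astype(int))
    logit += vec("age_group", AGE_GROUP_LABELS, age_i)
    logit += vec("specialty", SPECIALTIES, spec_i)
    logit += vec("facility_category", FACILITY_CATEGORIES, fac_i)
    logit += vec("visit_hours", ("in_hours", "out_of_hours"), out_i.astype(int))
    logit += vec("diagnosis_category", DIAGNOSIS_CATEGORIES, dx_i)
    logit += vec("month", tuple(range(1, 13)), month_of_t - 1)
    fy_levels = sorted(set(fy_of_t))
    logit += vec("fiscal_year", tuple(fy_levels), np.searchsorted(fy_levels, fy_of_t))
    logit += model.trend_per_month * t

    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-logit))
    prescribed = rng.random(n) < p

    class_1 = rng.choice(len(ANTIBIOTIC_CLASSES), size=n, p=mix["antibiotic_class"])
    class_2 = rng.choice(len(ANTIBIOTIC_CLASSES), size=n, p=mix["antibiotic_class"])
    has_second = (rng.random(n) < config.p_second_class) & (class_2 != class_1)

    return pd.DataFrame(
        {
            "t": t,
            "month": month_of_t,
            "fiscal_year": fy_of_t,
            "sex": np.where(sex_i, "female", "male"),
            "insured_status": np.where(insured_i, "family_member", "member"),
            "age_group": np.array(AGE_GROUP_LABELS, dtype=object)[age_i],
            "specialty": np.array(SPECIALTIES, dtype=object)[spec_i],
            "facility_category": np.array(FACILITY_CATEGORIES, dtype=object)[fac_i],
            "visit_hours": np.where(out_i, "out_of_hours", "in_hours"),
            "diagnosis_category": np.array(DIAGNOSIS_CATEGORIES, dtype=object)[dx_i],
            "bacterial_codiagnosis": rng.random(n) < config.p_bacterial_codiagnosis,
            "decoy_diagnosis": rng.random(n) < config.p_decoy_diagnosis,
            "prescribed": prescribed,
            "class_1": np.array(ANTIBIOTIC_CLASSES, dtype=object)[class_1],
            "class_2": np.where(
                has_second, np.array(ANTIBIOTIC_CLASSES, dtype=object)[class_2], None
            ),
        }
    )


def simulate_cohort(config: SimConfig, n: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Fast path: an analysis-ready cohort frame drawn straight from the
    generative model, skipping the claims-table round trip.  Used for
    repeated-fit studies (e.g. confidence-interval coverage)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    visits = _draw_visits(config, rng, n=n)
    df = visits.drop(columns=["bacterial_codiagnosis", "decoy_diagnosis", "class_1", "class_2"])
    start = pd.Period(config.study_start, freq="M")
    df["date"] = pd.PeriodIndex([start + int(t) for t in df["t"]], freq="M").to_timestamp()
    return df


# --- date/time synthesis -------------------------------------------------

_MONTH_DAY_CACHE: dict[tuple[int, int], tuple[list[int], list[int]]] = {}


def _month_days(period: pd.Period) -> tuple[list[int], list[int]]:
    """(weekday day-numbers, weekend day-numbers) for a calendar month."""
    key = (period.year, period.month)
    if key not in _MONTH_DAY_CACHE:
        ndays = calendar.monthrange(period.year, period.month)[1]
        weekdays, weekends = [], []
        for day in range(1, ndays + 1):
            (weekends if dt.date(period.year, period.month, day).weekday() >= 5 else weekdays).append(day)
        _MONTH_DAY_CACHE[key] = (weekdays, weekends)
    return _MONTH_DAY_CACHE[key]


def _draw_datetime(period: pd.Period, out_of_hours: bool, rng: np.random.Generator) -> tuple[dt.date, str]:
    weekdays, weekends = _month_days(period)
    minute = int(rng.integers(0, 60))
    if not out_of_hours:
        day = int(rng.choice(weekdays))
        hour = int(rng.integers(8, 18))
    else:
        n_we, n_wd = len(weekends), len(weekdays)
        if rng.random() < n_we / (n_we + n_wd):
            day = int(rng.choice(weekends))
            hour = int(rng.integers(0, 24))
        else:
            day = int(rng.choice(weekdays))
            hour = int(rng.choice([*range(0, 8), *range(18, 24)]))
    return dt.date(period.year, period.month, day), f"{hour:02d}:{minute:02d}"


# --- patient assignment --------------------------------------------------

def _assign_patients(
    visits: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Group visits into patients consistent with fixed demographics.

    Visits sharing (sex, insured status, age bin) are chunked into patients;
    a chunk is split whenever the date gap falls below ``min_visit_gap_days``
    or no single birth month can reproduce the bin at every visit date.
    Returns the patients table; adds ``patient_id`` to ``visits`` in place.
    """
    bins = {label: (lo, hi) for lo, hi, label in AGE_BINS}
    mean_visits = max(1.0, config.consultation_rate * config.study_months / 12.0)
    patient_rows = []
    day_num = visits["date"].to_numpy("datetime64[D]").astype(int)
    order = np.argsort(day_num, kind="stable")
    c_idx = (visits["date"].dt.year * 12 + visits["date"].dt.month - 1).to_numpy()
    sexes = visits["sex"].to_numpy()
    insured = visits["insured_status"].to_numpy()
    ages = visits["age_group"].to_numpy()
    pids = np.empty(len(visits), dtype=object)
    open_state: dict[tuple, dict] = {}
    counter = 0

    def close(state) -> None:
        lo_b, hi_b = state["b_interval"]
        b_idx = (lo_b + hi_b) // 2
        patient_rows.append(
            {
                "patient_id": state["pid"],
                "sex": state["sex"],
                "birth_year_month": f"{b_idx // 12:04d}-{b_idx % 12 + 1:02d}",
                "insured_status": state["insured"],
            }
        )

    for i in order:
        key = (sexes[i], insured[i], ages[i])
        lo, hi = bins[ages[i]]
        b_lo, b_hi = c_idx[i] - 12 * hi - 11, c_idx[i] - 12 * lo
        state = open_state.get(key)
        ok = False
        if state is not None and state["n"] < state["target"]:
            gap = day_num[i] - state["last_day"]
            ilo = max(state["b_interval"][0], b_lo)
            ihi = min(state["b_interval"][1], b_hi)
            if gap >= config.min_visit_gap_days and ilo <= ihi:
                state["b_interval"] = (ilo, ihi)
                state["last_day"] = day_num[i]
                state["n"] += 1
                ok = True
        if not ok:
            if state is not None:
                close(state)
            counter += 1
            state = {
                "pid": f"P{counter:07d}",
                "sex": sexes[i],
                "insured": insured[i],
                "b_interval": (b_lo, b_hi),
                "last_day": day_num[i],
                "n": 1,
                "target": 1 + rng.poisson(mean_visits - 1.0),
            }
            open_state[key] = state
        pids[i] = state["pid"]
    for state in open_state.values():
        close(state)
    visits["patient_id"] = pids
    return pd.DataFrame(patient_rows)


def _make_facilities(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Facility table plus (category, specialty) -> facility-id list index."""
    mix = config._mixtures()
    rows, cells = [], {}
    counter = 0
    for ci, cat in enumerate(FACILITY_CATEGORIES):
        for si, spec in enumerate(SPECIALTIES):
            w = mix["facility_category"][ci] * mix["specialty"][si]
            if w <= 0:
                continue
            n_cell = max(1, round(config.n_facilities * w))
            ids = []
            for _ in range(n_cell):
                counter += 1
                fid = f"F{counter:05d}"
                if cat == "clinic_without_beds":
                    beds = 0
                elif cat == "clinic_with_beds":
                    beds = int(rng.integers(1, 20))
                else:
                    beds = int(rng.integers(20, 800))
                rows.append(
                    {
                        "facility_id": fid,
                        "bed_count": beds,
                        "is_university": cat == "university_hospital",
                        "is_public": cat == "public_hospital",
                        "specialty": spec,
                    }
                )
                ids.append(fid)
            cells[(cat, spec)] = ids
    return pd.DataFrame(rows), cells


def simulate(config: SimConfig) -> Simulation:
    """Generate the five claims tables plus the per-visit truth frame."""
    rng = np.random.default_rng(config.seed)
    visits = _draw_visits(config, rng)
    start = pd.Period(config.study_start, freq="M")

    dates, slots = [], []
    for t, out in zip(visits["t"], visits["visit_hours"] == "out_of_hours"):
        d, clock = _draw_datetime(start + int(t), bool(out), rng)
        dates.append(d)
        slots.append(clock if config.visit_slot_dialect == "clock" else
                     ("out_of_hours" if out else "in_hours"))
    visits["date"] = pd.to_datetime(dates)
    visits["visit_slot"] = slots

    facilities, cells = _make_facilities(config, rng)
    visits["facility_id"] = [
        cells[(cat, spec)][int(rng.integers(0, len(cells[(cat, spec)])))]
        for cat, spec in zip(visits["facility_category"], visits["specialty"])
    ]
    patients = _assign_patients(visits, config, rng)

    dx_rows = []
    for v in visits.itertuples(index=False):
        options = _CATEGORY_CODES[v.diagnosis_category]
        codes = options[int(rng.integers(0, len(options)))]
        for code in codes:
            dx_rows.append((v.patient_id, v.facility_id, code, v.date))
        if v.bacterial_codiagnosis:
            code = _BACTERIAL_CODES[int(rng.integers(0, len(_BACTERIAL_CODES)))]
            dx_rows.append((v.patient_id, v.facility_id, code, v.date))
        if v.decoy_diagnosis:
            lag = 31 + int(rng.integers(0, 15))
            dx_rows.append(
                (v.patient_id, v.facility_id, _DECOY_CODE, v.date - pd.Timedelta(days=lag))
            )
    diagnoses = pd.DataFrame(
        dx_rows, columns=["patient_id", "facility_id", "code", "diagnosis_date"]
    )

    rx_rows = []
    for v in visits.itertuples(index=False):
        if not v.prescribed:
            continue
        for cls in filter(None, (v.class_1, v.class_2)):
            atcs = _CLASS_ATC[cls]
            rx_rows.append(
                (v.patient_id, v.facility_id, v.date, atcs[int(rng.integers(0, len(atcs)))])
            )
    prescriptions = pd.DataFrame(
        rx_rows, columns=["patient_id", "facility_id", "date", "atc_code"]
    )

    consultations = visits[["patient_id", "facility_id", "date", "visit_slot"]].copy()
    bundle = ClaimsBundle(
        patients=patients.reset_index(drop=True),
        facilities=facilities,
        consultations=consultations.reset_index(drop=True),
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        config=ReadConfig(visit_slot_dialect=config.visit_slot_dialect),
    )
    return Simulation(bundle=bundle, visits=visits, config=config)


def generate_bundle(config: SimConfig) -> ClaimsBundle:
    """The five claims tables for a configuration (see :func:`simulate`)."""
    return simulate(config).bundle


def ground_truth(config: SimConfig) -> GroundTruth:
    """Exact ORs and expected monthly rate curve by grid enumeration."""
    mix = config._mixtures()
    model = config.prescribing_model
    start = pd.Period(config.study_start, freq="M")

    ors: dict = {}
    factor_levels = {
        "sex": ("male", "female"),
        "insured_status": ("member", "family_member"),
        "age_group": AGE_GROUP_LABELS,
        "specialty": SPECIALTIES,
        "facility_category": FACILITY_CATEGORIES,
        "visit_hours": ("in_hours", "out_of_hours"),
        "diagnosis_category": DIAGNOSIS_CATEGORIES,
        "month": tuple(range(1, 13)),
    }
    fy_levels = sorted(
        {(start + t).year if (start + t).month >= 4 else (start + t).year - 1
         for t in range(config.study_months)}
    )
    factor_levels["fiscal_year"] = tuple(fy_levels)
    for factor, levels in factor_levels.items():
        for lv in levels:
            ors[(factor, lv)] = float(np.exp(model.coef(factor, lv)))

    # joint (age, specialty) factor carries the confounding, if any
    spec_mat = config.specialty_probs_by_age()
    age_w = mix["age_group"]
    joint_w = (age_w[:, None] * spec_mat).ravel()
    joint_c = (
        np.array([model.coef("age_group", lv) for lv in AGE_GROUP_LABELS])[:, None]
        + np.array([model.coef("specialty", lv) for lv in SPECIALTIES])[None, :]
    ).ravel()

    factors = [
        (np.array([config.p_male, 1 - config.p_male]),
         np.array([model.coef("sex", "male"), model.coef("sex", "female")])),
        (np.array([config.p_member, 1 - config.p_member]),
         np.array([model.coef("insured_status", "member"),
                   model.coef("insured_status", "family_member")])),
        (np.array([1 - config.p_out_of_hours, config.p_out_of_hours]),
         np.array([model.coef("visit_hours", "in_hours"),
                   model.coef("visit_hours", "out_of_hours")])),
        (mix["facility_category"],
         np.array([model.coef("facility_category", lv) for lv in FACILITY_CATEGORIES])),
        (mix["diagnosis_category"],
         np.array([model.coef("diagnosis_category", lv) for lv in DIAGNOSIS_CATEGORIES])),
        (joint_w, joint_c),
    ]
    logit = np.array(model.intercept, dtype=float)
    weight = np.array(1.0)
    for w, c in factors:
        logit = logit[..., None] + c
        weight = weight[..., None] * w
    logit = logit.ravel()
    weight = weight.ravel()

    rates = np.empty(config.study_months)
    labels = []
    for t in range(config.study_months):
        period = start + t
        labels.append(str(period))
        fy = period.year if period.month >= 4 else period.year - 1
        shift = (
            model.trend_per_month * t
            + model.coef("month", period.month)
            + model.coef("fiscal_year", fy)
        )
        rates[t] = 100.0 * float(np.sum(weight / (1.0 + np.exp(-(logit + shift)))))

    expected_cohort = config.n_visits * (1.0 - config.p_bacterial_codiagnosis)
    return GroundTruth(
        or_by_level=ors,
        monthly_rate=rates,
        month_labels=labels,
        expected_cohort_size=expected_cohort,
        trend_per_month=model.trend_per_month,
    )
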