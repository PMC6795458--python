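"""Monthly prescribing rates, composition tables, trend fits, and the
linkage-window sensitivity sweep.

Rates are per 100 non-bacterial ARTI consultations per calendar month:
numerator = consultations with at least one same-date J01 prescription,
denominator = all cohort consultations that month.  Trend fits are ordinary
least squares of the rate on the month index.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .appropriateness import ANTIBIOTIC_CLASSES, AppropriatenessTable
from .cohort_builder import Cohort, DIAGNOSIS_CATEGORIES, LinkageWindow, build_cohort
from .claims_model import AGE_GROUP_LABELS, ClaimsBundle, SPECIALTIES

logger = logging.getLogger(__name__)

__all__ = [
    "MonthlyRateSeries",
    "TrendFit",
    "CompositionTable",
    "round_half_away",
    "month_label",
    "monthly_rate",
    "composition_table",
    "fit_trend",
    "rate_vs_diagnosisrate_regression",
    "relative_change",
    "window_sensitivity",
]

STRATIFIERS = {
    "age_group": list(AGE_GROUP_LABELS),
    "diagnosis_category": list(DIAGNOSIS_CATEGORIES),
    "specialty": list(SPECIALTIES),
    "antibiotic_class": list(ANTIBIOTIC_CLASSES),
}


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (presentation convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _month_index(dates: pd.Series, origin: str | None) -> tuple[pd.Series, pd.Period]:
    periods = pd.PeriodIndex(pd.to_datetime(dates), freq="M")
    origin_p = pd.Period(origin, freq="M") if origin else periods.min()
    return pd.Series((periods - origin_p).map(lambda o: o.n), index=dates.index), origin_p


def month_label(origin: pd.Period | str, t: int) -> str:
    return str(pd.Period(origin, freq="M") + int(t))


@dataclass
class MonthlyRateSeries:
    """Per-month numerator/denominator/rate, optionally for one stratum.

    ``frame`` columns: month_index, month_label, numerator, denominator,
    rate (NaN and flagged undefined when the denominator is zero).
    """

    frame: pd.DataFrame
    stratum_dim: str | None = None
    stratum: str | None = None
    origin: str | None = None

    def defined(self) -> pd.DataFrame:
        return self.frame[self.frame["denominator"] > 0]

    def rate_at(self, month_index: int) -> float:
        row = self.frame[self.frame["month_index"] == month_index]
        if not len(row) or row["denominator"].iloc[0] == 0:
            raise ValueError(f"rate undefined at month_index {month_index}")
        return float(row["rate"].iloc[0])

    @property
    def mean_of_monthly(self) -> float:
        return float(self.defined()["rate"].mean())

    @property
    def pooled(self) -> float:
        d = self.frame["denominator"].sum()
        return float(100.0 * self.frame["numerator"].sum() / d) if d else float("nan")


@dataclass
class TrendFit:
    """OLS fit of a monthly rate on the month index."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n_points: int
    stratum: str | None = None

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "stratum": self.stratum,
        }


@dataclass
class CompositionTable:
    """Counts and percentages by category, in labelled blocks."""

    frame: pd.DataFrame  # columns: block, level, count, percent
    total: int

    @classmethod
    def from_counts(
        cls, counts: dict[str, dict[str, int]], total: int | None = None
    ) -> "CompositionTable":
        """Build from precomputed per-block count mappings.

        Percentages are 100*count/total rounded to one decimal, half away
        from zero.  ``total`` defaults to the sum of the first block.
        """
        if total is None:
            total = sum(next(iter(counts.values())).values())
        rows = [
            {
                "block": block,
                "level": level,
                "count": int(n),
                "percent": round_half_away(100.0 * n / total, 1),
            }
            for block, block_counts in counts.items()
            for level, n in block_counts.items()
        ]
        return cls(pd.DataFrame(rows), int(total))

    def percent(self, block: str, level: str) -> float:
        sel = self.frame[(self.frame["block"] == block) & (self.frame["level"] == level)]
        if not len(sel):
            raise KeyError((block, level))
        return float(sel["percent"].iloc[0])


def _series_from_counts(
    num: pd.Series, den: pd.Series, months: range, origin, stratum_dim=None, stratum=None
) -> MonthlyRateSeries:
    idx = list(months)
    n = num.reindex(idx, fill_value=0).astype(int)
    d = den.reindex(idx, fill_value=0).astype(int)
    rate = np.where(d > 0, 100.0 * n / np.where(d > 0, d, 1), np.nan)
    frame = pd.DataFrame(
        {
            "month_index": idx,
            "month_label": [month_label(origin, t) for t in idx],
            "numerator": n.to_numpy(),
            "denominator": d.to_numpy(),
            "rate": rate,
        }
    )
    return MonthlyRateSeries(frame, stratum_dim, stratum, str(origin))


def monthly_rate(
    cohort: Cohort | pd.DataFrame,
    stratify_by: str | None = None,
    origin: str | None = None,
) -> list[MonthlyRateSeries]:
    """Monthly prescribing rate series, overall or one series per stratum.

    For the ``antibiotic_class`` stratifier a consultation contributes to the
    numerator of every distinct class prescribed that day but only once to
    the overall numerator; the denominator is always the full cohort month
    count.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    if not len(df):
        raise ValueError("cohort is empty; no month with data")
    if stratify_by is not None and stratify_by not in STRATIFIERS:
        raise KeyError(
            f"unknown stratifier {stratify_by!r}; expected one of {sorted(STRATIFIERS)}"
        )
    t, origin_p = _month_index(df["date"], origin)
    months = range(int(t.min()), int(t.max()) + 1)
    den_all = df.groupby(t).size()
    if stratify_by is None:
        num = df.loc[df["prescribed"]].groupby(t[df["prescribed"]]).size()
        return [_series_from_counts(num, den_all, months, origin_p)]
    out = []
    if stratify_by == "antibiotic_class":
        exploded = df.loc[df["prescribed"], ["antibiotic_classes"]].copy()
        exploded["_t"] = t[df["prescribed"]]
        exploded["antibiotic_classes"] = exploded["antibiotic_classes"].map(sorted)
        exploded = exploded.explode("antibiotic_classes")
        for level in STRATIFIERS[stratify_by]:
            num = (
                exploded[exploded["antibiotic_classes"] == level].groupby("_t").size()
            )
            out.append(
                _series_from_counts(num, den_all, months, origin_p, stratify_by, level)
            )
        return out
    for level in STRATIFIERS[stratify_by]:
        sub = df[stratify_by] == level
        den = df.loc[sub].groupby(t[sub]).size()
        pres = sub & df["prescribed"]
        num = df.loc[pres].groupby(t[pres]).size()
        out.append(_series_from_counts(num, den, months, origin_p, stratify_by, level))
    return out


_COMPOSITION_BLOCKS = (
    "sex",
    "age_group",
    "insured_status",
    "specialty",
    "facility_category",
    "diagnosis_category",
    "fiscal_year",
)


def composition_table(cohort: Cohort | pd.DataFrame) -> CompositionTable:
    """Cohort composition by sex, age group, insurance, specialty, facility
    category, diagnosis category and fiscal year (counts and one-decimal
    percentages of the cohort total)."""
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    counts = {
        block: df.groupby(block, observed=True).size().to_dict()
        for block in _COMPOSITION_BLOCKS
    }
    return CompositionTable.from_counts(counts, total=len(df))


def fit_trend(series: MonthlyRateSeries) -> TrendFit:
    """OLS of rate on month index over the defined months.

    Requires at least three defined points with non-constant month index.  A
    zero-variance response yields slope 0 with R-squared reported as 0 and a
    warning.
    """
    defined = series.defined()
    y = defined["rate"].to_numpy(dtype=float)
    t = defined["month_index"].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError(f"need >= 3 defined monthly rates, got {len(y)}")
    if np.ptp(t) == 0:
        raise ValueError("zero variance in month index")
    if np.ptp(y) == 0:
        logger.warning("constant rate series: slope 0, R-squared reported as 0")
        return TrendFit(0.0, float(y[0]), 1.0, 0.0, len(y), series.stratum)
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        n_points=len(y),
        stratum=series.stratum,
    )


def rate_vs_diagnosisrate_regression(
    cohort: Cohort, origin: str | None = None
) -> TrendFit:
    """OLS of the monthly prescribing rate (per 100 NB-ARTI consultations) on
    the monthly NB-ARTI diagnosis rate (per 100 ARTI consultations).

    Used to check whether a declining prescribing rate merely tracks a
    decline in non-bacterial diagnoses.
    """
    arti = cohort.arti_consultations
    if not len(arti):
        raise ValueError("no ARTI-stage consultations available")
    (overall,) = monthly_rate(cohort, origin=origin)
    t_arti, origin_p = _month_index(
        arti["date"], origin or overall.origin
    )
    arti_counts = arti.groupby(t_arti).size()
    frame = overall.frame.set_index("month_index")
    common = frame.index.intersection(arti_counts.index)
    common = [
        t
        for t in common
        if frame.loc[t, "denominator"] > 0 and arti_counts.loc[t] > 0
    ]
    if len(common) < 3:
        raise ValueError(f"need >= 3 common defined months, got {len(common)}")
    y = frame.loc[common, "rate"].to_numpy(dtype=float)
    x = 100.0 * frame.loc[common, "denominator"].to_numpy(dtype=float) / arti_counts.loc[
        common
    ].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("diagnosis-rate predictor is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        r2 = float(res.rsquared) if np.ptp(y) > 0 else 0.0
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]) if np.ptp(y) > 0 else 1.0,
        r_squared=r2,
        n_points=len(common),
        stratum="prescribing_rate_vs_diagnosis_rate",
    )


def relative_change(
    series: MonthlyRateSeries, from_month: int, to_month: int
) -> float:
    """Percent change 100*(rate_to - rate_from)/rate_from, to one decimal."""
    r_from = series.rate_at(from_month)
    r_to = series.rate_at(to_month)
    if r_from == 0:
        raise ZeroDivisionError("rate at from_month is zero; relative change undefined")
    return round_half_away(100.0 * (r_to - r_from) / r_from, 1)


def window_sensitivity(
    bundle: ClaimsBundle,
    table: AppropriatenessTable,
    windows: list[int],
    origin: str | None = None,
) -> pd.DataFrame:
    """Rebuild the cohort per linkage window; report counts and mean rates.

    Columns: window_days, arti_consultations, excluded_bacterial,
    nbarti_consultations, mean_of_monthly_rate, pooled_rate.
    """
    if not windows:
        raise ValueError("need at least one window value")
    rows = []
    for w in windows:
        window = LinkageWindow(int(w))  # rejects negative values
        cohort = build_cohort(bundle, table, window)
        if len(cohort):
            (overall,) = monthly_rate(cohort, origin=origin)
            mean_rate, pooled = overall.mean_of_monthly, overall.pooled
        else:
            mean_rate = pooled = float("nan")
        rows.append(
            {
                "window_days": int(w),
                "arti_consultations": cohort.attrition["arti_consultations"],
                "excluded_bacterial": cohort.attrition["excluded_bacterial"],
                "nbarti_consultations": cohort.attrition["nbarti_consultations"],
                "mean_of_monthly_rate": mean_rate,
                "pooled_rate": pooled,
            }
        )
    return pd.DataFrame(rows)
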