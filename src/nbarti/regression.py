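"""Crude and adjusted logistic odds-ratio models for the prescribed flag.

Each covariate is categorical with a declared reference level; odds ratios
are exponentiated coefficients with Wald 95% confidence intervals
(estimate +/- 1.96 standard errors on the log scale).  The joint model takes
all factors at once (main effects only); the specialty-stratified yearly
model refits a reduced covariate set within each specialty stratum.

Fitting is maximum likelihood by iteratively reweighted least squares
(statsmodels GLM/Binomial; convergence at max 1e-8 coefficient change or
100 iterations).  Patients can contribute several consultations; no
clustering adjustment is applied — consultations are treated as
independent observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_builder import Cohort, DIAGNOSIS_CATEGORIES
from .claims_model import AGE_GROUP_LABELS, FACILITY_CATEGORIES, SPECIALTIES

logger = logging.getLogger(__name__)

__all__ = [
    "ORRow",
    "ORTable",
    "ModelSpec",
    "PerfectSeparationError",
    "RankDeficiencyError",
    "fit_crude",
    "fit_adjusted",
    "or_table",
    "stratified_yearly_aor",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class PerfectSeparationError(ValueError):
    """A factor level perfectly predicts the outcome."""


class RankDeficiencyError(ValueError):
    """The reference-coded design matrix is not full rank."""


DEFAULT_LEVELS: dict[str, list] = {
    "sex": ["male", "female"],
    "age_group": list(AGE_GROUP_LABELS),
    "insured_status": ["member", "family_member"],
    "specialty": list(SPECIALTIES),
    "facility_category": list(FACILITY_CATEGORIES),
    "visit_hours": ["in_hours", "out_of_hours"],
    "diagnosis_category": list(DIAGNOSIS_CATEGORIES),
}

DEFAULT_REFERENCES: dict[str, object] = {
    "sex": "male",
    "age_group": "60-",
    "insured_status": "family_member",
    "specialty": "others",
    "facility_category": "other_hospital",
    "visit_hours": "in_hours",
    "diagnosis_category": "J20",
    "fiscal_year": 2012,
    "month": 1,
}


@dataclass(frozen=True)
class ModelSpec:
    """Ordered categorical factors with their reference levels."""

    factors: tuple[tuple[str, object], ...] = tuple(
        (name, DEFAULT_REFERENCES[name])
        for name in (
            "sex",
            "age_group",
            "insured_status",
            "specialty",
            "facility_category",
            "visit_hours",
            "diagnosis_category",
            "fiscal_year",
            "month",
        )
    )

    @classmethod
    def of(cls, *names: str, references: dict | None = None) -> "ModelSpec":
        refs = dict(DEFAULT_REFERENCES)
        refs.update(references or {})
        return cls(tuple((n, refs[n]) for n in names))

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.factors)


@dataclass
class ORRow:
    term: str
    level: object
    or_: float | None
    ci_low: float | None
    ci_high: float | None
    is_reference: bool = False
    coef: float | None = None
    se: float | None = None


@dataclass
class ORTable:
    """Fitted odds-ratio rows plus model metadata."""

    rows: list[ORRow]
    n_obs: int
    log_likelihood: float | None = None
    kind: str = "adjusted"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "level": r.level,
                    "or": r.or_,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "is_reference": r.is_reference,
                }
                for r in self.rows
            ]
        )

    def get(self, term: str, level) -> ORRow:
        for r in self.rows:
            if r.term == term and str(r.level) == str(level):
                return r
        raise KeyError((term, level))


def _complete_cases(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    kept = df.dropna(subset=cols)
    dropped = len(df) - len(kept)
    if dropped:
        logger.info("dropped %d rows with missing covariates (complete-case)", dropped)
    return kept


def _design(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, list[tuple[str, object]]]:
    """Reference-coded design matrix and the (term, level) column labels."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    labels: list[tuple[str, object]] = [("const", None)]
    for name, ref in spec.factors:
        values = df[name]
        levels = [lv for lv in pd.unique(values) if str(lv) != str(ref)]
        try:
            levels = sorted(levels)
        except TypeError:
            levels = sorted(levels, key=str)
        if str(ref) not in {str(v) for v in pd.unique(values)}:
            raise ValueError(f"reference level {ref!r} of factor {name!r} absent from data")
        for lv in levels:
            cols[f"{name}[{lv}]"] = (values.astype(str) == str(lv)).to_numpy(dtype=float)
            labels.append((name, lv))
    X = pd.DataFrame(cols, index=df.index)
    return X, labels


def _check_separation(df: pd.DataFrame, outcome: str, factors: list[str]) -> None:
    for name in factors:
        grouped = df.groupby(name, observed=True)[outcome].agg(["mean", "size"])
        for level, row in grouped.iterrows():
            if row["size"] > 0 and row["mean"] in (0.0, 1.0):
                raise PerfectSeparationError(
                    f"factor {name!r} level {level!r} has outcome constant at "
                    f"{int(row['mean'])} over {int(row['size'])} rows"
                )


def _fit_glm(y: np.ndarray, X: pd.DataFrame):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in 100 iterations (deviance {res.deviance:.6g})"
        )
    return res


def _rows_from_fit(res, labels, spec: ModelSpec) -> list[ORRow]:
    rows: list[ORRow] = []
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    est = {lab: (params[i], bse[i]) for i, lab in enumerate(labels)}
    for name, ref in spec.factors:
        rows.append(ORRow(name, ref, 1.0, None, None, is_reference=True))
        for lab in labels:
            if lab[0] != name:
                continue
            coef, se = est[lab]
            rows.append(
                ORRow(
                    name,
                    lab[1],
                    float(np.exp(coef)),
                    float(np.exp(coef - Z_95 * se)),
                    float(np.exp(coef + Z_95 * se)),
                    coef=float(coef),
                    se=float(se),
                )
            )
    return rows


def fit_crude(
    cohort: Cohort | pd.DataFrame, factor: str, reference=None, outcome: str = "prescribed"
) -> ORTable:
    """Single-factor logistic regression; one OR row per non-reference level.

    Levels with no observations are dropped with a warning; a level with a
    constant outcome raises :class:`PerfectSeparationError` naming it.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    df = _complete_cases(df, [factor, outcome])
    if reference is None:
        reference = DEFAULT_REFERENCES.get(factor, None)
        if reference is None or str(reference) not in set(df[factor].astype(str)):
            reference = df[factor].iloc[0]
    present = df[factor].value_counts()
    if (present == 0).any():
        logger.warning("factor %r: empty levels dropped: %s", factor, list(present[present == 0].index))
    if len(present) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 observed levels")
    _check_separation(df, outcome, [factor])
    spec = ModelSpec(((factor, reference),))
    X, labels = _design(df, spec)
    res = _fit_glm(df[outcome].to_numpy(dtype=float), X)
    return ORTable(_rows_from_fit(res, labels, spec), n_obs=len(df), log_likelihood=float(res.llf), kind="crude")


def fit_adjusted(
    cohort: Cohort | pd.DataFrame,
    spec: ModelSpec | None = None,
    outcome: str = "prescribed",
) -> ORTable:
    """One joint logistic model over all factors in ``spec``; adjusted ORs
    with Wald 95% CIs for every non-reference level."""
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    spec = spec or ModelSpec()
    df = _complete_cases(df, list(spec.factor_names) + [outcome])
    _check_separation(df, outcome, list(spec.factor_names))
    X, labels = _design(df, spec)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(R))
        aliased = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]}; aliased columns: {aliased}"
        )
    res = _fit_glm(df[outcome].to_numpy(dtype=float), X)
    return ORTable(_rows_from_fit(res, labels, spec), n_obs=len(df), log_likelihood=float(res.llf), kind="adjusted")


def or_table(
    cohort: Cohort | pd.DataFrame, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Combined crude + adjusted OR table (one row per factor level)."""
    spec = spec or ModelSpec()
    adjusted = fit_adjusted(cohort, spec)
    frames = []
    for name, ref in spec.factors:
        crude = fit_crude(cohort, name, reference=ref).to_frame()
        crude = crude.rename(
            columns={"or": "crude_or", "ci_low": "crude_ci_low", "ci_high": "crude_ci_high"}
        )
        frames.append(crude)
    crude_all = pd.concat(frames, ignore_index=True)
    adj = adjusted.to_frame().rename(
        columns={"or": "adjusted_or", "ci_low": "adjusted_ci_low", "ci_high": "adjusted_ci_high"}
    )
    merged = adj.merge(
        crude_all.drop(columns=["is_reference"]),
        on=["term", "level"],
        how="left",
    )
    order = ["term", "level", "crude_or", "crude_ci_low", "crude_ci_high",
             "adjusted_or", "adjusted_ci_low", "adjusted_ci_high", "is_reference"]
    return merged[order]


def stratified_yearly_aor(
    cohort: Cohort | pd.DataFrame,
    strata: str = "specialty",
    year_factor: str = "fiscal_year",
) -> pd.DataFrame:
    """Fiscal-year adjusted ORs overall and within each stratum.

    Within each stratum the model adjusts for sex, age group, insurance
    status, facility operation type, visit hours, and calendar month, plus
    the fiscal year (reference: first study year).  A year absent from a
    stratum is reported as missing, never imputed.  Returns a frame indexed
    by fiscal year with one column per stratum plus ``overall``.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    covariates = [
        "sex", "age_group", "insured_status", "facility_category", "visit_hours", "month",
    ]
    years = sorted(df[year_factor].unique())
    ref_year = DEFAULT_REFERENCES.get(year_factor, years[0])
    if ref_year not in years:
        ref_year = years[0]
    spec = ModelSpec.of(*covariates, year_factor, references={year_factor: ref_year})

    def yearly(sub: pd.DataFrame) -> dict:
        # drop factors that are constant within the stratum (e.g. a
        # single-facility-category stratum) to keep the design full rank
        names = [n for n in spec.factor_names if sub[n].nunique() > 1 or n == year_factor]
        refs = {n: r for n, r in spec.factors if n in names}
        local_ref = refs[year_factor]
        if local_ref not in set(sub[year_factor]):
            refs[year_factor] = sorted(sub[year_factor].unique())[0]
        local = ModelSpec(tuple((n, refs[n]) for n in names))
        for n in names:  # references must exist in the stratum
            if str(refs[n]) not in set(sub[n].astype(str)):
                refs[n] = sub[n].iloc[0]
        local = ModelSpec(tuple((n, refs[n]) for n in names))
        fitted = fit_adjusted(sub, local)
        out = {}
        for y in years:
            if y not in set(sub[year_factor]):
                out[y] = np.nan
            elif str(y) == str(refs[year_factor]):
                out[y] = 1.0
            else:
                out[y] = fitted.get(year_factor, y).or_
        return out

    table = {"overall": yearly(df)}
    for level in sorted(df[strata].unique()):
        table[str(level)] = yearly(df[df[strata] == level])
    return pd.DataFrame(table, index=pd.Index(years, name=year_factor))
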