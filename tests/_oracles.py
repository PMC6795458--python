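"""Independent brute-force oracles used by the test suite.

These deliberately re-derive everything with naive loops and their own
constant tables so that they share no code path with the package.
"""

from __future__ import annotations

import pandas as pd

ARTI3 = {"J00", "J01", "J02", "J03", "J04", "J05", "J06", "J20", "J21", "J22"}
SINGLES = {"J20", "J06", "J02", "J00", "J03"}
PAIRS = {
    frozenset({"J06", "J20"}),
    frozenset({"J02", "J20"}),
    frozenset({"J02", "J06"}),
    frozenset({"J00", "J20"}),
    frozenset({"J00", "J06"}),
}
CLASS_PREFIXES = [
    ("J01DD", "third_gen_cephalosporin"),
    ("J01FA", "macrolide"),
    ("J01MA", "fluoroquinolone"),
    ("J01C", "penicillin"),
]


def oracle_atc_class(atc: str) -> str:
    for prefix, label in CLASS_PREFIXES:
        if atc.startswith(prefix):
            return label
    return "other_J01"


def oracle_category(codes) -> str:
    classes = frozenset(c[:3] for c in codes if c[:3] in ARTI3)
    if len(classes) == 1 and next(iter(classes)) in SINGLES:
        return next(iter(classes))
    if classes in PAIRS:
        return " & ".join(sorted(classes))
    return "others"


def oracle_cross_product_or(a: int, b: int, c: int, d: int) -> float:
    """OR of exposed (a yes / b no) vs reference (c yes / d no)."""
    return (a * d) / (b * c)


def brute_force_cohort(bundle, verdicts: dict, window: int):
    """Naive triple-loop cohort build.

    ``verdicts`` maps diagnosis codes (exact or 3-char class) to the
    requires-antibiotics boolean; unknown codes default to False.
    """
    def requires(code: str) -> bool:
        if code in verdicts:
            return verdicts[code]
        return verdicts.get(code[:3], False)

    dx = list(bundle.diagnoses.itertuples(index=False))
    rx = list(bundle.prescriptions.itertuples(index=False))
    rows = []
    n_arti = 0
    n_excluded = 0
    for c in bundle.consultations.itertuples(index=False):
        active = set()
        for d in dx:
            if d.patient_id != c.patient_id:
                continue
            gap = (c.date - d.diagnosis_date).days
            if 0 <= gap <= window:
                active.add(d.code)
        if not any(code[:3] in ARTI3 for code in active):
            continue
        n_arti += 1
        if any(requires(code) for code in active):
            n_excluded += 1
            continue
        classes = set()
        for r in rx:
            if (
                r.patient_id == c.patient_id
                and r.date == c.date
                and str(r.atc_code).startswith("J01")
            ):
                classes.add(oracle_atc_class(str(r.atc_code)))
        rows.append(
            {
                "patient_id": c.patient_id,
                "facility_id": c.facility_id,
                "date": c.date,
                "active_codes": frozenset(active),
                "diagnosis_category": oracle_category(active),
                "prescribed": bool(classes),
                "antibiotic_classes": frozenset(classes),
            }
        )
    attrition = {
        "consultations_in": len(bundle.consultations),
        "arti_consultations": n_arti,
        "excluded_bacterial": n_excluded,
        "nbarti_consultations": len(rows),
    }
    return pd.DataFrame(rows), attrition


def oracle_ols_slope(t, y) -> float:
    """Closed-form OLS slope: sum((t-tbar)(y-ybar)) / sum((t-tbar)^2)."""
    n = len(t)
    tbar = sum(t) / n
    ybar = sum(y) / n
    num = sum((ti - tbar) * (yi - ybar) for ti, yi in zip(t, y))
    den = sum((ti - tbar) ** 2 for ti in t)
    return num / den
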