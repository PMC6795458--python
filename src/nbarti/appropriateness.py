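"""Diagnosis-level antibiotic-appropriateness verdicts and the ATC class map.

The appropriateness table maps a diagnosis code (a 3-character ICD-10 class
or a finer suffixed code) to a binary verdict: does this diagnosis require
antibiotic treatment?  Consultations carrying any code with a ``true``
verdict in their active window are excluded from the non-bacterial cohort.

The packaged default table (``data/appropriateness_default.csv``) is a
clearly-labelled stand-in covering the ICD-10 J00-J22 classes: acute
respiratory tract infection classes map to ``false`` and bacterial
pneumonia-type classes to ``true``.  Real analyses should supply their own
adjudicated table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AppropriatenessError",
    "UnknownCodeError",
    "AppropriatenessTable",
    "AntibioticClass",
    "load_appropriateness_table",
    "default_appropriateness_table",
    "classify_antibiotic",
    "ANTIBIOTIC_CLASSES",
    "BROAD_SPECTRUM_CLASSES",
]

_CODE_RE = re.compile(r"^[A-Z]\d{2}[0-9A-Z]*$")
_ATC_RE = re.compile(r"^[A-Z][0-9A-Z]*$")

# ATC prefix -> class label.  Longest prefix wins; any other J01 code falls
# through to other_J01.
_ATC_CLASS_PREFIXES: tuple[tuple[str, str], ...] = (
    ("J01DD", "third_gen_cephalosporin"),
    ("J01FA", "macrolide"),
    ("J01MA", "fluoroquinolone"),
    ("J01C", "penicillin"),
)
BROAD_SPECTRUM_CLASSES = frozenset(
    {"third_gen_cephalosporin", "macrolide", "fluoroquinolone"}
)
ANTIBIOTIC_CLASSES: tuple[str, ...] = (
    "third_gen_cephalosporin",
    "macrolide",
    "fluoroquinolone",
    "penicillin",
    "other_J01",
)


class AppropriatenessError(ValueError):
    """Malformed or self-contradictory appropriateness table."""


class UnknownCodeError(KeyError):
    """Strict-mode lookup of a code absent from the table."""


@dataclass(frozen=True)
class AntibioticClass:
    label: str
    is_broad_spectrum: bool

    def __post_init__(self) -> None:
        if self.label not in ANTIBIOTIC_CLASSES:
            raise ValueError(f"unknown antibiotic class label: {self.label!r}")
        if self.is_broad_spectrum != (self.label in BROAD_SPECTRUM_CLASSES):
            raise ValueError(
                f"is_broad_spectrum inconsistent with label {self.label!r}"
            )


@dataclass
class AppropriatenessTable:
    """Deterministic diagnosis-code -> requires-antibiotics lookup.

    Lookup order: exact code match, then the 3-character class prefix; a code
    matching neither raises in ``strict`` mode and defaults to ``False``
    (with a logged warning) in ``lenient`` mode.
    """

    entries: dict[str, bool]
    mode: str = "lenient"
    provenance: str = ""
    _warned: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "lenient"):
            raise AppropriatenessError(f"unknown mode: {self.mode!r}")
        for code in self.entries:
            if not _CODE_RE.match(code):
                raise AppropriatenessError(f"syntactically invalid diagnosis code: {code!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def requires_antibiotics(self, code: str) -> bool:
        code = str(code).strip().upper()
        if code in self.entries:
            return self.entries[code]
        prefix = code[:3]
        if prefix in self.entries:
            return self.entries[prefix]
        if self.mode == "strict":
            raise UnknownCodeError(code)
        if code not in self._warned:
            self._warned.add(code)
            logger.warning(
                "code %r not in appropriateness table; defaulting to requires_antibiotics=False",
                code,
            )
        return False


def load_appropriateness_table(
    path: str | Path,
    mode: str = "lenient",
    delimiter: str = ",",
    provenance: str | None = None,
) -> AppropriatenessTable:
    """Load a two-column (code, requires_antibiotics) delimited table.

    Identical duplicate rows are collapsed with a log note; duplicate codes
    with conflicting verdicts are an error, as are malformed verdicts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in ("code", "requires_antibiotics"):
        if col not in df.columns:
            raise AppropriatenessError(f"appropriateness table missing column {col!r}")
    verdict_map = {"true": True, "false": False, "1": True, "0": False}
    entries: dict[str, bool] = {}
    n_dup = 0
    for row_no, (code, verdict) in enumerate(
        zip(df["code"], df["requires_antibiotics"]), start=2
    ):
        code = str(code).strip().upper()
        key = str(verdict).strip().lower()
        if key not in verdict_map:
            raise AppropriatenessError(
                f"{path}:{row_no}: malformed verdict {verdict!r} for code {code!r}"
            )
        value = verdict_map[key]
        if code in entries:
            if entries[code] != value:
                raise AppropriatenessError(
                    f"{path}: conflicting verdicts for code {code!r}"
                )
            n_dup += 1
            continue
        entries[code] = value
    if n_dup:
        logger.info("appropriateness table %s: %d identical duplicate rows collapsed", path, n_dup)
    return AppropriatenessTable(
        entries=entries,
        mode=mode,
        provenance=provenance if provenance is not None else str(path),
    )


def default_appropriateness_table(mode: str = "lenient") -> AppropriatenessTable:
    """The packaged stand-in table over the ICD-10 J00-J22 classes."""
    with resources.as_file(
        resources.files("nbarti.data") / "appropriateness_default.csv"
    ) as path:
        return load_appropriateness_table(
            path, mode=mode, provenance="packaged stand-in table (J00-J22 classes)"
        )


def classify_antibiotic(atc_code: str) -> AntibioticClass:
    """Map a J01 ATC code to its antibiotic class.

    J01DD -> third-generation cephalosporin, J01FA -> macrolide,
    J01MA -> fluoroquinolone (all broad-spectrum); J01C -> penicillin; any
    other J01 code -> other_J01.  Non-J01 codes are out of scope and raise.
    """
    code = str(atc_code).strip().upper()
    if not _ATC_RE.match(code):
        raise ValueError(f"invalid ATC code: {atc_code!r}")
    if not code.startswith("J01"):
        raise ValueError(f"ATC code out of scope (not J01): {atc_code!r}")
    for prefix, label in _ATC_CLASS_PREFIXES:
        if code.startswith(prefix):
            return AntibioticClass(label, label in BROAD_SPECTRUM_CLASSES)
    return AntibioticClass("other_J01", False)
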