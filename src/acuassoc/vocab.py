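"""Controlled vocabularies for acupoints and diagnosis codes.

Acupoints follow the WHO standard nomenclature: a two-letter meridian
identifier (12 organ meridians plus the Conception Vessel CV and Governing
Vessel GV) and a positive point index, e.g. ``ST36`` (Zusanli).  The 14
meridians carry 361 points in total.

Diagnosis codes are ICD-10-style three-character strings: the Korean-medicine
pattern extension codes U20-U99 ("U-pattern" family) and R symptom codes
("R-symptom" family, used when a doctor records an individual symptom such as
R42, vertigo, instead of a full pattern).

Raw clinical terms are normalized against these registries, optionally via a
user-supplied synonym table.  Normalization failures are returned as tagged
:class:`Rejection` values rather than raised, so preprocessing can count and
log drops (points outside the 14 meridians — auricular points, trigger
points — are a routine part of real prescriptions and must be filtered, not
crash the run).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "MERIDIAN_MAX",
    "AcupointCode",
    "DiagnosisCode",
    "Rejection",
    "SynonymTable",
    "load_acupoint_registry",
    "normalize_acupoint",
    "normalize_diagnosis",
    "acupoint_sort_key",
]

#: Highest point index on each of the 14 meridians (WHO standard); 361 total.
MERIDIAN_MAX: dict[str, int] = {
    "LU": 11, "LI": 20, "ST": 45, "SP": 21, "HT": 9, "SI": 19, "BL": 67,
    "KI": 27, "PC": 9, "TE": 23, "GB": 44, "LR": 14, "CV": 24, "GV": 28,
}

#: Input aliases for meridian identifiers ("SJ" = Sanjiao = Triple Energizer).
_MERIDIAN_ALIASES: dict[str, str] = {"SJ": "TE"}

# Substrings that mark a term as an extra-meridian point category.
_NON_MERIDIAN_MARKERS = (
    "auricular", "ear point", "trigger", "ashi", "a-shi", "a shi", "ex-",
    "extra point",
)

_ACUPOINT_RE = re.compile(r"^([A-Za-z]{2})\s*-?\s*([0-9]{1,3})$")
_DIAGNOSIS_RE = re.compile(r"^([A-Za-z])([0-9]{2})$")


@dataclass(frozen=True, order=True)
class AcupointCode:
    """A WHO-standard acupoint: meridian identifier plus point index."""

    meridian: str
    number: int

    def __post_init__(self) -> None:
        if self.meridian not in MERIDIAN_MAX:
            raise ValueError(f"unknown meridian {self.meridian!r}")
        if not 1 <= self.number <= MERIDIAN_MAX[self.meridian]:
            raise ValueError(
                f"{self.meridian}{self.number}: point index out of range "
                f"(max {MERIDIAN_MAX[self.meridian]})"
            )

    def __str__(self) -> str:
        return f"{self.meridian}{self.number}"

    @classmethod
    def parse(cls, code: str) -> "AcupointCode":
        """Parse a canonical code string such as ``ST36``, ``st 36`` or ``SJ5``."""
        m = _ACUPOINT_RE.match(code.strip())
        if m is None:
            raise ValueError(f"not a canonical acupoint code: {code!r}")
        meridian = m.group(1).upper()
        meridian = _MERIDIAN_ALIASES.get(meridian, meridian)
        return cls(meridian, int(m.group(2)))


@dataclass(frozen=True)
class DiagnosisCode:
    """An ICD-10-style diagnosis code: U20-U99 pattern codes or R symptom codes."""

    code: str

    def __post_init__(self) -> None:
        m = _DIAGNOSIS_RE.match(self.code)
        if m is None:
            raise ValueError(f"not a letter+2-digit code: {self.code!r}")
        letter, digits = m.group(1).upper(), m.group(2)
        object.__setattr__(self, "code", letter + digits)
        if letter == "U":
            if not 20 <= int(digits) <= 99:
                raise ValueError(f"U code out of range U20-U99: {self.code}")
        elif letter != "R":
            raise ValueError(f"unsupported code family: {self.code}")

    @property
    def family(self) -> str:
        return "R-symptom" if self.code[0] == "R" else "U-pattern"

    def __str__(self) -> str:
        return self.code


@dataclass(frozen=True)
class Rejection:
    """Tagged marker for a term that could not be normalized.

    ``reason`` is one of ``non-meridian``, ``out-of-range``, ``unknown-term``
    or ``bad-code``.
    """

    raw: str
    reason: str

    def __bool__(self) -> bool:  # rejections are falsy; codes are truthy
        return False


@dataclass
class SynonymTable:
    """Raw term -> canonical code lookup for acupoints and diagnoses.

    Lookup is exact after whitespace stripping and case folding; no fuzzy
    matching.  Every target code is validated against the registries on
    insertion, so the table can never emit an out-of-registry code.
    """

    acupoints: dict[str, str] = field(default_factory=dict)
    diagnoses: dict[str, str] = field(default_factory=dict)
    #: casefolded key -> original display form, for re-emitting raw text
    display_forms: dict[str, str] = field(default_factory=dict)

    def add(self, raw_term: str, code: str, kind: str) -> None:
        key = raw_term.strip().casefold()
        if not key:
            raise ValueError("empty raw term")
        if kind == "acupoint":
            self.acupoints[key] = str(AcupointCode.parse(code))
        elif kind == "diagnosis":
            self.diagnoses[key] = str(DiagnosisCode(code))
        else:
            raise ValueError(f"kind must be 'acupoint' or 'diagnosis', got {kind!r}")
        self.display_forms[key] = raw_term.strip()

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "SynonymTable":
        """Load a table from CSV with header ``raw_term,code,kind`` (UTF-8)."""
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"raw_term", "code", "kind"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(
                    f"{path}: synonym CSV must have columns raw_term,code,kind"
                )
            for row in reader:
                table.add(row["raw_term"], row["code"], row["kind"].strip())
        return table

    def reverse_acupoint_index(self) -> dict[str, list[str]]:
        """Map each canonical acupoint code to its raw synonyms (sorted)."""
        rev: dict[str, list[str]] = {}
        for raw, code in sorted(self.acupoints.items()):
            rev.setdefault(code, []).append(self.display_forms.get(raw, raw))
        return rev

    def reverse_diagnosis_index(self) -> dict[str, list[str]]:
        rev: dict[str, list[str]] = {}
        for raw, code in sorted(self.diagnoses.items()):
            rev.setdefault(code, []).append(self.display_forms.get(raw, raw))
        return rev


def load_acupoint_registry() -> frozenset[AcupointCode]:
    """All 361 WHO-standard acupoints on the 14 meridians."""
    return frozenset(
        AcupointCode(meridian, number)
        for meridian, top in MERIDIAN_MAX.items()
        for number in range(1, top + 1)
    )


def _looks_non_meridian(term: str) -> bool:
    low = term.casefold()
    return any(marker in low for marker in _NON_MERIDIAN_MARKERS)


def normalize_acupoint(
    raw: str, table: Union[SynonymTable, None] = None
) -> Union[AcupointCode, Rejection]:
    """Resolve a raw acupoint term to a registry code or a tagged rejection.

    Canonical code strings (any case, optional space/hyphen, ``SJ`` alias for
    ``TE``) resolve without a table entry; anything else goes through the
    synonym table.  Extra-meridian categories (auricular, trigger/ashi
    points) are rejected as ``non-meridian``; a valid meridian with an
    impossible index is ``out-of-range``.
    """
    term = raw.strip()
    if not term:
        raise ValueError("empty acupoint term")
    m = _ACUPOINT_RE.match(term)
    if m is not None:
        meridian = _MERIDIAN_ALIASES.get(m.group(1).upper(), m.group(1).upper())
        number = int(m.group(2))
        if meridian in MERIDIAN_MAX:
            if 1 <= number <= MERIDIAN_MAX[meridian]:
                return AcupointCode(meridian, number)
            return Rejection(raw, "out-of-range")
    if table is not None:
        hit = table.acupoints.get(term.casefold())
        if hit is not None:
            return AcupointCode.parse(hit)
    if _looks_non_meridian(term):
        return Rejection(raw, "non-meridian")
    return Rejection(raw, "unknown-term")


def normalize_diagnosis(
    raw: str, table: Union[SynonymTable, None] = None
) -> Union[DiagnosisCode, Rejection]:
    """Resolve a raw diagnosis term to a U/R code or a tagged rejection."""
    term = raw.strip()
    if not term:
        raise ValueError("empty diagnosis term")
    m = _DIAGNOSIS_RE.match(term)
    if m is not None:
        letter = m.group(1).upper()
        if letter == "U" and not 20 <= int(m.group(2)) <= 99:
            return Rejection(raw, "out-of-range")
        if letter in ("U", "R"):
            return DiagnosisCode(term)
        return Rejection(raw, "bad-code")
    if table is not None:
        hit = table.diagnoses.get(term.casefold())
        if hit is not None:
            return DiagnosisCode(hit)
    return Rejection(raw, "unknown-term")


def acupoint_sort_key(code: str) -> tuple[str, int]:
    """Sort key giving natural code order (BL2 before BL23, meridians A-Z)."""
    point = AcupointCode.parse(code)
    return (point.meridian, point.number)


def sort_acupoints(codes: Iterable[str]) -> list[str]:
    return sorted(codes, key=acupoint_sort_key)
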