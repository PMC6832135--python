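"""Raw record cleaning and diagnosis-acupoint pair extraction.

Input rows (free-text or coded dialect) are normalized against the
vocabularies: the diagnosis term must resolve to a U/R code and every
acupoint term to one of the 361 meridian points, otherwise the term is
dropped and counted by rejection reason.  Records losing their diagnosis or
all of their points are dropped whole.  The surviving records are unfolded
into (diagnosis, acupoint) pair instances — the unit of counting for every
downstream statistic.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .synthetic import PrescriptionRecord
from .vocab import SynonymTable, acupoint_sort_key, normalize_acupoint, normalize_diagnosis

__all__ = ["PairInstance", "CleaningReport", "clean_records", "extract_pairs",
           "read_records_csv", "pairs_to_frame"]

REQUIRED_COLUMNS = ("doctor_id", "case_id", "diagnosis", "acupoints")


class PairInstance(NamedTuple):
    """One (diagnosis, acupoint) occurrence, traceable to its source record."""

    diagnosis: str
    acupoint: str
    record_ref: str


@dataclass
class CleaningReport:
    """Auditable account of what preprocessing kept and dropped."""

    n_input_records: int = 0
    n_kept_records: int = 0
    n_dropped_records: dict[str, int] = field(default_factory=dict)
    n_dropped_points: dict[str, int] = field(default_factory=dict)
    n_duplicate_points_collapsed: int = 0
    n_pair_instances: int = 0
    n_unique_pairs: int = 0

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def read_records_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read the record CSV dialect (raw or coded terms)."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frame


def clean_records(
    rows: Union[pd.DataFrame, str, Path],
    table: Optional[SynonymTable] = None,
    collapse_duplicates: bool = True,
) -> tuple[list[PrescriptionRecord], CleaningReport]:
    """Normalize raw rows into validated records plus a cleaning report.

    ``rows`` may be a DataFrame in the record dialect or a path to one.
    With ``collapse_duplicates`` (default) a prescription is treated as a
    set: a point listed twice in one record counts once.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = read_records_csv(rows)
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"record table missing columns {missing}")
    table = table or SynonymTable()

    report = CleaningReport(n_input_records=len(rows))
    dropped_records: Counter[str] = Counter()
    dropped_points: Counter[str] = Counter()
    records: list[PrescriptionRecord] = []

    for i, row in enumerate(rows.itertuples(index=False)):
        try:
            raw_points = [t for t in str(row.acupoints).split(";") if t.strip()]
        except AttributeError as exc:  # pragma: no cover - guarded above
            raise ValueError(f"row {i}: malformed record") from exc
        dx = normalize_diagnosis(str(row.diagnosis), table) if str(row.diagnosis).strip() else None
        if not dx:
            dropped_records["no-diagnosis"] += 1
            continue
        points: list[str] = []
        for term in raw_points:
            code = normalize_acupoint(term, table)
            if code:
                points.append(str(code))
            else:
                dropped_points[code.reason] += 1
        if collapse_duplicates:
            deduped = sorted(set(points), key=acupoint_sort_key)
            report.n_duplicate_points_collapsed += len(points) - len(deduped)
            points = deduped
        else:
            points = sorted(points, key=acupoint_sort_key)
        if not points:
            dropped_records["no-valid-acupoints"] += 1
            continue
        if collapse_duplicates:
            record = PrescriptionRecord(
                str(row.doctor_id), int(row.case_id), str(dx), tuple(points)
            )
        else:
            # bypass the distinctness invariant when duplicates are kept
            record = PrescriptionRecord.__new__(PrescriptionRecord)
            object.__setattr__(record, "doctor_id", str(row.doctor_id))
            object.__setattr__(record, "case_id", int(row.case_id))
            object.__setattr__(record, "diagnosis", str(dx))
            object.__setattr__(record, "acupoints", tuple(points))
        records.append(record)

    report.n_kept_records = len(records)
    report.n_dropped_records = dict(dropped_records)
    report.n_dropped_points = dict(dropped_points)
    pairs = extract_pairs(records)
    report.n_pair_instances = len(pairs)
    report.n_unique_pairs = len({(p.diagnosis, p.acupoint) for p in pairs})
    return records, report


def extract_pairs(records: Sequence[PrescriptionRecord]) -> list[PairInstance]:
    """One pair instance per (record, acupoint), record order then code order."""
    pairs: list[PairInstance] = []
    for i, record in enumerate(records):
        ref = f"{record.doctor_id}:{record.case_id}:{i}"
        for point in sorted(record.acupoints, key=acupoint_sort_key):
            pairs.append(PairInstance(record.diagnosis, point, ref))
    return pairs


def pairs_to_frame(pairs: Iterable[PairInstance]) -> pd.DataFrame:
    return pd.DataFrame(pairs, columns=["diagnosis", "acupoint", "record_ref"])
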