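"""Seeded virtual-diagnosis cohort generator.

The study design this emulates: N doctors (default 80) each review the same
set of clinical cases (default 10) and record, per case, one diagnosis
pattern (an ICD-10 U pattern code, or an R symptom code) plus a prescription
of 3-5 distinct acupoints.  The real records from such a survey are not
public, so analyses are exercised on synthetic cohorts with the same
statistical structure:

* per-case categorical diagnosis distributions whose modal probabilities sit
  in the 0.2-0.4 band observed in practice (doctors agree on the leading
  pattern for a case only partially);
* per-diagnosis acupoint profiles that mix a *common pool* of broadly
  indicated points (ST36, LI4, LR3, SP6, CV12, PC6) with *pattern-specific*
  points (e.g. ST35/SP10 for blood disorder U61, KI3/KI7/BL23 for kidney
  disease U71), with ``common_weight`` controlling the split;
* 3-5 distinct points per record, drawn without replacement proportionally
  to the profile weights.

Generation is fully deterministic given (config, seed).  A companion
``degrade_to_raw_text`` step re-expresses coded records as free-text rows
(synonyms, optional injected extra-meridian points) to exercise the
normalization and filtering path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .vocab import (
    AcupointCode,
    DiagnosisCode,
    SynonymTable,
    load_acupoint_registry,
    acupoint_sort_key,
)

__all__ = [
    "PrescriptionRecord",
    "CohortConfig",
    "default_case_profiles",
    "default_pattern_profiles",
    "default_config",
    "null_config",
    "generate_cohort",
    "records_to_frame",
    "degrade_to_raw_text",
    "COMMON_POOL",
    "SPECIFIC_POINTS",
]

#: Broadly indicated points prescribed under essentially every pattern.
COMMON_POOL: tuple[str, ...] = ("ST36", "LI4", "LR3", "SP6", "CV12", "PC6")

#: Pattern-specific acupoints per diagnosis code.  The five patterns with
#: published top-5 prescription lists keep those points; the remaining codes
#: get meridian-plausible inventions so every default diagnosis has a
#: recoverable specific signature.
SPECIFIC_POINTS: dict[str, tuple[str, ...]] = {
    "U61": ("ST35", "SP10"),          # blood disorder
    "U62": ("KI3", "BL17"),           # qi-blood-yin-yang deficiency
    "U71": ("KI3", "KI7", "BL23"),    # kidney disease
    "U65": ("CV17", "GV20"),          # liver excess
    "U63": ("ST40", "CV12"),          # fluid and humour
    "U73": ("ST34", "ST21"),          # stomach disease
    "U30": ("GV3", "BL25"),           # musculoskeletal / connective tissue
    "U60": ("CV6", "CV4"),            # qi deficiency
    "U66": ("HT7", "BL15"),           # heart deficiency
    "U67": ("HT8", "PC8"),            # heart excess
    "U68": ("SP3", "BL20"),           # spleen disease
    "R42": ("GB20", "TE17"),          # vertigo (symptom code)
}

# Per-case diagnosis distributions: modal code first with its modal
# probability, then plausible alternates.  Modal probabilities follow the
# per-case agreement levels seen in the virtual-diagnosis survey (0.199-0.406).
_CASE_PROFILES: dict[int, dict[str, float]] = {
    1: {"U63": 0.406, "R42": 0.250, "U68": 0.200, "U60": 0.144},
    2: {"U73": 0.285, "U68": 0.250, "U66": 0.240, "U60": 0.225},
    3: {"U65": 0.278, "U66": 0.260, "U62": 0.240, "U60": 0.222},
    4: {"U61": 0.403, "U30": 0.250, "U71": 0.180, "U60": 0.167},
    5: {"U62": 0.238, "U61": 0.230, "U71": 0.210, "U63": 0.180, "U60": 0.142},
    6: {"U71": 0.386, "U62": 0.230, "U63": 0.200, "U60": 0.184},
    7: {"U65": 0.307, "U67": 0.260, "U66": 0.240, "U60": 0.193},
    8: {"U30": 0.338, "U71": 0.250, "U61": 0.220, "U62": 0.192},
    9: {"U61": 0.199, "U30": 0.195, "U62": 0.190, "U63": 0.180,
        "U66": 0.130, "U60": 0.106},
    10: {"U62": 0.397, "U61": 0.250, "U60": 0.200, "U68": 0.153},
}


@dataclass(frozen=True)
class PrescriptionRecord:
    """One doctor's diagnosis and acupoint prescription for one case."""

    doctor_id: str
    case_id: int
    diagnosis: str
    acupoints: tuple[str, ...]  # distinct, stored in natural code order

    def __post_init__(self) -> None:
        DiagnosisCode(self.diagnosis)  # validate
        points = tuple(sorted(set(self.acupoints), key=acupoint_sort_key))
        if len(points) != len(self.acupoints):
            raise ValueError("duplicate acupoints within a record")
        for p in points:
            AcupointCode.parse(p)
        object.__setattr__(self, "acupoints", points)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic virtual-diagnosis cohort.

    ``case_profiles`` maps case id -> {diagnosis code: probability};
    ``pattern_profiles`` maps diagnosis code -> {acupoint code: weight}.
    ``multi_pattern_rate`` is the probability that a (doctor, case) response
    contributes a second record with another pattern from the same case
    profile (real surveys occasionally yield more pairs than records x
    points would bound; off by default).
    """

    n_doctors: int = 80
    n_cases: int = 10
    points_min: int = 3
    points_max: int = 5
    case_profiles: dict[int, dict[str, float]] = field(default_factory=dict)
    pattern_profiles: dict[str, dict[str, float]] = field(default_factory=dict)
    common_weight: float = 0.5
    multi_pattern_rate: float = 0.0
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_doctors < 1 or self.n_cases < 1:
            raise ValueError("cohort sizes must be positive")
        if not 1 <= self.points_min <= self.points_max:
            raise ValueError("invalid points-per-record range")
        if not 0.0 <= self.multi_pattern_rate <= 1.0:
            raise ValueError("multi_pattern_rate must lie in [0, 1]")
        registry = {str(p) for p in load_acupoint_registry()}
        if set(self.case_profiles) != set(range(1, self.n_cases + 1)):
            raise ValueError("case_profiles must cover case ids 1..n_cases")
        for case_id, profile in self.case_profiles.items():
            total = sum(profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"case {case_id} probabilities sum to {total}")
            for code in profile:
                DiagnosisCode(code)
                if code not in self.pattern_profiles:
                    raise ValueError(f"no pattern profile for {code}")
        for code, weights in self.pattern_profiles.items():
            positive = [a for a, w in weights.items() if w > 0]
            if len(positive) < self.points_max:
                raise ValueError(
                    f"profile {code} has {len(positive)} positive-weight points; "
                    f"need at least points_max={self.points_max}"
                )
            for point in weights:
                if point not in registry:
                    raise ValueError(f"profile {code}: unregistered acupoint {point}")


def default_case_profiles() -> dict[int, dict[str, float]]:
    return {case: dict(profile) for case, profile in _CASE_PROFILES.items()}


def default_pattern_profiles(common_weight: float = 0.5) -> dict[str, dict[str, float]]:
    """Mix the common pool and the specific set for every default diagnosis.

    Each common point gets ``common_weight / len(pool)``; each specific point
    shares the remaining mass.  A point in both sets (CV12 for U63)
    accumulates both contributions.
    """
    if not 0.0 < common_weight < 1.0:
        raise ValueError("common_weight must lie strictly between 0 and 1")
    profiles: dict[str, dict[str, float]] = {}
    for code, specific in SPECIFIC_POINTS.items():
        weights: dict[str, float] = {}
        for point in COMMON_POOL:
            weights[point] = weights.get(point, 0.0) + common_weight / len(COMMON_POOL)
        for point in specific:
            weights[point] = weights.get(point, 0.0) + (1.0 - common_weight) / len(specific)
        profiles[code] = weights
    return profiles


def default_config(seed: Optional[int] = None, **overrides) -> CohortConfig:
    """The standard cohort: 80 doctors x 10 cases with the default profiles."""
    common_weight = overrides.pop("common_weight", 0.5)
    n_cases = overrides.get("n_cases", 10)
    if not 1 <= n_cases <= len(_CASE_PROFILES):
        raise ValueError(f"default profiles cover 1..{len(_CASE_PROFILES)} cases")
    cfg = CohortConfig(
        case_profiles={c: p for c, p in default_case_profiles().items() if c <= n_cases},
        pattern_profiles=default_pattern_profiles(common_weight),
        common_weight=common_weight,
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


def null_config(
    n_doctors: int = 8,
    n_cases: int = 10,
    pool_size: int = 36,
    seed: Optional[int] = None,
) -> CohortConfig:
    """A no-association cohort: every diagnosis shares one acupoint distribution.

    Each case maps deterministically to its own diagnosis code and all
    diagnoses draw points uniformly from the same fixed pool, so any apparent
    diagnosis-acupoint specificity is sampling noise.  The default sizes keep
    per-document instance counts commensurate with the pool so the tf-idf
    statistic is non-degenerate (document frequencies below N, varying term
    counts); at much larger cohort sizes every point reaches every document
    and all idf weights collapse to zero.
    """
    registry = sorted((str(p) for p in load_acupoint_registry()), key=acupoint_sort_key)
    pool = registry[:pool_size]
    shared = {p: 1.0 / pool_size for p in pool}
    codes = [f"U{20 + i}" for i in range(n_cases)]
    cfg = CohortConfig(
        n_doctors=n_doctors,
        n_cases=n_cases,
        case_profiles={i + 1: {codes[i]: 1.0} for i in range(n_cases)},
        pattern_profiles={c: dict(shared) for c in codes},
        seed=seed,
    )
    cfg.validate()
    return cfg


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: Sequence[str], weights: np.ndarray, k: int
) -> list[str]:
    """Sequential weighted draws with renormalization after each pick."""
    idx = np.arange(len(items))
    w = weights.astype(float).copy()
    picked: list[str] = []
    for _ in range(k):
        p = w / w.sum()
        choice = rng.choice(idx, p=p)
        picked.append(items[choice])
        w[choice] = 0.0
    return picked


def generate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> list[PrescriptionRecord]:
    """Draw one full cohort; identical (config, seed) gives identical records.

    ``seed`` overrides ``config.seed`` when given.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    width = len(str(config.n_doctors))
    records: list[PrescriptionRecord] = []
    for d in range(1, config.n_doctors + 1):
        doctor_id = f"D{d:0{width}d}"
        for case_id in range(1, config.n_cases + 1):
            profile = config.case_profiles[case_id]
            codes = sorted(profile)
            probs = np.array([profile[c] for c in codes])
            diagnoses = [codes[rng.choice(len(codes), p=probs / probs.sum())]]
            if config.multi_pattern_rate > 0 and rng.random() < config.multi_pattern_rate:
                others = [c for c in codes if c != diagnoses[0]]
                if others:
                    q = np.array([profile[c] for c in others])
                    diagnoses.append(others[rng.choice(len(others), p=q / q.sum())])
            for diagnosis in diagnoses:
                weights = config.pattern_profiles[diagnosis]
                points = sorted(
                    (a for a, w in weights.items() if w > 0), key=acupoint_sort_key
                )
                w = np.array([weights[a] for a in points])
                k = int(rng.integers(config.points_min, config.points_max + 1))
                chosen = _weighted_sample_without_replacement(rng, points, w, k)
                records.append(
                    PrescriptionRecord(doctor_id, case_id, diagnosis, tuple(chosen))
                )
    return records


def records_to_frame(records: Iterable[PrescriptionRecord]) -> pd.DataFrame:
    """Coded CSV dialect: doctor_id, case_id, diagnosis, ';'-joined acupoints."""
    return pd.DataFrame(
        {
            "doctor_id": [r.doctor_id for r in records],
            "case_id": [r.case_id for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "acupoints": [";".join(r.acupoints) for r in records],
        }
    )


def degrade_to_raw_text(
    records: Sequence[PrescriptionRecord],
    table: SynonymTable,
    noise_rate: float,
    seed: Optional[int] = None,
    inject_nonmeridian_rate: float = 0.0,
    nonmeridian_term: str = "auricular Shenmen",
) -> pd.DataFrame:
    """Re-express coded records as free-text rows.

    Each code is replaced by one of its synonyms from ``table`` with
    probability ``noise_rate`` (codes without synonyms stay canonical), and a
    fraction of records gains one extra-meridian point so the cleaning step's
    filter is exercised.  Cleaning the output with the same table recovers
    the coded records exactly.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must lie in [0, 1]")
    if not 0.0 <= inject_nonmeridian_rate <= 1.0:
        raise ValueError("inject_nonmeridian_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rev_acu = table.reverse_acupoint_index()
    rev_dx = table.reverse_diagnosis_index()

    def degrade(code: str, rev: dict[str, list[str]]) -> str:
        synonyms = rev.get(code)
        if synonyms and rng.random() < noise_rate:
            return synonyms[rng.integers(len(synonyms))]
        return code

    rows = []
    for r in records:
        points = [degrade(a, rev_acu) for a in r.acupoints]
        if inject_nonmeridian_rate > 0 and rng.random() < inject_nonmeridian_rate:
            points.append(nonmeridian_term)
        rows.append(
            {
                "doctor_id": r.doctor_id,
                "case_id": r.case_id,
                "diagnosis": degrade(r.diagnosis, rev_dx),
                "acupoints": ";".join(points),
            }
        )
    return pd.DataFrame(rows)
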