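"""One-command pipeline: input -> cleaning -> network -> tf-idf -> permutation.

``run_pipeline`` chains every stage and writes a reproducible artifact
bundle into the output directory:

* ``cleaning_report.json``  — what was kept/dropped during normalization
* ``pairs.csv``             — the pair instances all statistics consume
* ``case_diagnoses.csv``    — per-case diagnosis prevalence
* ``frequency_table.csv``   — per-diagnosis top-k acupoints with percentages
* ``network.gexf``          — thresholded bipartite graph with centrality
* ``tfidf_heatmap.csv``     — full weight matrix
* ``associations.csv``      — weights above threshold, with p-values
* ``p_values.csv``          — per-cell permutation p-values (long form)
* ``run_metadata.json``     — all parameters, seed, package version

Reruns with an identical config are byte-identical for all CSV/JSON
artifacts.  Stage failures are re-raised tagged with the stage name and the
bundle is marked incomplete in the metadata written so far.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .model import DiagnosisAcupointModel
from .network import export_network
from .preprocessing import clean_records, extract_pairs, pairs_to_frame
from .synthetic import CohortConfig, default_config, generate_cohort, records_to_frame
from .tfidf import heatmap_matrix
from .vocab import SynonymTable

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

ARTIFACTS = (
    "cleaning_report.json", "pairs.csv", "case_diagnoses.csv", "frequency_table.csv",
    "network.gexf", "tfidf_heatmap.csv", "associations.csv", "p_values.csv",
    "run_metadata.json",
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full parameterization of one pipeline run.

    Exactly one input source applies: ``input_csv`` (coded or raw record
    CSV, with optional ``synonym_csv``) or the built-in synthetic cohort
    (default, sized by ``cohort``).
    """

    input_csv: Optional[str] = None
    synonym_csv: Optional[str] = None
    cohort: Optional[CohortConfig] = None
    min_cooccurrence: float = 10
    tfidf_threshold: float = 0.1
    idf_variant: str = "classic"
    n_perm: int = 10_000
    alpha: float = 0.05
    correction: str = "none"
    seed: Optional[int] = None
    out_dir: str = "acuassoc_out"
    frequency_top_k: int = 5

    def validate(self) -> None:
        if self.min_cooccurrence < 0 or self.tfidf_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cohort = data.pop("cohort", None)
        cfg = cls(**data)
        if cohort is not None:
            cfg.cohort = CohortConfig(**cohort)
        cfg.validate()
        return cfg

    def to_jsonable(self) -> dict:
        data = asdict(self)
        return data


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> "PipelineRun":
    """Execute every stage and write the artifact bundle; returns the run."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata = {
        "package": "acuassoc",
        "version": __version__,
        "config": config.to_jsonable(),
        "complete": False,
    }
    _write_json(out / "run_metadata.json", metadata)

    stage = "ingest"
    try:
        table = SynonymTable.from_csv(config.synonym_csv) if config.synonym_csv else SynonymTable()
        if config.input_csv is not None:
            rows = pd.read_csv(config.input_csv, dtype=str).fillna("")
        else:
            cohort = config.cohort or default_config()
            rows = records_to_frame(generate_cohort(cohort, seed=config.seed))

        stage = "preprocess"
        records, report = clean_records(rows, table)
        report.to_json(out / "cleaning_report.json")
        pairs = extract_pairs(records)
        pairs_to_frame(pairs).to_csv(out / "pairs.csv", index=False)
        prevalence = (
            pd.DataFrame(
                {"case_id": [r.case_id for r in records],
                 "diagnosis": [r.diagnosis for r in records]}
            )
            .groupby(["case_id", "diagnosis"]).size().rename("count").reset_index()
        )
        prevalence["percent"] = prevalence.groupby("case_id")["count"].transform(
            lambda c: (100.0 * c / c.sum()).round(1)
        )
        prevalence.to_csv(out / "case_diagnoses.csv", index=False)

        stage = "fit"
        model = DiagnosisAcupointModel(pairs)
        results = model.fit(
            min_cooccurrence=config.min_cooccurrence,
            tfidf_threshold=config.tfidf_threshold,
            idf_variant=config.idf_variant,
            n_perm=config.n_perm,
            alpha=config.alpha,
            correction=config.correction,
            seed=config.seed,
        )

        stage = "report"
        results.frequency_table(config.frequency_top_k).to_csv(
            out / "frequency_table.csv", index=False
        )
        if results.network.graph.number_of_edges() > 0:
            export_network(results.network, out / "network.gexf", "gexf")
        else:  # degenerate but valid: write an empty graph
            export_network(results.network, out / "network.gexf", "gexf")
        heatmap_matrix(results.tfidf, out / "tfidf_heatmap.csv")
        results.associations.to_csv(out / "associations.csv", index=False)
        results.permutation.p_long().to_csv(out / "p_values.csv", index=False)
        metadata["complete"] = True
        metadata["cleaning"] = json.loads(report.to_json())
        _write_json(out / "run_metadata.json", metadata)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return PipelineRun(config=config, out_dir=out, results=results, report=report)


@dataclass
class PipelineRun:
    config: PipelineConfig
    out_dir: Path
    results: object
    report: object
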