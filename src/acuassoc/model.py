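"""Model/results interface over the association pipeline.

:class:`DiagnosisAcupointModel` holds a validated pair list (built from
records, a coded DataFrame/CSV, or an explicit pair list) and ``fit()``
runs the whole analysis — co-occurrence counts, thresholded bipartite
network with eigenvector centrality, tf-idf weighting, and the permutation
test — returning an :class:`AssociationResults` that carries the estimates,
their permutation p-values and a text ``summary()``.

Typical use::

    from acuassoc import DiagnosisAcupointModel, synthetic

    records = synthetic.generate_cohort(synthetic.default_config(), seed=1)
    res = DiagnosisAcupointModel.from_records(records).fit(n_perm=1000, seed=1)
    print(res.summary())
    res.associations        # tf-idf table with p-values
    res.centrality          # node -> eigenvector centrality
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import network as net
from . import permutation as perm
from . import tfidf as tfidf_mod
from .preprocessing import PairInstance, extract_pairs, pairs_to_frame
from .synthetic import PrescriptionRecord

__all__ = ["DiagnosisAcupointModel", "AssociationResults"]


class DiagnosisAcupointModel:
    """Association model between diagnosis patterns and prescribed acupoints."""

    def __init__(self, pairs: Sequence[PairInstance]):
        if len(pairs) == 0:
            raise ValueError("model requires at least one diagnosis-acupoint pair")
        self.pairs: list[PairInstance] = list(pairs)
        self.cooccurrence: net.CooccurrenceMatrix = net.build_matrix(self.pairs)

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[PrescriptionRecord]) -> "DiagnosisAcupointModel":
        return cls(extract_pairs(records))

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        diagnosis: str = "diagnosis",
        acupoint: str = "acupoint",
        record_ref: Optional[str] = "record_ref",
    ) -> "DiagnosisAcupointModel":
        """Build from a long-form pair table (one row per pair instance)."""
        refs = (
            frame[record_ref].astype(str)
            if record_ref is not None and record_ref in frame.columns
            else frame.index.astype(str)
        )
        pairs = [
            PairInstance(str(d), str(a), str(r))
            for d, a, r in zip(frame[diagnosis], frame[acupoint], refs)
        ]
        return cls(pairs)

    @classmethod
    def from_pair_csv(cls, path: Union[str, Path]) -> "DiagnosisAcupointModel":
        return cls.from_dataframe(pd.read_csv(path, dtype=str))

    # ---- fitting ------------------------------------------------------
    def fit(
        self,
        min_cooccurrence: float = 10,
        tfidf_threshold: float = 0.1,
        idf_variant: str = "classic",
        n_perm: int = 10_000,
        alpha: float = 0.05,
        correction: str = "none",
        seed: Optional[int] = None,
        permutation_mode: str = "pair",
    ) -> "AssociationResults":
        """Run the full analysis; see :class:`AssociationResults`."""
        graph = net.build_network(self.cooccurrence, min_cooccurrence)
        centrality = (
            pd.Series(net.eigenvector_centrality(graph)).sort_values(ascending=False)
            if graph.graph.number_of_edges() > 0
            else pd.Series(dtype=float)
        )
        weights = tfidf_mod.compute_tfidf(self.cooccurrence, idf_variant)
        result = perm.null_distribution(
            self.pairs, n_perm=n_perm, seed=seed, idf_variant=idf_variant,
            mode=permutation_mode,
        )
        associations = tfidf_mod.threshold_associations(weights, tfidf_threshold)
        associations = associations.merge(
            result.p_long()[["diagnosis", "acupoint", "p_value"]],
            on=["diagnosis", "acupoint"],
        )
        significant = perm.significant_associations(result, alpha, correction)
        params = {
            "min_cooccurrence": min_cooccurrence,
            "tfidf_threshold": tfidf_threshold,
            "idf_variant": idf_variant,
            "n_perm": n_perm,
            "alpha": alpha,
            "correction": correction,
            "seed": seed,
            "permutation_mode": permutation_mode,
        }
        return AssociationResults(
            model=self,
            params=params,
            network=graph,
            centrality=centrality,
            tfidf=weights,
            permutation=result,
            associations=associations,
            significant=significant,
        )


@dataclass
class AssociationResults:
    """Fitted association estimates with permutation-based uncertainty."""

    model: DiagnosisAcupointModel
    params: dict
    network: net.BipartiteNetwork
    centrality: pd.Series  # node -> score, descending
    tfidf: tfidf_mod.TfidfMatrix
    permutation: perm.PermutationResult
    associations: pd.DataFrame  # weight > threshold, with p-values
    significant: pd.DataFrame  # p_adjusted <= alpha

    frequency_top_k: int = field(default=5, repr=False)

    @property
    def cooccurrence(self) -> net.CooccurrenceMatrix:
        return self.model.cooccurrence

    def frequency_table(self, top_k: Optional[int] = None) -> pd.DataFrame:
        return net.frequency_table(self.cooccurrence, top_k or self.frequency_top_k)

    def summary(self) -> str:
        m = self.cooccurrence
        lines = [
            "Diagnosis-acupoint association analysis",
            "=" * 55,
            f"Pair instances: {m.n_pairs:>6d}   unique pairs: "
            f"{int((m.counts.to_numpy() > 0).sum())}",
            f"Diagnosis patterns: {len(m.diagnoses):>3d}   acupoints: {len(m.acupoints)}",
            f"Network (co-occurrence > {self.params['min_cooccurrence']:g}): "
            f"{len(self.network.diagnoses)} patterns, {len(self.network.acupoints)} acupoints, "
            f"{self.network.graph.number_of_edges()} edges",
            "",
            "Top eigenvector centrality:",
        ]
        for node, score in self.centrality.head(8).items():
            kind = self.network.graph.nodes[node].get("kind", "?")
            lines.append(f"  {node:<6s} {kind:<10s} {score:6.2f}")
        lines += [
            "",
            f"tf-idf ({self.params['idf_variant']} idf, threshold "
            f"{self.params['tfidf_threshold']:g}): {len(self.associations)} associations",
            f"Permutation test (B={self.params['n_perm']}, alpha="
            f"{self.params['alpha']:g}, correction={self.params['correction']}): "
            f"{len(self.significant)} significant pairs",
        ]
        top = self.significant.head(10)
        if len(top):
            lines.append("  diagnosis  acupoint   weight   p-value")
            for row in top.itertuples(index=False):
                lines.append(
                    f"  {row.diagnosis:<10s} {row.acupoint:<8s} "
                    f"{row.weight:7.3f}  {row.p_value:8.2e}"
                )
        return "\n".join(lines)

    def plot_heatmap(self, ax=None, path: Optional[Union[str, Path]] = None):
        """Render the tf-idf weight matrix as a heatmap (matplotlib)."""
        import matplotlib

        if path is not None and ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        weights = self.tfidf.weights
        if ax is None:
            _, ax = plt.subplots(
                figsize=(max(6, 0.3 * weights.shape[1]), max(4, 0.3 * weights.shape[0]))
            )
        im = ax.imshow(weights.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(weights.shape[1]), weights.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(weights.shape[0]), weights.index, fontsize=7)
        ax.set_xlabel("acupoint (term)")
        ax.set_ylabel("diagnosis pattern (document)")
        ax.figure.colorbar(im, ax=ax, label="L2-normalized tf-idf")
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        return ax

    def pairs_frame(self) -> pd.DataFrame:
        return pairs_to_frame(self.model.pairs)
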