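"""Tf-idf association weights between diagnosis patterns and acupoints.

Acupoints play the role of *terms* and diagnosis patterns the role of
*documents*: tf(d, t) is the co-occurrence count, df(t) the number of
diagnosis documents in which acupoint t appears at all, and

    weight(d, t) = tf(d, t) * idf(t),        idf(t) = ln(N / df(t))

followed by L2 normalization of each document row.  A point prescribed
under every pattern (df = N) gets idf 0 and can never look specific, which
is the property that separates this score from raw frequency: the common
pool drops out and pattern-specific points dominate.

Three idf variants are supported: ``classic`` ln(N/df) (default), ``log10``
log10(N/df), and ``smoothed`` ln(N/df) + 1 (which keeps ubiquitous terms at
a positive weight — it changes which associations clear a reporting
threshold, so the variant is recorded in all outputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .network import CooccurrenceMatrix
from .vocab import acupoint_sort_key

__all__ = ["IDF_VARIANTS", "TfidfMatrix", "compute_tfidf",
           "threshold_associations", "heatmap_matrix", "read_heatmap_matrix"]

IDF_VARIANTS = ("classic", "log10", "smoothed")


def _idf(df: np.ndarray, n_docs: int, variant: str) -> np.ndarray:
    """Inverse document frequency; terms absent everywhere (df=0) get 0."""
    df = np.asarray(df, dtype=float)
    out = np.zeros_like(df)
    present = df > 0
    ratio = n_docs / df[present]
    if variant == "classic":
        out[present] = np.log(ratio)
    elif variant == "log10":
        out[present] = np.log10(ratio)
    elif variant == "smoothed":
        out[present] = np.log(ratio) + 1.0
    else:
        raise ValueError(f"unknown idf variant {variant!r}; expected one of {IDF_VARIANTS}")
    return out


def tfidf_weights(counts: np.ndarray, variant: str = "classic") -> np.ndarray:
    """Raw-array tf-idf kernel shared by the observed fit and permutation loop."""
    counts = np.asarray(counts, dtype=float)
    n_docs = counts.shape[0]
    df = (counts > 0).sum(axis=0)
    weights = counts * _idf(df, n_docs, variant)[np.newaxis, :]
    norms = np.linalg.norm(weights, axis=1)
    positive = norms > 0
    weights[positive] /= norms[positive, np.newaxis]
    return weights


@dataclass
class TfidfMatrix:
    """L2-normalized tf-idf weights plus the ingredients they came from."""

    weights: pd.DataFrame  # diagnoses x acupoints, rows L2-normalized
    tf: pd.DataFrame
    df: pd.Series  # per-acupoint document frequency
    n_docs: int
    idf_variant: str


def compute_tfidf(matrix: CooccurrenceMatrix, idf_variant: str = "classic") -> TfidfMatrix:
    """Tf-idf weights from a co-occurrence matrix (see module docstring)."""
    counts = matrix.counts
    if counts.size == 0:
        raise ValueError("empty co-occurrence matrix")
    weights = tfidf_weights(counts.to_numpy(), idf_variant)
    return TfidfMatrix(
        weights=pd.DataFrame(weights, index=counts.index, columns=counts.columns),
        tf=counts.copy(),
        df=(counts > 0).sum(axis=0),
        n_docs=len(counts.index),
        idf_variant=idf_variant,
    )


def threshold_associations(tfidf: TfidfMatrix, min_value: float = 0.1) -> pd.DataFrame:
    """Long-form (diagnosis, acupoint, weight) table with weight strictly above
    ``min_value``, sorted by weight descending then code order."""
    if min_value < 0:
        raise ValueError("min_value must be non-negative")
    long = (
        tfidf.weights.stack()
        .rename("weight")
        .rename_axis(["diagnosis", "acupoint"])
        .reset_index()
    )
    long = long[long["weight"] > min_value]
    long = long.sort_values(
        by=["weight", "diagnosis", "acupoint"],
        ascending=[False, True, True],
        key=lambda col: col.map(acupoint_sort_key) if col.name == "acupoint" else col,
    )
    return long.reset_index(drop=True)


def heatmap_matrix(tfidf: TfidfMatrix, path: Union[str, Path]) -> Path:
    """Write the weight matrix as CSV (diagnosis rows x acupoint columns).

    Values are written at full precision (repr round-trip), so rereading
    reproduces the weights exactly.
    """
    path = Path(path)
    out = tfidf.weights.copy()
    out.index.name = "diagnosis"
    out.to_csv(path, float_format=None)
    return path


def read_heatmap_matrix(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, index_col="diagnosis")
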