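"""Permutation null for tf-idf association weights.

The null hypothesis is "acupoints are prescribed independently of the
diagnosis pattern, given how often each diagnosis and each acupoint occur
overall".  It is realized by shuffling the acupoint column of the pair list
against the fixed diagnosis column: both marginal totals of the rebuilt
contingency matrix are exactly preserved.  After each shuffle the full
tf-idf computation is repeated (document frequencies and row norms are
re-derived from the permuted table, not reused), and each cell's observed
weight is compared against that same cell's permuted weights — a one-sided
upper test, since a *specifically* prescribed point shows up as an
unusually high weight.

P-values use the add-one estimator (1 + #exceedances) / (1 + B), which
counts the observed arrangement as one realization of the null and can
never return zero.  Exceedance counting is streaming: memory is one
matrix-sized counter, independent of B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .network import CooccurrenceMatrix, build_matrix
from .preprocessing import PairInstance
from .tfidf import TfidfMatrix, compute_tfidf, tfidf_weights
from .vocab import acupoint_sort_key

__all__ = ["PermutationResult", "permute_pairs", "null_distribution",
           "significant_associations"]


@dataclass
class PermutationResult:
    """Observed weights, per-cell exceedance counts and add-one p-values."""

    observed: TfidfMatrix
    n_perm: int
    exceed_counts: pd.DataFrame
    p_values: pd.DataFrame
    seed: Optional[int]
    mode: str = "pair"
    pooled: bool = False

    def p_long(self) -> pd.DataFrame:
        """Long-form table: diagnosis, acupoint, observed weight, p-value."""
        weights = (
            self.observed.weights.stack().rename("weight")
            .rename_axis(["diagnosis", "acupoint"]).reset_index()
        )
        pvals = (
            self.p_values.stack().rename("p_value")
            .rename_axis(["diagnosis", "acupoint"]).reset_index()
        )
        return weights.merge(pvals, on=["diagnosis", "acupoint"])


def permute_pairs(
    pairs: Sequence[PairInstance], rng: Union[np.random.Generator, int, None]
) -> list[PairInstance]:
    """Uniformly permute the acupoint column against the diagnosis column."""
    if len(pairs) == 0:
        raise ValueError("cannot permute an empty pair list")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    acupoints = [p.acupoint for p in pairs]
    order = rng.permutation(len(pairs))
    return [
        PairInstance(p.diagnosis, acupoints[j], p.record_ref)
        for p, j in zip(pairs, order)
    ]


def _encode(pairs: Sequence[PairInstance], matrix: CooccurrenceMatrix):
    row_of = {d: i for i, d in enumerate(matrix.diagnoses)}
    col_of = {a: j for j, a in enumerate(matrix.acupoints)}
    d_idx = np.fromiter((row_of[p.diagnosis] for p in pairs), dtype=np.int64, count=len(pairs))
    a_idx = np.fromiter((col_of[p.acupoint] for p in pairs), dtype=np.int64, count=len(pairs))
    return d_idx, a_idx


def null_distribution(
    pairs: Sequence[PairInstance],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    idf_variant: str = "classic",
    mode: str = "pair",
    pooled: bool = False,
) -> PermutationResult:
    """Build the permutation null and per-cell p-values.

    ``mode='pair'`` shuffles acupoint labels at pair-instance level (exactly
    preserves both marginals).  ``mode='record'`` instead reassigns whole
    acupoint sets across records (each record keeps its point set but gets a
    random record's diagnosis); acupoint marginals are exact, diagnosis
    marginals are preserved at record level only.  ``pooled=True`` compares
    each observed weight against the pooled null of *all* cells' permuted
    weights instead of its own cell's.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("pair", "record"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    matrix = build_matrix(pairs)
    observed = compute_tfidf(matrix, idf_variant)
    w_obs = observed.weights.to_numpy()
    n_d, n_a = w_obs.shape
    d_idx, a_idx = _encode(pairs, matrix)
    # canonicalize pair order so p-values depend on the pair *multiset* only
    order = np.lexsort((a_idx, d_idx))
    pairs = [pairs[i] for i in order]
    d_idx, a_idx = d_idx[order], a_idx[order]
    rng = np.random.default_rng(seed)

    if mode == "record":
        refs = pd.factorize(np.asarray([p.record_ref for p in pairs]))[0]
        n_records = refs.max() + 1
        # diagnosis row index of each record (constant within a record)
        record_rows = np.zeros(n_records, dtype=np.int64)
        record_rows[refs] = d_idx

    exceed = np.zeros((n_d, n_a), dtype=np.int64)
    pooled_exceed = np.zeros((n_d, n_a), dtype=np.int64)
    flat_obs = w_obs.ravel()
    n_cells = n_d * n_a
    for _ in range(n_perm):
        if mode == "pair":
            rows = d_idx
            cols = a_idx[rng.permutation(len(a_idx))]
        else:
            shuffled = record_rows[rng.permutation(n_records)]
            rows = shuffled[refs]
            cols = a_idx
        counts = np.bincount(rows * n_a + cols, minlength=n_cells).reshape(n_d, n_a)
        w_perm = tfidf_weights(counts, idf_variant)
        exceed += w_perm >= w_obs
        if pooled:
            flat = np.sort(w_perm.ravel())
            pooled_exceed += (
                n_cells - np.searchsorted(flat, flat_obs, side="left")
            ).reshape(n_d, n_a)

    if pooled:
        p = (1.0 + pooled_exceed) / (1.0 + n_perm * n_cells)
        exceed_out = pooled_exceed
    else:
        p = (1.0 + exceed) / (1.0 + n_perm)
        exceed_out = exceed
    index, columns = observed.weights.index, observed.weights.columns
    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        exceed_counts=pd.DataFrame(exceed_out, index=index, columns=columns),
        p_values=pd.DataFrame(p, index=index, columns=columns),
        seed=seed,
        mode=mode,
        pooled=pooled,
    )


def significant_associations(
    result: PermutationResult,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Cells with (adjusted) p <= alpha, sorted by p then code order.

    ``correction`` is ``none`` (raw permutation p-values) or
    ``benjamini-hochberg`` (FDR control across all cells).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    table = result.p_long()
    if correction == "none":
        table["p_adjusted"] = table["p_value"]
    elif correction == "benjamini-hochberg":
        from statsmodels.stats.multitest import multipletests

        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    flagged = table[table["p_adjusted"] <= alpha]
    flagged = flagged.sort_values(
        by=["p_adjusted", "diagnosis", "acupoint"],
        key=lambda col: col.map(acupoint_sort_key) if col.name == "acupoint" else col,
    )
    return flagged.reset_index(drop=True)
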