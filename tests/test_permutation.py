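"""Permutation null of tf-idf weights."""

import itertools
import random

import numpy as np
import pytest

from conftest import pairs_from_counts

from acuassoc.network import build_matrix
from acuassoc.permutation import null_distribution, permute_pairs, significant_associations
from acuassoc.preprocessing import PairInstance, extract_pairs
from acuassoc.synthetic import default_config, generate_cohort
from acuassoc.tfidf import tfidf_weights

SMALL = {
    ("U61", "ST36"): 3, ("U61", "ST35"): 2, ("U62", "LI4"): 3,
    ("U62", "ST36"): 1, ("U63", "LR3"): 2, ("U63", "LI4"): 1,
}


class TestPermutePairs:
    def test_marginals_exactly_preserved(self):
        pairs = pairs_from_counts(SMALL)
        observed = build_matrix(pairs)
        rng = np.random.default_rng(0)
        for _ in range(200):
            permuted = build_matrix(permute_pairs(pairs, rng))
            permuted = permuted.counts.reindex(
                index=observed.counts.index, columns=observed.counts.columns, fill_value=0
            )
            assert (permuted.sum(axis=1) == observed.row_totals).all()
            assert (permuted.sum(axis=0) == observed.col_totals).all()

    def test_two_instances_swap_with_probability_half(self):
        pairs = [PairInstance("U61", "ST36", "r0"), PairInstance("U62", "LI4", "r1")]
        swaps = sum(
            permute_pairs(pairs, seed)[0].acupoint == "LI4" for seed in range(400)
        )
        # Binomial(400, 1/2): 3 s.e. band around 200
        assert abs(swaps / 400 - 0.5) <= 3 * np.sqrt(0.25 / 400)

    def test_single_symbol_multiset_is_fixed(self):
        pairs = [PairInstance("U6%d" % i, "ST36", f"r{i}") for i in range(5)]
        assert permute_pairs(pairs, 3) == pairs

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            permute_pairs([], 0)


class TestNullDistribution:
    def test_single_permutation_p_values(self):
        result = null_distribution(pairs_from_counts(SMALL), n_perm=1, seed=0)
        assert set(np.unique(result.p_values.to_numpy())) <= {0.5, 1.0}

    def test_uniform_matrix_all_p_one(self):
        counts = {(d, a): 2 for d in ("U61", "U62") for a in ("ST36", "LI4")}
        result = null_distribution(pairs_from_counts(counts), n_perm=50, seed=0)
        assert (result.observed.weights.to_numpy() == 0.0).all()
        assert (result.p_values.to_numpy() == 1.0).all()

    def test_deterministic_and_pair_order_invariant(self):
        pairs = pairs_from_counts(SMALL)
        a = null_distribution(pairs, n_perm=200, seed=7).p_values
        b = null_distribution(pairs, n_perm=200, seed=7).p_values
        assert a.equals(b)
        shuffled = list(pairs)
        random.Random(1).shuffle(shuffled)
        c = null_distribution(shuffled, n_perm=200, seed=7).p_values
        assert a.equals(c)
        d = null_distribution(pairs, n_perm=200, seed=8).p_values
        assert not a.equals(d)

    def test_p_value_bounds(self):
        result = null_distribution(pairs_from_counts(SMALL), n_perm=99, seed=2)
        p = result.p_values.to_numpy()
        assert (p >= 1 / 100).all() and (p <= 1.0).all()
        assert (result.exceed_counts.to_numpy() <= 99).all()

    def test_matches_exact_enumeration_on_tiny_input(self):
        """Estimated exceedance probabilities agree with full enumeration of
        all acupoint-column permutations within 3 binomial s.e."""
        counts = {("U61", "ST36"): 2, ("U61", "LI4"): 1, ("U62", "LI4"): 2, ("U62", "LR3"): 1}
        pairs = pairs_from_counts(counts)
        matrix = build_matrix(pairs)
        obs = tfidf_weights(matrix.counts.to_numpy())
        col_of = {a: j for j, a in enumerate(matrix.acupoints)}
        row_of = {d: i for i, d in enumerate(matrix.diagnoses)}
        rows = [row_of[p.diagnosis] for p in pairs]
        symbols = [col_of[p.acupoint] for p in pairs]
        n_d, n_a = obs.shape
        exact = np.zeros_like(obs)
        arrangements = 0
        for perm in itertools.permutations(symbols):
            arrangements += 1
            c = np.zeros((n_d, n_a))
            for r, a in zip(rows, perm):
                c[r, a] += 1
            exact += tfidf_weights(c) >= obs
        exact /= arrangements

        B = 3000
        result = null_distribution(pairs, n_perm=B, seed=11)
        estimate = result.exceed_counts.to_numpy() / B
        se = np.sqrt(exact * (1 - exact) / B)
        assert (np.abs(estimate - exact) <= 3 * se + 1e-12).all()

    def test_record_mode_preserves_acupoint_marginals(self):
        records = generate_cohort(default_config(n_doctors=5), seed=1)
        pairs = extract_pairs(records)
        result = null_distribution(pairs, n_perm=30, seed=0, mode="record")
        assert result.mode == "record"
        assert result.p_values.shape == result.observed.weights.shape

    def test_pooled_mode_runs(self):
        result = null_distribution(pairs_from_counts(SMALL), n_perm=100, seed=0, pooled=True)
        p = result.p_values.to_numpy()
        assert (p > 0).all() and (p <= 1.0).all()


class TestSignificantAssociations:
    def test_all_p_one_gives_empty(self):
        counts = {(d, a): 2 for d in ("U61", "U62") for a in ("ST36", "LI4")}
        result = null_distribution(pairs_from_counts(counts), n_perm=100, seed=0)
        assert significant_associations(result, 0.05).empty

    def test_minimal_p_flagged(self):
        pairs = extract_pairs(generate_cohort(default_config(), seed=2))
        result = null_distribution(pairs, n_perm=400, seed=0)
        flagged = significant_associations(result, 0.05)
        assert (flagged.p_value >= 1 / 401).all()
        assert ("U61", "ST35") in set(zip(flagged.diagnosis, flagged.acupoint))

    def test_bh_correction_is_more_conservative(self):
        pairs = extract_pairs(generate_cohort(default_config(), seed=2))
        result = null_distribution(pairs, n_perm=400, seed=0)
        raw = significant_associations(result, 0.05, "none")
        bh = significant_associations(result, 0.05, "benjamini-hochberg")
        assert set(zip(bh.diagnosis, bh.acupoint)) <= set(zip(raw.diagnosis, raw.acupoint))

    def test_unknown_correction_raises(self):
        result = null_distribution(pairs_from_counts(SMALL), n_perm=10, seed=0)
        with pytest.raises(ValueError):
            significant_associations(result, 0.05, "bonferroni-holm-sidak")
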