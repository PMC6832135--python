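# Methods

This note documents the statistical procedures implemented in `acuassoc`,
the defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the package's known limitations.

## Data model

The atomic observation is a *prescription record*: one doctor's diagnosis
for one case plus a set of 3–5 distinct acupoints. Diagnoses are ICD-10
style codes — the Korean-medicine pattern extension codes U20–U99, or R
symptom codes when a symptom rather than a full pattern was recorded.
Acupoints are WHO-standard codes on the 14 meridians (two-letter meridian
identifier + point index; 361 valid codes, `SJ` accepted as an input alias
for `TE`). Records are unfolded into *(diagnosis, acupoint)* pair
instances, one per prescribed point; every statistic below is a function of
the pair list.

Normalization is deliberately conservative: canonical code strings resolve
directly (case-insensitive, optional space/hyphen), anything else must hit
an exact entry in a user-supplied synonym table, and everything else is
*rejected with a tagged reason* (`non-meridian` for auricular/trigger/ashi
categories, `out-of-range`, `unknown-term`) and counted in the cleaning
report. There is no fuzzy matching: silent miscoding is worse than an
audited drop. Within-record duplicate points are collapsed by default (a
prescription is a set; double-counting one record would inflate term
frequencies), with a flag to keep them.

## Co-occurrence network and centrality

The contingency matrix C counts pair instances per (pattern, acupoint).
Edges with C[p,a] strictly greater than `min_cooccurrence` (default 10, an
inclusive-mode flag is available) form a bipartite weighted graph with
isolated nodes removed; edge weight is the raw count.

Eigenvector centrality is computed on the **symmetrized** graph. In the
natural directed graph (pattern → acupoint) acupoints have zero out-degree,
so directed eigenvector centrality is degenerate; undirected treatment
scores both node types. Numerically, the Perron vector of each connected
component's weighted adjacency W is found by power iteration on W + sI with
s = max row sum: the shift leaves eigenvectors unchanged but breaks the
±λ_max symmetry of bipartite spectra that makes unshifted iteration
oscillate. Iteration stops when the relative eigen-residual
‖Wv − λv‖∞ / λ falls below 1e-12 (max 10,000 iterations); this keeps the
result within ~1e-9 of a dense eigendecomposition even on small-spectral-gap
graphs, where an iterate-difference criterion is too loose. Components are
scaled by their spectral radius relative to the global maximum, and the
final scores are normalized so the top node is 1. Scores are invariant to
node relabeling and to uniform edge-weight scaling.

## tf-idf association weights

Acupoints are terms, patterns are documents: tf(p,a) = C[p,a], df(a) =
number of patterns with C[p,a] > 0, and

    w(p,a) = tf(p,a) · idf(a),   idf(a) = ln(N / df(a))   (classic, default)

followed by L2 normalization of each document row (zero rows stay zero).
`log10` and `smoothed` (ln(N/df) + 1) variants are available; the smoothed
variant keeps ubiquitous terms at positive weight and therefore changes
which associations clear the reporting threshold, so the variant is recorded
in all outputs. L2 normalization makes each pattern's weight vector
scale-free in document length: multiplying one pattern's counts by a
constant leaves its normalized weights unchanged. Associations are reported
when w strictly exceeds `tfidf_threshold` (default 0.1).

## Permutation test

Null hypothesis: acupoints are prescribed independently of the pattern,
given both sets of marginal totals. Realization: the acupoint column of the
pair list is uniformly permuted against the fixed diagnosis column, which
preserves both marginals exactly; after each of B shuffles (default
10,000), the full tf-idf computation is repeated — document frequencies,
idf and row norms are re-derived from the permuted table. Each cell's
one-sided upper p-value is (1 + #{permuted w ≥ observed w}) / (1 + B): the
add-one estimator counts the observed arrangement as one null realization
and cannot return 0; the attainable minimum is 1/(B+1) ≈ 1e-4 at the
default B. Exceedance counting is streaming (one counter matrix), and the
pair list is canonicalized before shuffling so p-values depend only on the
pair multiset, not input order. Two documented alternatives: record-level
reassignment (each record keeps its point set, diagnoses are permuted
across records — diagnosis marginals preserved at record level only) and a
pooled null (each observed weight compared to all cells' permuted weights).

No multiple-testing correction is applied by default; Benjamini–Hochberg
(via statsmodels) is available. α defaults to 0.05 and is configurable.

### Calibration

Per cell, the unconditional rejection probability under the null is ≈ α
(the add-one estimator makes it floor(α(B+1))/(B+1), 0.0499 at B = 500 and
α = 0.05). Calibration must be assessed over **all** cells of the matrix:
restricting to cells with positive observed weight conditions on an event
positively correlated with small p-values and inflates the apparent rate
(to ~0.08 in our null simulations), while cells with observed weight 0
necessarily have p = 1. The calibration test uses null cohorts in which
every pattern shares one uniform acupoint distribution over a 36-point
pool, sized (8 doctors × 10 cases) so per-document instance counts (~32)
are commensurate with the pool: document frequencies then vary below N and
the statistic is non-degenerate. At much larger cohort sizes every point
reaches every document, all idf values collapse to 0, and the test has
nothing to measure — a genuine limitation of idf-based scoring on dense
data, not of the calibration.

## Synthetic cohorts

The generator emulates a virtual-diagnosis survey: `n_doctors` (80) ×
`n_cases` (10) records, one diagnosis per record drawn from a per-case
categorical profile, and 3–5 distinct acupoints drawn without replacement
(sequential draws with renormalization) from the diagnosis's weight
profile. Defaults:

* Per-case modal probabilities between 0.199 and 0.406 — the level of
  inter-doctor agreement reported for this kind of survey — with 3–5
  plausible alternate patterns per case.
* Acupoint profiles mix a **common pool** {ST36, LI4, LR3, SP6, CV12, PC6}
  carrying `common_weight` = 0.5 of the mass with 2–3 **pattern-specific**
  points sharing the rest (e.g. U61 → ST35/SP10, U71 → KI3/KI7/BL23,
  U65 → CV17/GV20, U63 → ST40/CV12). Five high-prevalence patterns follow
  published top-5 prescription lists; the rarer alternates use
  meridian-plausible inventions so every pattern has a recoverable
  signature.
* A `multi_pattern_rate` flag (off by default) lets a response contribute a
  second pattern record, mirroring surveys whose reported pair counts
  exceed the records × points bound.

`degrade_to_raw_text` re-expresses coded records as free text (synonyms at
a configurable rate, optional injected extra-meridian points) so the
normalization path can be tested by round trip.

What the generator does **not** emulate: free-text narrative variability
beyond exact synonyms, doctor experience levels, inter-doctor correlation
beyond the shared case profiles, and any real prescription co-dependencies
between points within a record (points are drawn independently up to the
without-replacement constraint). Passing the recovery tests therefore shows
the statistics detect the planted structure under these idealized
conditions; it does not certify performance on real free-text records.

### Power

With the default effect size, the specifics of the five high-prevalence
patterns (≈380–460 pair instances each) are flagged significant in
essentially every seeded cohort. Specifics of the rare alternate patterns
(~20 records each) sit near the significance boundary (p ≈ 0.05–0.13):
with few instances, the permuted null for a small document is wide.
Detection power is governed by pattern prevalence; the recovery guarantees
in the test suite are therefore stated for the five core patterns.

## Reproducibility

All randomness flows through `numpy.random.default_rng` (PCG64) seeds:
identical (config, seed) gives byte-identical cohort CSVs and p-value
tables across runs and platforms. The pipeline writes every parameter,
the seed and the package version into `run_metadata.json`.

## Problem sizes used in the validation suite

Test and acceptance runs use: the full 800-record default cohort for
recovery (50 cohorts at B = 1,000 in the test suite; 20 at B = 500 in the
acceptance script, which also fits one cohort at the full B = 10,000);
8 × 10 null cohorts at B = 500 (tests) / 300 (script) for calibration; 100
random bipartite graphs ≤ 50 nodes for the centrality oracle; and 1,000
shuffles for marginal conservation. These sizes give Monte-Carlo standard
errors a factor of ≥3 below every margin being asserted.

## Known limitations

* The edge threshold (>10) and tf-idf threshold (>0.1) are conventions, not
  estimates; conclusions near the thresholds are sensitive to them.
* Raw co-occurrence counts weight edges; no association measure corrects
  for marginal imbalance before thresholding (the permutation test is the
  calibrated route to "specificity").
* idf-based specificity degenerates on dense data (every point in every
  pattern): use the smoothed variant or larger vocabularies there.
* The synonym tables shipped are demonstrations; real Korean free-text
  coding requires a curated lexicon and, in practice, human adjudication.
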