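# acuassoc

Association mining between traditional Korean-medicine **diagnosis patterns**
and the **acupoints** doctors prescribe for them.

In pattern-based acupuncture practice, a clinical presentation is classified
into a diagnosis pattern (coded with the ICD-10 Korean-medicine extension
codes U20–U99, or an R symptom code when a doctor records a symptom instead
of a pattern) and treated with a combination of 3–5 acupoints on the 14
meridians (WHO standard nomenclature, e.g. `ST36`). Given a table of such
prescription records — for example, from a survey where N doctors each
diagnose the same set of published case reports — this package quantifies
which acupoints are *shared* across patterns and which are *specific* to
one, with a permutation test for the specificity claims. It is aimed at
researchers studying clinical decision-making in traditional East Asian
medicine, and at anyone who needs the same machinery for generic
"label × item" prescription data.

## Methods at a glance

Records are normalized (synonym tables, rejection of extra-meridian points)
and unfolded into diagnosis–acupoint pair instances. From the contingency
matrix *C* (patterns × acupoints):

* **Co-occurrence network** — edges (p, a) with C[p,a] above a threshold
  (strictly > 10 by default) form a bipartite graph; **eigenvector
  centrality** (principal eigenvector of the symmetrized weighted adjacency,
  max-normalized to 1) ranks broadly indicated points such as ST36 and LI4.
* **tf-idf** — with acupoints as terms and patterns as documents,
  w(p,a) = tf(p,a) · ln(N / df(a)), rows L2-normalized. Points prescribed
  under every pattern get idf 0 and drop out; pattern-specific points
  dominate. Associations are reported when w > 0.1.
* **Permutation test** — the acupoint column of the pair list is shuffled
  against the diagnosis column (both marginals exactly preserved), tf-idf is
  recomputed each time (B = 10,000 by default), and each cell's one-sided
  p-value is (1 + #exceedances)/(1 + B).

Because real prescription surveys of this kind are typically not deposited,
the package ships a seeded synthetic cohort generator (80 doctors × 10
cases by default) with per-case diagnosis distributions and per-pattern
acupoint profiles that mix a common pool with pattern-specific points, so
every statistic can be exercised and validated end to end.

## Worked example

```python
from acuassoc import DiagnosisAcupointModel, synthetic

records = synthetic.generate_cohort(synthetic.default_config(), seed=1)
res = DiagnosisAcupointModel.from_records(records).fit(n_perm=10_000, seed=1)
print(res.summary())
```

```
Diagnosis-acupoint association analysis
=======================================================
Pair instances:   3188   unique pairs: 96
Diagnosis patterns:  12   acupoints: 29
Network (co-occurrence > 10): 12 patterns, 29 acupoints, 83 edges

Top eigenvector centrality:
  U62    diagnosis    1.00
  U60    diagnosis    0.99
  CV12   acupoint     0.79
  ST36   acupoint     0.77
  LI4    acupoint     0.71
  LR3    acupoint     0.67
  SP6    acupoint     0.66
  U61    diagnosis    0.65

tf-idf (classic idf, threshold 0.1): 24 associations
Permutation test (B=10000, alpha=0.05, correction=none): 21 significant pairs
  diagnosis  acupoint   weight   p-value
  U63        ST40       1.000  1.00e-04
  U62        BL17       0.781  4.00e-04
  U60        CV4        0.725  7.00e-04
  U61        ST35       0.726  7.00e-04
  ...
```

Reading the output: the common-pool points (ST36, LI4, LR3, SP6, CV12)
occupy the top acupoint centrality ranks because many patterns share them,
yet none of them appears in the significant tf-idf list — ubiquity gives
them idf 0. The significant pairs are exactly the pattern-specific
prescriptions (e.g. ST40, the phlegm point, for the fluid-and-humour
pattern U63; ST35/SP10 around the knee for the blood-disorder pattern U61),
each with a permutation p-value far below 0.05.

The same analysis is available from the shell:

```bash
acuassoc run --seed 1 --out results/          # full pipeline, all artifacts
acuassoc generate --seed 1 --raw --out cohort.csv
acuassoc preprocess cohort.csv --synonyms src/acuassoc/data/synonyms_demo.csv
acuassoc network pairs.csv --out network.gexf  # Gephi-compatible
```

`run` writes a reproducible bundle: cleaning report (JSON), pair list,
Table-style frequency summaries, GEXF network with centrality attributes,
tf-idf heatmap matrix (CSV), thresholded association table, per-cell
p-values, and run metadata. Identical config + seed gives byte-identical
tables.

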