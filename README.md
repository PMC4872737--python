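# mitodyn

Analysis of mitochondrial (mt) genome variant dynamics in matched
normal / primary-tumor / relapse cohorts, built for studies that screen
mtDNA variants from exome or genome sequencing of relapsing solid
tumors (the motivating setting is neuroblastoma). The package covers
the full path from per-sample variant tables to cohort-level claims:

* **Filtering and classification** — coverage (> 50 reads) and
  heteroplasmy abundance thresholds (≥ 2% for classification, ≥ 1% for
  trend counting); every variant key of a patient becomes *germline*
  (present in normal tissue), *tumor-specific* (absent in normal,
  present in ≥ 1 tumor) or *uninformative* (normal not adequately
  covered), with known/novel annotation against a local catalog.
* **Trend statistics** — per patient, the paired difference
  *D = R − P* of tumor-specific counts and the OLS slope
  *b = (R − N)/2* of germline counts over stages coded 0, 1, 2.  The
  cohort mean of either statistic is tested against a Monte Carlo null
  that redraws every count uniformly within the range of the observed
  counts (10,000 iterations; add-one p-value
  *(1 + #{|null| ≥ |obs|}) / (1 + iterations)*).
* **Relapse phylogeny** — tumor samples encoded over variant sites
  (alt base if AF ≥ 1%, else ref), Jukes-Cantor distances
  *d = −(3/4)·ln(1 − 4p/3)*, optionally with gamma rate variation
  *d = (3a/4)·[(1 − 4p/3)^(−1/a) − 1]* (shape *a* = 0.75), Saitou–Nei
  Neighbor-Joining, and site-bootstrap bipartition support (1,000
  replicates), emitted as Newick.
* **Mutation spectrum** — tumor-specific SNVs binned into the 96
  pyrimidine-framed substitution-in-context categories, normalized by
  the reference genome's trinucleotide frequencies and rescaled to
  percentages; primary and relapse profiles compared by cosine
  similarity.
* **Synthetic cohorts** — a generator that plants germline drift/loss
  and preferential tumor-specific gain at relapse with a
  replication-type (C>T / T>C enriched) substitution spectrum, emitting
  the same table formats plus ground truth, so every stage is testable
  end to end.

A published 16-patient neuroblastoma relapse cohort's per-patient
variant counts are bundled (`mitodyn.load_cohort_counts()`) as the
reference input for the trend statistics.

## Worked example

```python
>>> import mitodyn as md
>>> counts = md.load_cohort_counts()
>>> md.count_summary(counts)["tumor_specific"]["mean_per_tumor"]
6.28125
>>> diffs = md.paired_differences(counts)
>>> diffs["difference"].mean()
6.5625
>>> res = md.monte_carlo_test(counts[["ts_p", "ts_r"]].to_numpy(float),
...                           md.difference_statistic,
...                           iterations=10_000, seed=0)
>>> res.p_value
0.0017998200179982
```

Across the cohort's 32 tumor samples there are on average 6.3
tumor-specific mt variants per tumor; the mean relapse-minus-primary
difference of 6.56 variants is highly unlikely under the no-trend
Monte Carlo null (p ≈ 0.002), i.e. tumor-specific mt variants
accumulate at relapse.

The same works on simulated data from the shell:

```sh
mitodyn simulate --out sim/ --seed 3 --n-patients 16
mitodyn run-all --manifest sim/manifest.tsv --tables sim/ \
    --reference sim/reference.fasta --out run/ --seed 1
```

which writes classified variants, count tables, trend-test JSON,
per-patient Newick trees (for patients with ≥ 2 relapses) and the
primary/relapse spectra under `run/`.

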