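# Methods

## Setting and data model

The unit of analysis is a patient with matched samples from normal
tissue (N), the primary tumor at diagnosis (P) and one or more relapse
tumors (R1..Rk, ordered by clinical time).  Each sample contributes a
table of mitochondrial variant calls — 1-based position on a circular
mt reference, ref and alt allele, alt-allele fraction (heteroplasmy)
and read depth — as produced by an upstream mt variant screen of exome
or genome alignments.  Calls are taken at face value; read-level
evidence, NUMT contamination and haplogroup structure are out of scope.
A position with no call in a sample is interpreted as reference-covered
at adequate depth, matching the convention of callers that report every
non-reference site; the one exception is the normal sample, where a
*reported* call failing the depth filter marks the position as
uninformative for germline status.

Coordinates are 1-based and the genome is treated as circular
everywhere, so positions 1 and L have well-defined trinucleotide
contexts (this matters for an mt genome, a circular molecule; whether
to wrap is a genuine choice and we wrap).  `N` bases are allowed in the
reference; contexts containing `N` are excluded from spectrum analysis
and pooled under an `ambiguous` key in the context frequency table.

## Filters and classification

Three thresholds drive everything (defaults in parentheses):

* `min_depth` (50 reads, **exclusive**: a call needs > 50 reads);
* `abundance_classify` (2%): minimum heteroplasmy for calling a variant
  present when classifying germline vs tumor-specific;
* `abundance_dynamics` (1%): the more permissive presence cut used for
  the trend counts and the phylogeny matrix.

A variant key observed anywhere in a patient is **germline** if present
in normal at ≥ 2% with passing depth, **tumor-specific** if absent or
below threshold in normal (with passing depth at the position) and
present in ≥ 1 tumor sample, and **uninformative** if the normal sample
lacks passing depth at the position — a conservative rule: without
adequate normal coverage, tumor-only presence cannot be distinguished
from an uncovered germline variant.  Keys observed only below threshold
are dropped.  The three categories partition the observed keys.
Indels are classified and counted like SNVs but excluded from the
spectrum and the phylogeny matrix, which need single-base states.

Count tables evaluate presence per sample at a chosen threshold (1% by
default, matching how the reference cohort's printed counts were
tallied); multi-relapse patients collapse relapses by union, or the
first relapse can be selected.

## Trend statistics and their Monte Carlo null

Per patient, tumor-specific dynamics are summarized by the paired
difference D = R − P, and germline dynamics by the OLS slope of counts
over stages N, P, R coded at times 0, 1, 2 — with three equally spaced
points the slope is (R − N)/2, and the cohort statistic is the mean
over patients.  Time codes are a convention: affine recoding rescales
every slope by the same factor, so only equal spacing makes slope
magnitudes comparable across analyses.

The null distribution is simulated: each iteration replaces every
per-sample count by a continuous uniform draw over [min, max] of the
observed counts pooled across the stages entering the statistic (a
`per_role` mode bounds each stage by its own range instead), rebuilds
the per-patient statistics and records their mean; 10,000 iterations by
default.  The p-value uses the add-one estimator
(1 + #{|null| ≥ |obs|}) / (1 + iterations), never exactly zero for a
finite simulation.  Sidedness defaults to two-sided on |mean| and is
configurable.

**Calibration.**  Because the null range is *estimated* by the sample
min/max, the test is mildly anticonservative under its own null family:
with 16 patients and counts iid uniform, the type-I error at α = 0.05
is ≈ 6.5% rather than 5% (the pooled range of 32 draws underestimates
the true range, narrowing the null).  Under lighter-tailed no-trend
cohorts (e.g. Poisson counts) the same test is conservative (≈ 2–3%).
The calibration test freezes this protocol — 16 patients, iid uniform
counts, 999 iterations per test, 1,000 repetitions, master seed 0 —
and checks the rate stays within 5% ± 2 points.

## Phylogeny

Tumor samples of one patient (primary plus relapses; ≥ 3 samples) are
encoded as pseudo-sequences over the SNV sites passing the 1% threshold
in at least one sample: alt base where present, ref base otherwise.
This variant-site-only encoding is the most direct realization of
"variants passing the filter were used for reconstruction"; branch
lengths are therefore substitutions per *variant site*, a scale that
would shrink by ~L_sites/16569 if full pseudo-genomes were used
instead.  Sites where every sample carries the alt base differ from the
reference but not among samples; they are retained (they dilute p
uniformly) but cannot affect topology.

The p-distance denominator is the full site count — columns are
complete by construction because absence of a call is treated as
reference-covered (see above), so no pairwise-deletion mode is needed.
Distances are Jukes-Cantor, d = −(3/4)ln(1 − 4p/3), or Jukes-Cantor
with gamma rate variation among sites,
d = (3a/4)[(1 − 4p/3)^(−1/a) − 1], default shape a = 0.75; both are
undefined at p ≥ 3/4 (saturation error).

Trees are built by classic Saitou–Nei Neighbor-Joining: join the pair
minimizing Q_ij = (n−2)d_ij − r_i − r_j (ties broken toward the lowest
index pair, making output deterministic), three-point formulas at the
final trifurcation.  On additive matrices the reconstruction is exact.
Negative branch lengths, possible on non-additive input, are clamped to
zero with the deficit moved to the sibling branch (preserving path
lengths through the join); a flag allows them through unchanged.

Support values are plain site-bootstrap bipartition percentages:
resample site columns with replacement, rebuild distances and the NJ
tree, and score each interior branch of the full-data tree by the
fraction of replicates containing the same leaf bipartition.  Samples
are put in canonical (sorted) order before the bootstrap so supports do
not depend on input order.  Replicates whose distances saturate are
skipped and counted; a warning is attached when more than 10% are
skipped.  Note this is *not* the same statistic as an interior-branch
confidence test (the probability that an interior branch length
exceeds zero); we implement the bootstrap because it is the standard,
implementation-independent notion of clade support.  With uncorrected
p-distances (`model="p"`) degenerate matrices such as a single site are
also analyzable.

## Mutation spectrum

Single-base substitutions are assigned to the 96 pyrimidine-framed
categories X[R>A]Y (COSMIC convention): a purine-reference substitution
is reverse-complemented, change and flanks, into the pyrimidine frame,
pooling the two strands of the circular genome — the natural choice
when no strand convention is given for mtDNA.  Each bin's raw count is
divided by the reference's pooled context frequency
freq(XRY) + freq(revcomp(XRY)) and the 96 rates are rescaled to sum to
100%, yielding a per-opportunity spectrum insensitive to the genome's
base composition.  Division (rather than, say, log-subtraction) is the
standard normalization of signature analysis.  Variants are pooled
across patients per group — "present in primary" and "present in any
relapse", a variant in both contributing to both — and groups are
compared by cosine similarity plus per-6-class aggregates; no
hypothesis test is attached, as stability is a descriptive claim.

## Synthetic cohorts

`simulate_cohort` generates patients with three variant populations:

* **germline** — Poisson(112) per patient, allele fraction uniform on
  [0.30, 0.95] in normal; at each stage transition (N→P, P→each R) a
  variant drops below detection with probability 0.15 (Markov loss:
  lost at P means absent from relapses), reproducing the observed
  germline decline;
* **tumor-specific, primary** — Poisson(3) arising in P, each carried
  to a relapse with probability 0.5;
* **tumor-specific, relapse** — Poisson(8) gained privately per
  relapse, so relapses carry more tumor-specific variants than
  primaries (means ≈ 3 in P vs ≈ 9.5 in R, the scale of the reference
  cohort whose per-tumor mean is 6.3).

Tumor-specific allele fractions are uniform on [0.04, 0.25] (low
heteroplasmy, as observed for somatic mt variants); per-sample
fractions get N(0, 0.01) jitter and are clipped away from the 2%
threshold so ground truth is unambiguous at default filters.  Depth is
Poisson with mean 212 (the reference cohort's mean coverage); substitution
types are drawn from a 96-bin weight vector, by default
replication-type (C>T and T>C carry 35% each, transversion classes
7.5% each, uniform within class), and positions are drawn uniformly
among genome positions whose context matches the drawn bin on either
strand (position retries on key collision keep the realized bin
distribution multinomial).  `simulate_multirelapse` adds two planted
relapse lineages with mutually exclusive shared variants
(Poisson(30) per lineage) plus per-relapse private noise (Poisson(5)),
recording the true lineage split for tree validation.

What the generator does *not* emulate: genetic drift as a continuous
AF random walk (loss is all-or-none), read-level noise and strand
bias, NUMT artifacts, site-specific mutability, or linkage between
variants on mtDNA molecules.  Passing tests therefore demonstrate the
*pipeline's* correctness on data with known structure, not robustness
to every artifact of real sequencing data.

A full-size synthetic circular reference (16,569 bp, human-mtDNA-like
base composition, seeded) stands in for a real mt genome wherever one
is needed; any single-record FASTA over {A,C,G,T,N} can be supplied
instead.

## Numerical and interface choices

* Monte Carlo and simulation RNG is numpy's PCG64 (`default_rng`),
  seeded explicitly; every report records its seed and a hash of the
  effective configuration, and artifacts contain no timestamps so
  identical runs are byte-identical.
* The add-one p-value bounds estimates away from 0; with k iterations
  the smallest reportable p is 1/(k+1).
* Table dialects: comma- or tab-separated with mandatory header
  (sniffed); minimal single-sample VCF with AF/DP in INFO or FORMAT is
  accepted.  Malformed rows are reported with their line number.
* Problem sizes in the test-suite and acceptance script (16–100
  simulated patients, 1,000 bootstrap replicates, 1,000 calibration
  repetitions, 10,000-iteration tests) were chosen to keep Monte Carlo
  error well below the asserted margins while remaining quick to run.

## Known limitations

* Classification trusts the caller's per-sample tables; systematic
  false negatives in the normal sample masquerade as tumor-specific
  variants (the uninformative rule only catches *reported* low-depth
  positions).
* The Monte Carlo trend test's uniform-range null is a heuristic; its
  type-I error depends on the true count distribution (see
  Calibration above), so p-values near 0.05 should be read cautiously.
* Branch lengths from variant-site-only matrices are not comparable
  across patients with different site counts.
* The spectrum normalization assumes the reference composition is the
  mutational opportunity; selection and transcription/replication
  asymmetries are not modeled.
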