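# Methods

This note documents the statistical procedures `protempo` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Data model

The shared currency is the feature-by-sample `AbundanceMatrix` with a
per-sample metadata sheet (species, cell line, ordered developmental stage,
replicate, assay) and a `scale` tag, either `raw` (strictly positive
intensities or counts) or `log2_ratio` (log2 fold change against a stated
baseline). Operations declare which scale they accept and refuse the other,
which also guards against normalizing twice. Missing values are explicit
(`NA`/empty on disk, NaN in memory) and are never coerced to zero: zeros in
raw matrices are treated as non-detections and converted to missing before
any log transform.

## Normalization and merging

Raw abundances are normalized per feature to the geometric mean over a
sample group (by default the species): `log2(x / geomean(x))`, i.e. the log2
values are centred per feature within the group. The geometric mean runs
over all of the group's samples (all stages × replicates), complete-case: a
feature missing any value in a group is dropped from that group with a
warning. Cross-species merging joins two normalized matrices over a
one-to-one ortholog map (bijectivity is enforced), indexes the result by the
first species' IDs, and keeps complete cases only — no imputation, matching
a design in which a protein must be quantified in every retained sample to
enter the correlation analysis. Isoform trimming keeps accessions without a
`-<integer>` suffix; network edges touching removed nodes are removed.

Gene-set collections (GMT, with the source category in the description
field) are filtered before use: any set must have more than two detected
members; GO sets must additionally contain at most 150 genes in total, which
screens out uninformatively broad terms. Each retained set records its
detected subset.

## Co-regulation network

Pearson r is computed for all C(n, 2) unordered feature pairs in blocks
(`O(block² + features × samples)` peak memory; the all-pairs sweep over
~6,300 features — 19.6 M pairs — never materializes a per-pair metadata
table). Raw p-values use the two-sided t transform of r with n − 2 df.
Benjamini–Hochberg adjustment runs over the **full** pair universe, not only
pairs passing the r gate; an edge requires both |r| ≥ `r_min` (default
0.95) and adjusted p < `alpha` (default 0.01). Pairs with a zero-variance
feature are emitted with undefined r and excluded from the family.

The permutation null independently permutes each feature's sample vector,
draws `n_pairs` (default 50,000) random pairs without replacement, and
repeats for `n_shuffles` (default 10) rounds. It is a diagnostic — a
distributional contrast to the observed r histogram and an empirical-FDR
estimate for the r gate — while the parametric p gates edges: only the
parametric route yields a per-pair p for all 19.6 M pairs at realistic cost.
With few sampled conditions the observed r distribution is strongly bimodal
and the null is not; that contrast is the point of the plot.

Sample axis: correlations default to replicate-level columns; stage-mean
columns are available via the matrix helpers. Edge ordering is canonical
(lexicographic on feature IDs). Annotation enrichment for a category is the
fraction of observed (by default positive) edges annotated — both endpoints
sharing a set of that category, or the pair appearing in a PPI table —
divided by the annotated fraction among **all** C(|nodes|, 2) pairs of
network nodes; an expected fraction of zero makes the ratio undefined (NaN,
logged). Mean set correlation averages r over all detected member pairs, not
only significant edges, and is undefined below two detected members.

## Cooperative proteins

For each (candidate, module) pair over the sign-selected edge set (positive
edges by default — cooperative relationships are co-regulation, and the
`all` option is one config switch away):

* a — edges linking the candidate to module members;
* b — edges touching the module but not the candidate, **including**
  intra-module edges, which preserves the partition a+b+c+d = |E| (asserted
  on every run);
* c — edges touching the candidate but not the module;
* d — edges touching neither.

Significance is the one-sided (enrichment) Fisher exact test, computed as
the hypergeometric tail with fixed margins; a = 0 gives p = 1 identically,
so restricting candidates to first-degree neighbours of the module would
change nothing. BH adjustment pools all (candidate, module) tests into one
family. Ranking is by adjusted p, ties broken by larger a, then candidate
ID. Modules need at least 3 members in the network; smaller ones are
skipped and logged. Withheld-member validation reruns the test with part of
a complex removed and reports the withheld members' ranks. Shared
cooperativity is the Jaccard coefficient between modules' significant
cooperative sets, clustered with Euclidean distance and average linkage.

## Differential abundance and clustering

Between two stages, fold change is `log2(mean_b / mean_a)` of linear means
(raw scale) or the difference of log2 means (ratio scale); p-values come
from a two-sided two-sample Student t across replicates (Welch via config),
BH-adjusted over all tested features; a feature is differential when
|fold change| > 2 and adjusted p < 0.05 (both configurable). Identical
replicate values in both stages yield p = 1 rather than an undefined t.
Temporal clustering z-scores per-feature stage-mean profiles and cuts an
average-linkage hierarchy over correlation distances (1 − r) into k = 10
clusters by default; the distance/linkage/k are configuration, not claims —
the correlation metric matches the co-regulation framing, and constant
profiles are placed at maximal distance. Gene-set enrichment of a selection
against a background uses the one-sided hypergeometric tail with the
background as universe, BH across sets.

## RNA–protein discordance

Both assays are reduced to log2 ratios against their own per-species
geometric-mean baseline (RNA counts first get a pseudocount of 1 and a
transcripts-per-million scaling), making the per-stage fold changes
comparable; replicate means are taken within assay before the ratio, so
unbalanced replication (3 protein vs 2 RNA replicates) needs no weighting.
Discordance per gene and stage is D = protein FC − RNA FC; |D| ≥ 1 (one
two-fold unit) classifies protein-abundant vs RNA-abundant genes. D is
antisymmetric under exchanging the assays and zero when the fold changes
agree.

Two complex-level statistics are reported side by side, neither privileged:
the median per-gene RNA–protein correlation across members, and the median
per-stage discordance across members — the field uses both framings, and
they answer different questions. Complexes need more than two detected
members (medians of pairs are averages, not medians). The stage-transition
test compares, per complex member, the protein and RNA fold changes across a
transition and tests the paired member-wise differences against zero
(two-sided paired t by default, unpaired optional), BH across complexes; an
all-zero difference vector short-circuits to p = 1, and a zero-variance
non-zero shift to p = 0 (the noiseless planted limit). TF-target analysis
retains annotated targets whose transcript condition-mean profile correlates
with the TF's protein profile at r ≥ 0.9 and labels each with its
maximum-abundance stage.

## Phosphosites and kinase activity

Site log2 ratios are corrected by subtracting the host protein's log2 ratio
per sample (matched on cell line × stage × replicate when the assays use
separate sheets); sites with unquantified hosts are retained unnormalized
and flagged. Multiple peptides mapping to one (protein, residue, position)
are collapsed by median first. KSEA follows the published z-score: with m
mapped substrate sites (m ≥ 2 by default), z = (s̄ − p̄)√m / δ, where p̄ and
δ are the mean and sample (n−1) standard deviation of all site values in the
column — a sample, or a stage contrast (mean difference) when contrasts are
requested; both modes are provided since activity can be read per timepoint
or per transition. The score is invariant to adding a constant to all site
values. The kinase–substrate network correlates each annotated kinase's
profile (its protein abundance row by default; a KSEA z-series can be
substituted) with each of its substrate sites' profiles and keeps
|r| ≥ 0.5, dropping constant profiles (undefined r).

## Synthetic data and what passing tests mean

The generator emulates the sampling design of a stage-resolved gastruloid
study: 3 stages (primed → early → late) × 3 replicates × 2 cell-line groups
for proteins and phosphosites, 2 replicates for RNA (forcing downstream code
to handle unbalanced replication). All noise is Gaussian on the log2 scale;
replicates share a gene's stage profile and get i.i.d. replicate noise
(0.1 log2 by default, emulating tight replicate grouping); raw values are
`2^(log2 profile) ×` a random per-gene base abundance. All randomness flows
through one seeded PCG64 generator, so equal configs give bit-identical
matrices across platforms.

Planted structure, all recorded as ground truth exactly as realized:

* two 10-protein modules with stage profiles (0, 1, 2) and (0, −1, −2) log2
  units and 0.1 within-module sd (each member's profile is the module
  profile plus a per-gene, per-stage perturbation shared across replicates);
* one cooperative satellite per module at correlation strength 1.0, sd 0.05;
* six background co-regulation clusters of six genes whose profile
  directions are spread 40–140° from the module axis in the 2-D centred
  profile space of a 3-stage design. These exist because a real
  proteome-wide network contains abundant structure beyond any one module
  under test; without them essentially every edge touches the tested module
  and the Fisher contrast has no power.
* 50 background singletons with low-amplitude profiles (0.3 log2 sd) whose
  directions are rejection-sampled outside a 25° cone around each module
  axis. With only three stages, centred profiles live in a plane and two
  random high-amplitude profiles are frequently near-collinear — a singleton
  aligned with a module axis would be observationally indistinguishable from
  a planted satellite, and the "background" label would be false. The 25°
  margin sits outside the ±18.2° cone that the |r| ≥ 0.95 gate defines, and
  the low amplitude attenuates sample-level correlations below the gate even
  within the allowed directions.
* per-gene RNA profiles: concordance multiplier × protein profile −
  discordance offset + noise. The discordance statistic is invariant to
  per-gene constants, so any realizable offset vector sums to zero across
  stages; configured offsets are therefore centred across stages and the
  realized (centred) offsets are what the ground truth records. An offset
  vector that already sums to zero is planted exactly.
* phosphosites riding on randomly chosen host proteins' profiles plus a
  kinase activity profile: one active kinase (profile (0, 1, 2)), one null
  kinase, 10 substrate sites each, plus 40 background sites.

What the generator does **not** emulate: missingness mechanisms,
peptide-level effects, compositional TMT artefacts, count noise in RNA
(synthetic RNA is abundance-scale, which is why the recovery analyses
normalize it directly rather than via the TPM step — column-sum scaling on
a small compositional panel introduces a per-stage shift that is a property
of TPM, not of the estimator), batch effects, or cell-type mixtures.
Passing the recovery suite therefore demonstrates that the estimators
recover the structures they target at realistic noise levels and
replication — not that real data meet these assumptions.

Recovery at these conditions (20 seeds; reproduced by
`scripts/acceptance.py`): pooled within-module edge recall ≈ 0.99 at the
default network gate (individual seeds can dip to ≈ 0.93 when a member
pair's within-module noise pushes its r below 0.95 — a property of the
planted conditions, not of the estimator), zero cross-module edges among
the top-|truth| positive edges, every satellite significant and rank 1 for
its module, no background protein ever significant, discordance-offset RMSE
≈ 0.05 log2 units, and the active kinase top-ranked by KSEA z in every
seed.

## Numerical choices

* BH is implemented once (`stats.bh_adjust`) as the step-up procedure with
  NaN (untested) entries excluded from the family size; it is cross-checked
  against statsmodels in the test suite.
* One-sided Fisher p is the hypergeometric survival function with fixed
  margins (exact, vectorized); cross-checked against explicit enumeration
  and `scipy.stats.fisher_exact`.
* |r| is clipped to 1 before the t transform; |r| = 1 maps to p = 0.
* Correlation-distance clustering assigns constant (zero-variance) profiles
  distance 2.0 from everything rather than propagating NaN.
* Degenerate t-tests: identical groups give p = 1 (no evidence), a
  zero-variance non-zero paired shift gives p = 0 (the noiseless limit).
* Tie-breaks are deterministic everywhere: canonical lexicographic edge
  ordering; cooperativity ranking by (p_adj, −a, candidate ID); mergesort
  for all stable sorts.

## Known limitations

* The parametric per-pair p assumes approximate bivariate normality of the
  log2 profiles; with few samples the r gate, not the p gate, does most of
  the filtering (by design).
* The permutation null is diagnostic only; it is not used to calibrate the
  edge p-values.
* Complex-level discordance tests treat members as independent, which
  understates within-complex correlation; BH across complexes is a
  pragmatic, not exact, error control.
* The KSEA z treats substrate sites as exchangeable draws from the global
  site distribution; shared-host sites violate independence mildly.
* No batch correction, imputation, count-model shrinkage for RNA, or
  peptide-to-protein roll-up — inputs are assumed to be quantified matrices.
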