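# Methods

This note documents the models and procedures implemented in `refselect`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Problem setting

Read-depth CNV calling from exome data compares each sample's per-target
coverage with the coverage expected under the diploid assumption. The
expectation is estimated from a *reference sample set*: other samples whose
technical coverage profile resembles the query's. In cohorts aggregated
from several sequencing centres or capture designs, coverage profiles
cluster by design; a panel that mixes designs misestimates the expected
depth target-by-target, which surfaces as false CNV calls (concentrated in
short events, where one or two biased targets suffice) and as lost
sensitivity. `refselect` implements and compares four panel-construction
strategies and the diagnostics needed to choose between them.

## Quality control (`depthio`)

Targets are removed when their median raw depth across all cohort samples
is below 20 or above 4000, their length is below 20 bp or above 2000 bp,
their mappability is below 0.9, or their GC fraction is below 0.20 or above
0.80. All bounds are strict, so a value sitting exactly on a threshold is
retained. Medians use the standard even-count midpoint convention. QC
operates on raw counts, before any normalization, and never touches
samples; it is idempotent. Coordinates are 0-based half-open (BED
convention) throughout, so lengths are simply `end − start`.

## Similarity, embedding and selection (`selection`)

Sample similarity is the Pearson correlation *r* of raw QC-passed depth
profiles (columns of the matrix). No log transform is applied by default:
depth is the quantity whose technical covariation identifies a shared
capture design, and correlation is already scale-invariant. A sample with
zero variance across targets has no defined correlation and is rejected by
name.

Distances are *d* = 1 − *r*. For clustering and visualisation the cohort is
embedded by classical (Torgerson) multidimensional scaling: double-centre
−D²/2, eigendecompose, and keep the top *m* positive eigenpairs with
coordinates scaled by the square root of the eigenvalue. The default
*m* = min(10, S−1) retains the batch structure of realistic cohorts with
room to spare while keeping k-means cheap; *m* is configurable, and the
embedding is truncated with a warning when *d* is not Euclidean-embeddable
in *m* dimensions (correlation distances often have a few negative
eigenvalues; they carry no usable geometry).

Strategies:

- `all`: every other sample, cohort order.
- `random(size, seed)`: an independent uniform draw without replacement per
  sample. The draw is per sample (each sample gets its own panel), which is
  also why the workflow charges it one normalization context per sample.
- `knn(k)`: the *k* most-correlated other samples, ordered by descending
  correlation with exact ties broken by ascending sample ID. The tie rule
  makes selection deterministic and the k-panel monotone in *k*.
- `kmeans(k, seed)`: Lloyd's k-means (k-means++ initialisation, 10
  restarts, best within-cluster sum of squares kept) on the MDS
  coordinates; a sample's panel is its cluster minus itself. Clustering on
  the embedding rather than on raw T-dimensional count vectors makes the
  correlation metric — not Euclidean count distance, which is dominated by
  library size — govern the partition. A singleton cluster leaves its
  sample without a panel; downstream calling skips such samples with a
  recorded warning.

With k = 1, `kmeans` degenerates to `all`; `knn` with k = S−1 likewise
equals `all` as a set. These equivalences are asserted in the test suite.

## Choosing the number of groups (`clustqc`)

Three internal validation indices are computed on the same embedding that
k-means clusters, so one metric governs both the partition and its
assessment: the Dunn index (minimum inter-cluster point distance over
maximum intra-cluster diameter; higher is better), mean silhouette width
(higher is better; singleton-cluster points score 0), and the
Davies–Bouldin index (mean worst-pair scatter-to-separation ratio; *lower*
is better — despite occasionally being described alongside the other two as
"higher is better", its standard definition is a minimisation criterion,
and that definition is used here). `sweep_k` scores each candidate *k* and
recommends by a 2-of-3 vote: each index nominates its best *k* (per-index
ties to the smallest k); a *k* with two or more votes wins, otherwise the
smallest nominated *k* is returned — a deterministic stand-in for reading
the three curves by eye, biased deliberately toward fewer groups because
each extra group shrinks every panel.

Degenerate cases raise rather than return sentinel values: Dunn with all
clusters singleton, silhouette with one cluster, Davies–Bouldin with
coincident centroids. Inside `sweep_k`, an undefined Dunn value is recorded
as 0 so a single pathological *k* cannot abort a sweep.

## The plumbing caller (`mincall`)

The caller exists so that panel choice can be measured end to end; it is
deliberately minimal and fully parameterised, and no claim made by this
package concerns calling algorithmics. Per query:

1. **Expected profile**: the per-target median depth over the panel,
   rescaled by s = median(observed/expected over targets with positive
   expectation), which absorbs library size.
2. **Signal**: r_j = log2((x_j + 0.5) / (e_j + 0.5)); the 0.5 pseudocount
   keeps ratios finite at zero depth.
3. **Segmentation**: per chromosome, Viterbi decoding of a 3-state Gaussian
   HMM with state means −1 (copy 1), 0 (copy 2) and log2(3/2) ≈ +0.585
   (copy 3) — single-copy-change expectations on a diploid background —
   shared switch probability 1e−4 per off-diagonal transition, and an
   initial distribution equal to the neutral state's transition row.
   Maximal runs of non-neutral states become DEL/DUP calls spanning first
   to last target of the run.

The shared emission standard deviation is estimated robustly as
1.4826 × MAD of the profile, floored at 0.05 (so noise-free profiles remain
decodable) and capped at 0.25 by default (`CallerParams.sd_cap`, settable
to `None`). The cap is a modelling choice worth spelling out: an unbounded
MAD estimate silently widens the emission model until it swallows whatever
mismatch the reference panel introduced, making a bad panel look safe
(no calls, perfect precision, terrible sensitivity). Production read-depth
callers behave differently — their Poisson/negative-binomial likelihoods
tie the tolerated noise to sequencing depth — so panel mismatch shows up in
their output as false calls. The cap reproduces that behaviour: 0.25 is a
generous log2-ratio noise ceiling for ~150× exome coverage (counting noise
alone contributes ≈ 0.19 at the simulator's default depth and dispersion),
so within-design panels sit below it while cross-design mismatch exceeds
it and surfaces in the calls, where the benchmarking can see it.

## Benchmarking (`evalcnv`)

A call matches a gold variant iff same sample, same type, and reciprocal
overlap ≥ 0.5 (both `min_recip_overlap` and an any-overlap mode are
configurable — published benchmarks differ here, so the rule is explicit
and reported). Matching is greedy 1-to-1 in descending reciprocal overlap;
on sets whose gold variants are non-overlapping this attains the optimum
(the test suite checks it against exhaustive maximum matching). TP are
matched gold variants, FN unmatched gold, FP unmatched calls.

Strata: rare iff cohort frequency ≤ 0.05 (boundary inclusive); short iff
the event overlaps 1–2 QC-passed targets, long iff ≥ 3, making the classes
a partition (three-exon events are classified long). TP and FN inherit the
gold variant's frequency and span; an FP has no gold annotation, so its
frequency is the fraction of cohort samples carrying an overlapping
same-type call and its span is its own exon count. An event overlapping
zero retained targets cannot be span-classified and is excluded from the
strata with a warning (it still counts in the overall row). Precision,
sensitivity and F1 are reported as NaN when their denominators are zero;
true negatives are not reported, being ill-defined for interval events.

## Synthetic cohorts (`simcohort`)

The generator emulates the features of a multi-centre exome cohort that
matter for panel selection, and only those:

    x_ij ~ NegBin(mean = L_i · t_j · B_{b(i),j} · c_ij / 2,  size = r)

- t_j: per-target efficiency = log-normal baseline (sd 0.25) × a quadratic
  GC-bias curve exp(0.3·(gc−0.5) − 2·(gc−0.5)²), times a mean depth of
  150×;
- B: per-batch, per-target log-normal capture effect (sd 0.3 by default),
  shared by every sample of a batch — this is what makes samples cluster by
  design;
- L_i: per-sample library scale, uniform on [0.8, 1.2];
- c_ij: integer copy number, 2 outside events; injected deletions are
  heterozygous (c = 1; homozygous optional) and duplications single-copy
  (c = 3);
- r = 100 gives mild overdispersion over Poisson (`noise` may also be
  `"poisson"` or `"none"`, the latter writing rounded means for exact
  caller tests).

Defaults — 60 samples, 3 batches, 400 targets, ten events in each
{rare, common} × {short, long} cell (~40 events, 60 % deletions), rare
carrier frequencies in (0, 0.05], common in (0.05, 0.30], short spans of
1–2 targets, long of 3–12 — describe a mid-sized multi-design cohort in
which all four strata are populated and both the batch structure and its
consequences are visible. Events are placed on disjoint contiguous target
runs (longest first, uniformly over feasible starts), carriers drawn
uniformly, and the exact events returned as a truth set whose realised
frequencies are carriers/S. Everything derives from a single seed;
identical configurations are bit-identical.

What the simulator does *not* model: read-level artefacts, positionally
correlated capture effects (batch effects are independent across targets),
mappability-driven signal (mappability is annotation only), sex chromosomes,
and overlapping or recurrent-boundary CNVs. Passing tests on these cohorts
therefore demonstrate that the selection machinery behaves as designed
under clean batch structure — not that any particular caller will achieve
these metrics on real data.

## Workflow and cost accounting (`workflow`)

The pipeline is fork-join: every sample is processed independently
(select → normalize → segment → call) and the per-sample call lists are
unioned without cross-sample merging, so results are invariant to
processing order and trivially parallelizable. Normalization contexts
(distinct expected-depth profiles) are counted per run: `all` builds one
cohort-median profile shared by all queries; `kmeans` builds one median
profile per non-singleton cluster, shared by its members; `knn` and
`random` build one per sample. For the shared contexts the profile median
includes the query itself — with more than a handful of members the median
is insensitive to one sample, and sharing is precisely what makes those
strategies cheap. The count, not wall-clock time, is the package's cost
statement: with S samples and k clusters, `kmeans` performs S/k times
fewer normalizations than `knn` at essentially equal accuracy.

## Problem sizes

The test suite and the acceptance script run entirely on simulated cohorts
of 20–60 samples with 100–400 targets, five seeds for the pooled strategy
comparison, and brute-force oracle instances of at most 12 elements —
sizes at which exhaustive enumeration (3^T Viterbi paths, all pairwise
distances, maximum bipartite matching) is exact and fast, which is what
makes the oracle checks meaningful.

## Known limitations

- The caller is a stand-in: its absolute precision/sensitivity numbers
  characterise the synthetic study, not any production tool.
- The FP frequency proxy (overlapping same-type calls in the cohort) can
  misclassify a recurrent artefact as common when only few samples show it.
- Correlation on raw counts can be dominated by a few very deep targets;
  `correlation_matrix(..., median_scale=True)` divides each target by its
  cohort-median depth first, which removes that leverage (per-sample
  scaling would change nothing, correlation being scale-invariant per
  profile). The default stays raw, keeping depth itself as the similarity
  signal.
- `random` draws an independent panel per sample; a single cohort-wide
  random panel would be cheaper (one context) but is not what per-sample
  selection means here.
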