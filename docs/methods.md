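# Methods

`cnvpd` analyses population differentiation of copy number variation
regions (CNVRs) from read-depth CNV calls, the setting being a multi-breed
cattle panel partitioned into four regional groups — Eurasian taurine
(EAT), Asian indicine (ASI), African taurine (AFT) and African humped
(AFH) cattle — optionally with an outgroup breed. This note documents the
model and procedure each stage implements, the defaults and why, what the
synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Coordinates and input conventions

All intervals are 0-based half-open internally. The CNVnator call table is
the only 1-based-inclusive dialect handled; conversion happens at the I/O
boundary and nowhere else. CNVnator emits four e-value columns; the filter
consumes `e-val1` (the primary t-test p-value) by default, configurable via
`eval_column` because call sets in the wild differ in which column their
authors filtered on. A `q0` of −1 (regions with no mapped reads) is clamped
to 1 so the mapping-quality filter removes such calls. Strand is ignored
throughout: CNVs are unstranded.

## Call filtering and CNVR construction

Calls survive when length > 1 kb, p-value < 0.001 and q0 < 0.5 — all
strict inequalities — and they lie on an autosome of the supplied genome
model. Two filtered calls belong to the same CNVR when their reciprocal
overlap, `min(ov/len(a), ov/len(b))`, is at least 0.5. Merging is
single-linkage by default: an edge between every qualifying pair,
connected components become regions, so a chain a–b–c merges even when a
and c themselves fall short of 50%. This matches the semantics of the
widely used CNV-overlap merging scripts; a stricter greedy clique mode
(every member must reciprocally overlap every other) is available via
`mode="clique"` for sensitivity analysis. A region's span is the union of
its members — the convention under which genome-coverage statistics are
reported. Deletions and duplications may share a region; the per-individual
type profile (deletion / duplication / mixed) is retained, since typed
membership inside shared regions is what downstream summaries need.

The recurrence filter keeps regions carried by at least three distinct
individuals (strictly more than two), the usual guard against private
false positives. The threshold is configurable because two-carrier
variants are commonly accepted in smaller panels.

Copy number of a carrier in a region is `2 ×` the length-weighted mean
normalized read depth of that individual's member calls; individuals
without a member call take the diploid-neutral baseline of exactly 2.0
with presence 0. Re-estimating depth from alignments is out of scope; an
externally genotyped matrix can be supplied instead and is validated
against the region and individual labels.

## V_ST

For two populations with copy-number vectors of sizes n_a and n_b,

    V_ST = (V_T − V_S) / V_T,

where V_T is the variance of the pooled vector and
V_S = (n_a·var_a + n_b·var_b)/(n_a + n_b) is the size-weighted average of
the within-population variances. Both variances use ddof = 1 (sample
variance), the conventional choice at breed-level sample sizes; the
estimator is exposed as a parameter since the statistic's definition does
not pin it down. V_ST is clamped to [0, 1]: the raw value can fall below 0
when V_S exceeds V_T (pure sampling noise) and is retained in the output
for transparency. V_T = 0 — every copy number identical — yields V_ST = 0,
not NaN: with no variance there is no differentiation signal to partition.
Populations of one are excluded upstream (a single individual has no
within-population variance).

V_ST is computed per CNVR for every unordered pair of populations, at
group level (the four regional groups) for the differentiation criterion
and at breed level for the mean-V_ST breed matrix, which is symmetric with
zero diagonal and is intended for WPGMA display clustering.

## Kruskal-Wallis

Across the four regional groups the tie-corrected Kruskal-Wallis statistic
is computed on midranks of the pooled copy numbers:

    H = [12/(N(N+1)) · Σ n_i (R̄_i − (N+1)/2)²] / [1 − Σ(t³−t)/(N³−N)],

with the p-value from the chi-square upper tail at k−1 degrees of freedom
(no exact small-sample p — the standard implementation's behaviour). The
default-fill convention makes ties pervasive (most non-carriers sit at
exactly 2.0), which is why the tie correction matters here. All
observations identical is not an error: H = 0, p = 1.

## Dual-criterion differentiation calls

The V_ST threshold is the 0.99 empirical quantile (linear interpolation
between order statistics) of the pooled distribution of all pairwise group
V_ST values — pooled, not per pair, because the analysis is summarised by
single global top-1% and top-0.1% cutoffs; a per-pair mode exists as an
option. A CNVR is called differentiated iff any of its pairwise V_ST
values reaches the top-1% threshold AND its Kruskal-Wallis p-value is
below 0.01. No multiple-testing correction is applied to the KW p-values
in this rule. Pair-level top-1% and top-0.1% class labels are attached to
the output.

Note an intrinsic property of the quantile rule: the top-1% budget is one
value per hundred (CNVR, pair) entries, so when the truly differentiated
fraction of loci times the number of elevated pairs per locus exceeds 1%,
the threshold moves into the signal and recall saturates below 1. The
generator's default effect profile (below) respects this geometry.

## Clustering with bootstrap support

Individuals are clustered on their 0/1 CNVR presence vectors (optionally
on the copy-number vectors) with correlation distance, 1 − Pearson r. A
zero-variance vector (an individual carrying nothing or everything) has no
defined correlation; its distance is fixed at 1, the uninformative value,
so such individuals remain placeable. Agglomeration is UPGMA by default,
WPGMA (McQuitty) as an option; both are implemented directly so that ties
on the minimum distance are broken deterministically by the
lexicographically smallest pair of cluster labels (a cluster is labelled
by its smallest leaf). The distance matrix is symmetrised bitwise on entry
because BLAS-computed correlation matrices can differ in the last ulp
across the diagonal, which would otherwise make exact tie detection
asymmetric.

Support values resample CNVR columns — the units of evidence for grouping
individuals — with replacement. For each scale r in {0.5, 0.6, …, 1.4}
(the customary multiscale default; 1.0 must be present) and each of
n_boot replicates, round(r·m) columns are drawn, the tree recomputed, and
each reference clade's occurrence counted. BP is the clade frequency at
r = 1.0, hence always a multiple of 1/n_boot. AU fits
z_r = −Φ⁻¹(BP_r) with the two-parameter model z(r) = v·√r + c/√r by
weighted least squares (weights n_boot·φ(z_r)²/(BP_r(1−BP_r)), the
inverse delta-method variance; an unweighted option exists) and reports
AU = 1 − Φ(v − c). Scales where BP_r is exactly 0 or 1 carry no
information about z and are dropped per clade; with fewer than two usable
scales the fit is flagged degenerate and AU falls back to BP — which also
yields the correct limits AU = 1 for a clade present in every replicate at
every scale and AU = 0 for one never seen. All resampling flows through a
single seeded generator, so same-seed runs are bit-identical.

Newick output carries the support pair as a quoted internal-node label
`'AU,BP'`, scaled by 100, which standard Newick readers accept.

## Enrichment

CNVR–feature overlaps (genes, QTL intervals) use an interval-tree index
with a 1 bp minimum overlap — the annotation criterion is any overlap, as
no overlap fraction is standard for gene-level annotation; the threshold
is configurable. Genes overlapping several CNVRs are assigned the CNVR
most significant in the Kruskal-Wallis test (smallest p, ties by larger H,
then lexicographic region id). Hypothetical / putative / predicted /
uncharacterized genes, pseudogenes and bare `LOC` identifiers are dropped
by configurable regular expressions before gene-level statistics.

Category representation (GO-style terms via a user-supplied term→gene
mapping, or QTL trait classes counted over QTL records) is tested with a
two-sided exact binomial test of the observed category count among
CNVR-overlapping features against the category's genome-wide proportion.
The two-sided p-value uses the minimum-likelihood convention: the sum of
all outcome probabilities not exceeding the observed outcome's
probability. Bonferroni multiplies by the number of categories tested and
caps at 1. An observation exactly at expectation reports p = 1 with
direction "over" and an explicit tie flag. Features may carry multiple
category labels, so category counts may sum to more than the number of
distinct features.

## Synthetic data generator

The generator emulates the post-calling layer of a whole-genome CNV
survey; it does not simulate reads, linkage between loci, or demographic
history. Defaults define the reference scenario used throughout the test
suite: 5 autosomes of 10 Mb; 4 groups × 5 breeds × 8 individuals (160
animals); 1000 CNVR loci of 5–20 kb placed disjointly with ≥1 kb gaps (so
distinct truth loci can never merge); 5% differentiated loci; latent copy
number per individual drawn Normal(group mean, cn_sd = 0.4) and clipped at
0; boundary jitter Normal(0, 100 bp) clipped at ±6σ; call dropout 0.9 for
individuals within 0.5 of copy number 2; ~2 false calls per individual,
which by default fail every filter (short, large p, high q0) — a knob lets
a fraction survive to exercise the recurrence filter.

Non-differentiated loci share one mean across groups, drawn from
{1, 3, 2} with probabilities {0.4, 0.4, 0.2}: whole-panel deletions and
duplications plus diploid loci whose sparse noise calls exercise the
dropout path. Differentiated loci follow a two-pole gradient: one group's
mean raised to 2 + g, another's lowered to max(0, 2 − g) with g ≥ 2, the
remaining groups diploid. This mirrors the gradient profiles real
differentiated loci show across these cattle groups (one strongly gained
population, one strongly reduced, intermediates near diploid) and gives
each locus a single dominant population pair with clearly weaker secondary
pairs — the regime in which the pooled top-1% rule can recover every
injected locus (50 dominant pair values fit inside the 60-value top-1%
budget of 6000 pooled values). Explicit per-group mean profiles can be
supplied instead via `effect_profiles`, including single-deviant-group
patterns; note that such patterns put three equally elevated pairs per
locus into the pool and recall against the top-1% rule then saturates
accordingly.

Emitted calls carry normalized read depth CN/2, deletion type below copy
number 2, log-uniform p-values in [1e−12, 1e−4] and q0 in [0, 0.4]. With
cn_sd = 0, jitter = 0, dropout = 0 and no false calls, the whole pipeline
is deterministic and recovers the truth exactly. Latent copy number is
continuous (the observable layer of read-depth genotyping is continuous);
an integer-state mode exists for stress tests.

What passing the synthetic checks does not show: robustness to breed
substructure, to genotyping error correlated across individuals
(e.g. reference bias in repeat-rich regions), to loci that overlap
partially rather than sharing boundaries up to jitter, or to missing
metadata — real call sets exercise those paths differently.

## Truth scoring

Called CNVRs are matched to differentiated truth loci by ≥50% reciprocal
overlap. Recall is the fraction of differentiated loci matched by at least
one called region; precision the fraction of called regions matching some
differentiated locus. An empty call set reports precision 1.0 with an
explicit `precision_defined = False` flag (no false positives were made),
and recall 0.

## Pipeline and problem sizes

`cnvpd run` executes the stages in dependency order from one JSON config,
writes every artifact with a SHA-256 digest into the run report, and is
byte-identical on rerun with the same config — stage timers go to the log,
never into the report. The report's counts are recomputable from the
artifacts alone (`cnvpd report`).

The test suite runs the reference scenario (160 individuals × 1000 loci)
across five seeds for the recovery and null-calibration checks, and uses
a 20-individual block-structured presence matrix at 1000 bootstrap
replicates for the clustering support check; end-to-end determinism is
exercised on a reduced scenario (32 individuals × 200 loci, 50 bootstrap
replicates) — sizes chosen to make the full suite comfortably quick on a
single core while keeping every statistical property at play.

## Known limitations

- Copy numbers for CNVR spans wider than an individual's calls use the
  length-weighted member-call mean; there is no re-genotyping over the full
  span from alignments.
- The clique merge mode is greedy (order-dependent within a sweep), not a
  maximum-clique partition; it is intended for sensitivity analysis only.
- AU p-values inherit the multiscale model's assumptions; for clades with
  BP near 0 or 1 at most scales the degenerate fallback (AU = BP) is
  reported with a flag rather than an extrapolated fit.
- The X/Y/MT chromosomes are excluded by design; the statistics assume
  diploid-neutral baseline 2.0.
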