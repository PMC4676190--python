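# Methods

This note records the models, rules and numerical choices behind
`srna-atlas`, in the order the pipeline runs them, together with the
assumptions each stage makes and what the synthetic tests do and do not
demonstrate.

## Coverage model

Read coverage is per-strand, per-base read depth: a read contributes to
every base it spans, not only its 5′ end, because boundaries of called
transcripts are delimited from the coverage profile and 5′-end counting
would bias them left. Paired-end mates are treated as independent
intervals unless the caller supplies fragment intervals; no
mapping-quality filtering, duplicate marking or multi-mapper reweighting
is applied — every supplied interval counts once. Libraries are pooled
by exact element-wise summation before discovery, maximising depth the
way discovery studies merge their mapping files. All internal
coordinates are 1-based inclusive; BED and bedGraph files are written
and read in their native 0-based half-open convention with the
conversion made exactly once at the IO boundary.

## Transcript calling

A candidate region is a maximal run of bases whose pooled depth is
*strictly greater* than the cutoff (default 100 reads/nt — "above" read
literally; the boundary behaviour is a documented parameter, not an
accident). Candidates are then post-processed:

1. **gap joining** (`max_join_gap`, default 5 nt): adjacent same-strand
   regions separated by a sub-threshold gap of at most this many bases
   are merged; one left-to-right pass reaches the fixed point, so the
   operation is idempotent;
2. **length filter** (`min_length`, default 50 nt): bona-fide bacterial
   sRNAs below ~50 nt are rare, and shorter runs are mostly threshold
   noise;
3. **intergenic restriction**: a region is kept only if it overlaps *no*
   annotated gene on *either* strand; partial overlaps discard the whole
   region rather than trimming it, because a trimmed boundary would be an
   artifact of the annotation rather than of the coverage. The
   strand-agnostic definition is deliberate: an intergenic region is a
   property of the genomic span, and candidate sRNAs flanked by genes on
   either strand are legitimate;
4. **sRNA/UTR classification**: manual curation by visual inspection is
   replaced with an explicit rule. A region is a UTR iff its gap to the
   nearest same-strand gene is at most `utr_max_gap` (default 10 nt —
   "no gap" with a small allowance for threshold jitter at the region
   edge), or the gap is at most 50 nt and the mean depth over the 20 nt
   of that gene's region-facing end is at least the region's mean depth
   divided by `utr_expression_ratio` (default 2.0 — "similar expression
   levels"). All thresholds are parameters of `CallerParams` and are
   recorded with every call.

Raising the cutoff can never increase the *total length* of called
bases, and the implementation is property-tested for that; the *number*
of regions is not monotone (a higher cutoff can split one region into
two across a dip), which is why no such claim is tested.

Whether the cutoff applies to strand-specific or strand-summed depth is
a flag (`sum_strands`, default strand-specific), since either convention
is defensible for stranded libraries.

**Detection floor.** A transcript already in the annotation counts as
detected when its cumulative MEV is at least 1 read/nt (ties detect);
transcripts below the floor are reported as transcribed-but-undetected
rather than dropped.

## Quantification

A read is counted for a call iff it overlaps the call by ≥ 1 nt on the
same strand; a read overlapping two calls is assigned to the one with
the larger overlap, ties to the leftmost. The rule is deliberately
simple and deterministic — fractional assignment would complicate the
count model without changing any downstream statistic materially at
these depths. The mean expression value MEV = reads / length (reads/nt)
is computed on raw counts, cumulative over all libraries and per
condition; because the per-condition reads partition the total, the
condition MEVs sum exactly to the cumulative MEV. MEV histograms use
left-closed bins <1, [1,10), [10,100), ≥100; length histograms use
25-nt bins over [0, 400) with an overflow bin.

## TMM normalization

For library *i* against the reference *r*, features with a zero count in
either library are dropped, and for the rest

    M_g = log2((y_gi/N_i)/(y_gr/N_r)),
    A_g = 1/2 · log2((y_gi/N_i)·(y_gr/N_r)),
    w_g = 1 / (1/y_gi − 1/N_i + 1/y_gr − 1/N_r),

the top and bottom 30 % by M and 5 % by A are trimmed (rank-based, both
trims applied jointly), and the factor is 2 to the power of the
w-weighted mean of the surviving M values. Factors are rescaled to
geometric mean 1. The automatic reference is the sample whose
upper-quartile relative abundance (75th percentile of counts divided by
library size) is closest to the mean of those quantities. The trim
fractions and weight formula are the published defaults of the
trimmed-mean-of-M-values method; the implementation reproduces the
reference R implementation (edgeR's `calcNormFactors(method="TMM")`) to
8+ decimals on random matrices, and one test runs that cross-check.
Degenerate inputs (no surviving features, all-equal ratios) yield factor
1 with a warning.

## Dispersion estimation

Counts are modelled as negative binomial with variance μ + φμ²; φ = 0 is
Poisson. With only a handful of replicates a likelihood fit per feature
is not worth its fragility, so φ is estimated by method of moments on
counts scaled to the reference effective library size: each feature and
replicated condition contributes its within-condition mean m and
variance v, and the common dispersion pools them as

    φ_common = max(0, Σ(v − m) / Σ(m² − v/n)),

where the denominator is the unbiased estimate of μ² (without the −v/n
correction the estimator is biased low by ~var/(nμ²)). Per-feature
estimates use the same formula per feature and are shrunk toward
φ_common with weight d/(d + n₀), where d is the feature's residual
degrees of freedom and n₀ = 10 prior replicates. With no replicated
condition at all, φ is fixed to 0 with a loud warning that p-values will
be anti-conservative under overdispersion.

**Dispersion used for testing.** `de_test` tests each feature at
max(φ_g, φ_common). With d = 4 residual df the raw moment estimate is
extremely noisy, and features whose estimate fluctuates *below* the
common value would be tested with too small a variance — exactly the
features most likely to be selected, a classic selection effect that
measurably inflates the empirical FDR (0.081 vs 0.053 at the default
simulation settings). Flooring at φ_common removes the anti-conservative
half of that noise while keeping genuinely overdispersed features
protected by their larger φ_g.

## Exact negative-binomial test

All contrasts are two-group, so no GLM machinery is used. Replicate
counts are scaled to the *reference sample's* effective library size
(factor × library size), summed within each group and rounded. The sum
of n i.i.d. NB(m, φ) variables is NB(nm, φ/n); conditioning on the
feature's total t, the p-value is the summed probability of all splits
whose conditional probability is at most that of the observed split
(two-sided by summed probabilities, which is well defined for the
asymmetric NB; "doubling the smaller tail" is not used). The group mean
under the null is estimated as t/(n_A + n_B). φ = 0 reduces exactly to
the conditional binomial test with success probability
n_A/(n_A + n_B), verified against rational-arithmetic enumeration for
all totals ≤ 30. A zero total gives p = 1.

Scaling to the reference's effective size (rather than to a geometric
mean of effective sizes) is what makes the pipeline exactly invariant to
pure depth changes: multiplying a non-reference sample's counts by a
constant changes its library size and cancels out of its scaled counts
identically, leaving every p- and q-value bit-identical (tested at
φ = 0 with factors held fixed). TMM's precision weights depend on
absolute counts, so *recomputed* factors shift by ~1e−4 under such a
perturbation; exact invariance therefore holds for given factors.
Fold changes are log2 ratios of normalized group means with a prior
count of 0.5 added to each group mean so empty groups stay finite.
Multiple testing uses Benjamini–Hochberg step-up q-values (via
statsmodels, property-tested against the brute-force definition);
direction is `ns` iff q ≥ α (default 0.05). Each contrast is normalized
and tested independently; no information is shared across contrasts.

## Comparative layer

The overlap matrix counts, for each condition pair, features significant
in both *with the same sign*; the diagonal holds per-condition DE
counts, and the relative matrix is row-normalized by the row condition's
diagonal. Row z-scores use the sample (ddof = 1) standard deviation —
the convention must be fixed for exact tests — and zero-variance rows
are dropped and reported. Hierarchical clustering uses the Pearson
correlation distance d = 1 − r with average linkage (the distance is the
field's convention for expression profiles; the linkage is a
declared choice), implemented as an explicit agglomeration with a
deterministic tie rule (smallest leaf index), cross-checked against both
a brute-force re-agglomeration and scipy. PCA is centered but not
scaled — expression profiles are already on a common log scale, and
scaling would up-weight flat features — and is computed on
replicate-averaged normalized log2(count + 1) expression; the
pseudocount is configurable. Pattern groups classify each feature by the
sign multiset of its significant conditions (up-only / down-only /
mixed, exhaustive and exclusive) with a selection flag requiring
significance in at least k conditions (default 4 in the CLI workflow)
and a maximum condition-specific MEV of at least 1.

Printed percentages round half away from zero to one decimal; molarity
conversions (1000·(g/L)/M; %v/v via 10·percent·density) round to the
nearest integer mM, and densities and molar masses are always
caller-supplied.

## Synthetic data

The generator emulates a bacterial sRNA-sequencing experiment at desk
scale: a single linear-placement chromosome (circularity is ignored for
placement — no origin-spanning features are generated), 20 default genes
of 400–1200 nt separated by 300–900 nt gaps, 15 planted intergenic
sRNAs and 5 planted UTRs of 50–300 nt. sRNAs keep ≥ 20 nt clearance to
flanking genes; UTRs abut their host gene's downstream end with gap 0 on
the same strand. Counts are NB with mean = base_mean × length ×
fold_change(condition) × library factor and dispersion φ (default 0.1);
base_mean defaults to Uniform(2, 6) reads/nt/sample, which with 6
samples and 50-nt reads yields pooled coverage plateaus of roughly
600–1800 reads/nt — comfortably above twice the calling cutoff, with the
threshold crossing inside the coverage ramp within ~10 nt of the true
edge. Reads are placed uniformly *within* each feature (features shorter
than a read yield feature-length reads), so coverage never bleeds across
feature boundaries and read counting can recover the simulated counts
exactly when background is off. Genes receive Poisson reads at 0.5
reads/nt/sample — enough for gene regions to exercise the intergenic
filter, low enough that UTR coverage never merges across the gene
boundary. Background transcription is Poisson at an expected depth of 1
read/nt per strand per sample over intergenic space; real data give no
number for this, so it is a free parameter chosen to exercise the
cutoff's specificity, not an inference about any study.

What the generator does *not* emulate: sequence content (no bases are
simulated), alignment and sequencing error, positional coverage biases
(5′/3′ ramps from library chemistry), rRNA contamination, operon
read-through, and overlapping gene structures. Passing recovery tests
therefore demonstrates the correctness of the calling logic under the
stated coverage model, not calling performance on real libraries, where
boundary noise and background are less well behaved.

## Problem sizes and determinism

Test and acceptance simulations use a 50 kb genome, 20 planted
transcripts, 2 × 3 libraries for discovery fixtures, and 2000-feature
3 vs 3 count experiments (20 seeds) for calibration — sizes at which
every statistical property under test has already stabilised while the
whole suite stays fast. All randomness flows through integer seeds via
numpy Generators; identical seeds give bit-identical outputs, and the
pipeline writes byte-identical tables on reruns of the same
configuration.

## Known limitations

Single-factor, two-group contrasts only (no batch covariates,
quasi-likelihood tests or trended dispersion); read-level counting (no
fragment model); no TSS mapping, terminator or promoter prediction, and
no conservation analysis — those are external-tool territory. The exact
test's empirical FDR at the default simulation settings is ~0.05–0.06
against a nominal 0.05, the usual behaviour of plug-in dispersion
estimates with three replicates.
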