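# Methods

## The audit model

The package treats a candidate expression signature as suspect of being a
handling artifact and asks two questions. First, *does the signature vary
across samples more than chance?* The per-sample signature fraction
`f_s = sum_{g in S} x_gs / sum_g x_gs` is a scale-free summary that works on
any non-negative layer (intensities, normalized counts). Its coefficient of
variation across samples is ranked inside a null distribution of B random
gene sets of the same size drawn uniformly without replacement from the
matrix genes, independently per iteration; the tie-aware centile
`100 * (#below + 0.5 * #ties) / B` is the audit statistic. Defaults
B = 10,000 and seed 123 are the reference configuration, as is a 78-gene
signature inside a 19,570-gene array universe. The CV uses the sample
(n−1) standard deviation; the centile gives ties half weight — neither
convention is forced by the statistic itself, so both are fixed here and
covered by oracle tests. Second, *where does the signature sit in a
contrast?* Preranked GSEA against a batch or age contrast localizes the
signature at the induced or repressed end of the ranking.

Assumptions: samples are exchangeable under the null (no structure beyond
what random same-size gene sets capture); signature genes are a small
fraction of the transcriptome, so the fraction denominator is effectively
exogenous; expression values are non-negative and complete.

## Bulk preparation

Genes with a mean count below the number of samples are dropped before any
signature work. Count normalization is median-of-ratios: reference genes are
those positive in every sample, each sample's factor is the median ratio to
the per-gene geometric mean, and factors are geometric-mean-centred so their
logs sum to zero (this makes renormalization a fixed point, which the tests
assert). There is deliberately no pseudo-reference fallback when no gene is
positive everywhere — for the dense bulk matrices this audits, that
situation signals a data problem rather than something to patch silently.
Microarray matrices are accepted as already normalized; probe-set collapse
strategy is the caller's choice (a max-expression-per-gene helper hook
exists, nothing automatic).

## Overlap statistics

The 2×2 overlap test holds both margins fixed and sums hypergeometric table
probabilities. Two-sidedness uses the minimum-likelihood definition (all
tables no more probable than the observed one), matching the convention of
the common exact-test implementations. The odds ratio is the sample OR
`ad/bc`; when any cell is zero, 0.5 is added to every cell
(Haldane–Anscombe) — only then, so non-degenerate tables report the plain
ratio. The conditional-MLE OR that some packages report is deliberately not
used. The combined score `-ln(p) * OR` (0 at p = 1) mirrors the familiar
combined metric of p values and odds ratios for over-representation
reports; exact reproduction of any web service's numbers is a non-goal.
Genes outside the declared universe are trimmed with a warning rather than
an error, since cross-platform symbol drift is routine.

## Preranked GSEA

The ranking metric is signal-to-noise with each group standard deviation
floored at `max(0.2 * |mean|, 0.2)`; log2 fold change and Welch t are
selectable, and fold change is the documented fallback for single-sample
groups. The running sum weights hits by `|score|^p / sum_hits |score|^p`
(p = 1 default) and misses by `1/(N - N_hits)`; the ES is the extremum of
largest magnitude with exact ties broken toward the positive extremum for
determinism. The leading edge is the hit genes at or before the extremum
(at or after, for negative ES). Significance uses a gene-label permutation
null (same-size random sets, n_perm = 1000 default): NES divides the ES by
the mean magnitude of same-sign null ES; nominal p is the add-one-smoothed
same-sign tail fraction; FDR q follows the standard sign-matched pooling of
null NES across sets, clipped at 1. Phenotype permutation is out of scope —
the contrasts this audits are small-n, where gene permutation is the
standard fallback. One consequence of the tie rule: negating every ranking
score negates the ES exactly *except* when the running profile is
magnitude-symmetric, where both orientations report the positive extremum;
and the permutation null is equal in distribution but not pointwise under
ranking reversal, so NES magnitudes agree only approximately under
negation.

## Module scores and phase calls

Per-cell module scores follow the expression-bin control convention: genes
are placed into equal-frequency bins of mean expression (ties split
deterministically by gene order), each signature gene draws `nctrl` control
genes from its bin — excluding signature genes when the bin offers
alternatives, with replacement when the pool is small — and the score is
the mean over signature genes minus the mean over pooled controls. Defaults
nbins = 24 and nctrl = 100 mirror the common single-cell convention. The
score is invariant to adding a per-cell constant (both means shift
equally), which the tests assert. Phase calling: both S and G2M scores
negative → G1, otherwise the larger score wins, an exact tie going to S.
The two-way classifier used for generic signature pairs has no neutral
class; ties go to the first label.

## Single-cell pipeline

QC exclusion rules (mitochondrial fraction > 6%, detected genes outside
2,000–9,000, transcripts outside 5,000–60,000, hashtag totals outside
20–400) fire strictly beyond the bounds, so boundary cells are kept; the
per-rule tally attributes each excluded cell to the first failed rule in
the fixed order mito → features → counts → hashtag. Mitochondrial genes are
matched by a configurable, case-insensitive id prefix (default `mt-`).
Demultiplexing is a transparent ratio rule (negative below a minimum total;
top hashtag when `top/(second+1)` is at least 3; doublet otherwise), not a
re-implementation of any published hashing classifier — assignments on real
data may differ marginally at the margins.

Differential expression is a per-gene two-sided Wilcoxon rank-sum test on
log-normalized (counts-per-10k, log1p) values, restricted to highly
variable genes (standardized dispersion within 20 mean-expression bins,
top 2,000 by default). The exact-enumeration path is used when
`n_a * n_b <= 200` and the pooled values are tie-free; otherwise the tie-
and continuity-corrected normal approximation (the two agree within 0.02
at n = 15 per group, which the tests check). The fold change is
`log2((mean expm1 + 1e-9) / (mean expm1 + 1e-9))` — a toolkit-default-style
definition, documented but not asserted to match any particular package.
DE runs are stratified by called phase (phases with under 3 cells in either
group are skipped with a warning). A gene is called "up" in a contrast when
at least one phase is significant (q < 0.05 by default) with positive fold
change and no phase is significantly opposite; conflicting genes are
dropped with a warning — the conflict rule is this package's choice. The
ice and ice+TP groups are pooled into one reference when their own DE is
near-empty, and the six-way intersection of the 37 °C and 37 °C+TP calls
feeds the gene-length comparison (group quartiles, two-sided Mann–Whitney
U, exact when `n_a * n_b <= 10,000` and tie-free).

## Synthetic cohorts

The bulk generator draws per-gene baseline log-intensities from
N(4, 1), multiplies IER genes by `ier_fold` in the stressed batch and aging
genes by `aging_fold` in aged samples, and adds log-normal measurement
noise (sd 0.25). Defaults: 2,000 genes, 12 samples in three batches,
78 IER genes at 2-fold, 100 aging genes at 1.5-fold.

The single-cell generator draws negative-binomial counts (gamma–Poisson,
theta = 2) with gamma(0.6, 5) gene means and log-normal per-cell size
factors (sd 0.3) for four conditions of 400 cells each. IER genes (50,
drawn with log-normal per-gene stress folds, median 4) are induced at 37 °C
and suppressed under triptolide; a disjoint set of TP-response genes
(50 at 3-fold) is induced only at 37 °C + TP — without them the 37 °C+TP-only
arm of the DEG intersection would be empty and the length comparison would
have no second group. Triptolide at 37 °C also thins counts binomially
(25% loss) and raises the mitochondrial fraction (13 `mt-` genes, baseline
2%, +1 percentage point). Cell-cycle structure uses 50 S and 50 G2M
markers boosted 10-fold in cells of the matching phase, with cycling
fractions 0.40 on ice and 0.15 at 37 °C; marker baselines come from a
moderately-expressed gamma(2, 2.5) because a usable marker list consists of
detectable genes — with weak, sparse markers the zero-threshold phase rule
miscalls a large share of G1 cells, which no real cycle-scoring workflow
exhibits. Hashtag counts are multinomial around a log-normal total
(median 150) concentrated on the true tag (2% noise); doublets (5%) are
sums of two random cells carrying both hashtags. IER gene lengths are
log-normal with median 2 kb versus 20 kb background (sd 0.6). All
generators are pure functions of (config, seed).

What the generators do *not* emulate: ambient RNA, batch chemistry,
empirical mean–variance trends fitted to any particular dataset, distinct
doublet library sizes, or partial transcription inhibition. Passing
recovery tests therefore demonstrate that the statistics detect the
structure they target at realistic effect sizes and depths — not that any
particular real dataset contains that structure.

## Problem sizes and numerical choices

The test suite and the reproduction script run the audits at desk scale:
2,000-gene compendia, 200 random signatures at B = 1,000 for calibration
(the planted-effect audit uses the full B = 10,000), 1,000 GSEA
permutations, and 4 × 400 cells for the single-cell experiment — sizes
chosen so the full suite completes in well under a minute of compute per
stage while leaving every statistic far from its detection threshold.
Internal coordinates are 0-based (MatrixMarket's 1-based indices convert at
the boundary); gene symbols match case-sensitively; equal-frequency bins
split ties by position; the bootstrap null is drawn in chunks for memory
locality without changing the stream of any fixed seed. Degenerate inputs
fail loudly by design: zero-total samples, empty gene sets, signatures
spanning the whole gene list and single-hashtag experiments are errors, not
silent defaults.

## Known limitations

The two-sided p of the overlap test commits to the minimum-likelihood
definition; doubling-based definitions differ on asymmetric tables. The
permutation FDR can report exactly 0 when no pooled null NES exceeds an
observed NES; with 1,000 permutations that is a statement about resolution,
not certainty. The bootstrap centile saturates at 100 and cannot rank
signatures beyond the null's reach. The demultiplexer's ratio rule has no
model of ambient hashtag background beyond the additive +1. Microarray
probe-set collapse and cross-species symbol mapping are out of scope.
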