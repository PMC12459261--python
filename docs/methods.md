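# Methods

## Scope and model

`scessentials` treats gene essentiality as an expression phenotype in
single-cell atlases: an essential gene should be detected in essentially
every sequencing platform and cell type, show low biological variability,
sit in densely co-expressed neighbourhoods, lack cell-type-marker evidence,
and keep a stable expression profile through ageing. The package implements
the full chain from raw genes × cells counts to those statements, plus a
generator of synthetic atlases with planted truth so each stage can be
validated without external data.

## Filtering

Detectability: a gene passes a group (platform or cell type) when at least
`min_nonzero = 3` of the group's cells have a nonzero count. The phrase
"three nonzero reads" is interpreted as three *cells* with nonzero counts —
cells are the common currency of the per-cell-type clause, and a read-level
threshold would be platform-depth dependent. The threshold is configurable.

Stability: per cell type, genes whose biological residual (below) exceeds
the `q = 0.90` quantile of **all** genes' residuals in that cell type are
flagged; a gene is removed when flagged in more than `min_frac_celltypes =
0.5` of the cell types where it is measured. Both knobs are configurable and
logged in the filter trace; the quantile reference is the whole atlas, not
the candidate list, so a uniformly stable candidate set is not decimated by
its own internal ranking. The stability filter acts on the tissue atlas's
residuals (the benchmark atlas contributes the platform-detectability stage
only).

## Normalisation and variance decomposition

SCTransform-style Pearson residuals are deliberately not used; the
downstream statistics (quantile ranks of residuals, rank correlations) need
only monotone, deterministic normalisation. Counts are scaled per cell to
the median library size and log2(x+1) transformed. Cells with zero totals
are an input error, reported by id.

Per cell type and per donor block (blocks with < 2 cells are dropped with a
warning), each gene's mean and variance of log-normalised expression are
computed; the mean–variance trend is a sliding median of variance over
genes ordered by mean, window 51 genes (odd, clamped to full width at the
edges so the trend is the global median when there are fewer genes than the
window). The biological residual is total − trend; negative values mean
more stable than expected at that expression level. Blocks combine with
weights n_b − 1 (variance degrees of freedom); the combined residual is
computed as combined-total minus combined-trend so the identity
`residual = total − trend` holds exactly in floating point. A sliding
median rather than a loess fit keeps the estimator deterministic and
reproducible by a brute-force oracle; the window size trades smoothness for
locality and is exposed.

## Pair correlation

Spearman's ρ is the Pearson correlation of midranks; constant vectors have
undefined ρ and their pairs are skipped. Ties get midranks (not random
jitter) so results are deterministic. The permutation null is the
distribution of ρ between a fixed rank vector and random permutations,
shared by all pairs with the same cell count; when n! ≤ 5040 (n ≤ 7) the
null is enumerated exhaustively and p = #{|ρ_null| ≥ |ρ|}/n! is exact,
otherwise p = (1 + #{|ρ_null| ≥ |ρ|})/(iters + 1) with `iters = 10000`
(p floor 1/(iters+1)). Counting uses a 10⁻¹² tolerance on the comparison so
float roundoff at exactly-tied ρ values cannot flip a count; null values at
enumerable n are spaced ≥ ~0.018 apart, so the guard changes nothing else.
BH correction is applied across all pairs within one cell type (the
correction universe is a configuration choice; per-cell-type matches the
per-cell-type reporting downstream).

The expression filter retains genes with nonzero counts in at least 90% of
the cell type's cells. The source description of this filter is
self-contradictory (its wording excludes exactly the well-measured genes its
own rationale says to keep); the implemented reading — *require* ≥ 90%
nonzero — follows the rationale that excess zeroes corrupt rank
correlations. The threshold and direction are configurable.

Top pairs: significant pairs sorted by |ρ| (ties by pair id), keep at most
100; a cell type with ≤ 10 significant pairs is dropped. Counts of
significant pairs are compared between lists with a pooled two-proportion
z-test without continuity correction; correlation levels are compared with
the tie-corrected Kruskal–Wallis test (all-identical input returns H = 0,
p = 1 rather than an error).

## Networks

Edges are pairs with raw p < .01 (the network threshold is stricter than
the 0.05 significance flag, following the construction it reproduces).
Networks are undirected and unweighted — ρ is kept as an attribute but does
not weight metrics, degree is normalised by n − 1, betweenness is Brandes'
unnormalised count with each unordered pair counted once. The consensus
network keeps an edge iff significant in strictly more than
`min_support = ⌊total/2⌋` cell types. Communities come from
Clauset–Newman–Moore greedy modularity maximisation with Q =
Σ_c (e_c/m − (d_c/2m)²); community labels are ordered by smallest member so
output is deterministic.

## Essentiality score and multi-omic tests

ES_g = mean detection fraction across cell types × 1/(1 + m_g) with m_g the
number of cell types listing g in the marker table. Both ingredients are
exported so alternative weightings can be evaluated; an optional
multiplicative expression-magnitude quantile factor (off by default) serves
scores that also reward high level. ES is scale-free in the number of cell
types and bounded by the mean detection.

GDI association: Kruskal–Wallis across low/medium/high damage categories on
variability residuals, with the medium category downsampled (default to the
high-category size, 10 repetitions, seeded) to balance group sizes; per-rep
H/p and the median p are reported. Chromatin accessibility: a peak is
assigned to a gene when it intersects the ±1 kb window around the TSS
(window configurable; window 0 means point containment), per-gene values
aggregate by mean (sum by flag); ES–accessibility association uses the same
Spearman + permutation null as pair correlation. TF enrichment is an
upper-tail hypergeometric against a protein-coding background.

## Overlap statistics

Random-list ensembles are size-matched draws without replacement from a
stated universe (default 10 repetitions, seed 123441). Overlaps are
upper-tail hypergeometric with expectation |A||B|/|U|; per-pathway overlap
percentages of the gene set are compared against each random list's with
Kruskal–Wallis. The marker detector is a 1-vs-rest two-sided Wilcoxon
rank-sum per gene within a tissue with BH across genes and a
|Δ mean log2| ≥ 0.25 gate — a rank-based stand-in adequate for overlap
reporting, not a hurdle model. HVGs are the top-n genes by biological
residual, ties broken by gene id. Percent overlap uses the refined
essential set as denominator.

## Ageing model

Per gene, ordinary least squares on log-normalised expression with
treatment coding: y ~ sex + age * celltype, age an unordered three-level
factor. Two grouped F-tests are reported: the age main effect compares the
additive model {sex + age + celltype} with {sex + celltype}; the
interaction compares the full model with the additive one. A third contrast
dropping age and interaction together (full vs {sex + celltype}) is
exported as `p_age_overall` but is not used for classification: it flags
any age-dependence including pure interaction effects, which would make the
age/interaction two-step classification degenerate (every detectable
interaction gene would be absorbed into the age class). BH runs across
genes separately per family; classification is age_significant if age
q < .05, else interaction_significant if interaction q < .05, else stable.
Genes with zero residual variance are flagged and excluded from BH. All
genes share one design matrix, so fits are projections onto three fixed
column spaces (rank-revealing pivoted QR; unobserved age×cell-type
combinations drop out) and run vectorised. Per-cell-type counts re-test the
interaction-significant genes within each cell type ({sex + age} vs {sex},
BH across the tested genes).

A Gaussian OLS on log-normalised values is used rather than a count GLM:
per-cell counts in deeply sequenced full-length data are depth-confounded,
and the lm-on-lognorm reading is the standard one for this model family.

## Synthetic data

Counts are zero-inflated negative binomial, NB(mean μ_g·s_j·m_{g,ct},
size θ): θ defaults to 2 (variance μ + μ²/2), per-cell size factors are
log-normal with σ = 0.2, dropout is per platform, and marker genes carry an
8× multiplier in their target cell type. Baseline means are log-normal
(μ_log = 0, σ_log = 1, i.e. median mean 1 count); essential-like genes draw
from the upper quartile with a floor of 1 and use 4× the NB size (less
overdispersed) — essential genes are empirically high-expressed and stable,
and this is what makes the stability filter's planted truth well defined.
Platform-sensitive genes get a *complete* capture failure (dropout 1.0) on
the first platform: a partial failure leaves genes straddling the ≥ 3-cell
threshold by sampling chance, so the planted label would not be ground
truth. Correlated blocks are Gaussian copulas with equicorrelation ρ
(feasible range (−1/(k−1), 1)) mapped through the NB quantile function; the
induced rank correlation is slightly below the Gaussian ρ.

Ageing atlases have three age groups (3m/18m/24m) with donors nested in age
group and sex assigned per donor. Planted effects are multiplicative per
age step and **composition-balanced**: because library-size normalisation
makes measurements relative, an unbalanced shift in 10% of a ~100-gene
panel inflates old cells' libraries by ~10% and bleeds a spurious opposite
shift into every unaffected gene. Effects therefore come in mean-matched
up/down pairs with fold-changes f (default 1.3) and g = √(2 − f²) ≈ 0.56,
which cancel in expected library contribution exactly at the second age
step and nearly at the first; interaction pairs are mirrored across two
cell types (gene one up in A / down in B, gene two the reverse) so each
cell type's library stays flat and each gene's marginal age effect is ~null
while its age×cell-type term is strong. For f > √2 no cancelling partner
exists and 1/f is used, re-introducing a small composition shift. A small
sex effect (5% of genes, 1.3×) lives on a disjoint gene set.

What the generator does **not** emulate: empirical library-size
distributions of real atlases, UMI/read-level structure, batch effects
beyond platform dropout, donor random effects on the mean, ambient RNA, and
doublets. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability under NB-with-dropout conditions,
not robustness to every artefact of real data.

## Problem sizes and determinism

Validation runs use a few hundred cells per cell type and 45–300 genes —
large enough for the planted effects to be comfortably detectable at the
stated thresholds and small enough to re-run the whole pipeline in seconds.
All randomness flows through `numpy.random.default_rng` seeded from a
single configuration seed (default 123441); sub-streams use fixed offsets
so adding gene classes does not reshuffle existing draws, and every CLI
stage writes byte-identical output for a fixed seed.

## Known limitations

- The essentiality-score weighting of detection versus marker evidence is
  one concrete instantiation of the two stated ingredients; alternatives
  (e.g. an expression-level term) are exposed but not the default.
- The stability filter's quantile and majority rule are conventions; both
  are logged and configurable rather than estimated.
- The exhaustive permutation null ignores ties in the observed data (the
  null is built from untied ranks); for heavily tied low-count genes the
  null is an approximation, which the ≥ 90% detection filter mitigates.
- Community detection is unweighted; edge ρ values are carried but unused.
- No ortholog mapping: gene identifiers are opaque case-sensitive strings,
  so cross-species comparisons must be mapped upstream.
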