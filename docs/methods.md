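# Methods

`scregulon` re-implements, as a tested and reusable pipeline, the
computational core of a case-control single-cell RNA-seq analysis of
patient-derived cardiomyocytes: quality control and normalization, cluster
composition testing, differential expression with cross-line consistency,
correlation-based transcription-factor (TF) regulon construction,
rank-recovery AUC activity scoring, differential regulon activity, and
hypergeometric gene-set enrichment. Because the original patient data
cannot ship with the package, a synthetic-data generator plants the exact
statistical structure each stage is supposed to detect, and the test suite
scores every stage against that planted truth.

## Quality control and normalization

Genes expressed (count > 0) in fewer than 200 or more than 8,000 cells are
excluded; cells with fewer than 200 or more than 8,000 detected genes, or
with more than 30% mitochondrial counts, are removed. All inequalities are
read strictly as stated: a cell at exactly 30.0% mitochondrial fraction is
retained, a gene in exactly 200 cells is retained. Mitochondrial genes are
a caller-supplied name set, defaulting to the `MT-` prefix. Gene and cell
filters are applied sequentially, genes first by default; the order is
configurable and an optional fixpoint mode repeats the pair until stable
(it converges in at most three rounds on all our fixtures, since each pass
only shrinks the matrix). Filters are idempotent.

Normalization is `ln(1 + 10,000 * count / cell_total)`, strictly
column-local. Variable genes are ranked by a variance-stabilizing score
computed on raw counts: per-gene mean and unbiased variance, a lowess
trend of log10(variance) on log10(mean) with span 0.3 (a first-degree
local regression; the span, and the degree, are pragmatic choices — the
score is used only for ranking), counts standardized by the
trend-predicted standard deviation with upper clipping at sqrt(n_cells),
and the mean of squared clipped values (denominator n − 1) as the score.
Ties, including the degenerate all-constant matrix, break by gene
identifier.

## Cluster composition

Cluster labels are taken as input; the package does not cluster. Each
cluster is tested with a per-cluster 2x2 Pearson chi-square (in-cluster vs
not, unit A vs unit B) without continuity correction (a flag restores
it), and Benjamini-Hochberg (BH) FDR is applied across the clusters of one
comparison. The pooled case-vs-control comparison and each per-line
comparison form separate BH families, mirroring how such panels are
reported. Per-cluster 2x2 tests (rather than one global k x 2 test) were
chosen because per-cluster significance is the quantity of interest;
the global test answers a different question.

## Differential expression

Two-sided Wilcoxon rank-sum per gene: a tie- and continuity-corrected
normal approximation at single-cell group sizes, switching automatically
to the exact null distribution for small tie-free groups (where the
asymptotic p can deviate from enumeration by more than 0.01). The fold
change is `log2((mean(expm1(A)) + 1e-9) / (mean(expm1(B)) + 1e-9))`,
i.e. means on the de-logged normalized scale with a small pseudocount —
the convention of current single-cell toolkits; the source analysis does
not state its formula, so this is a documented package choice. Bonferroni
adjustment uses the genes tested in the call as the family (an override
accepts the full post-QC gene count). Significance requires |log2FC| > 0.5
(strict) and adjusted p < 0.05. Adjusted p-values of exactly zero are
displayed as 1e-320 so that -log10 is finite in volcano tables.

Cross-line consistency retains genes significant with the identical
direction in at least `min_lines` of the per-line comparisons. The default
is 3 of 4: "multiple lines" is not pinned down by the source, so the
majority-of-lines reading was adopted and the parameter left fully
configurable.

## TF regulons and activity

TFs are taken from a user-supplied list (in practice, a curated human TF
database) and kept if detected in at least 5% of cells (inclusive). For
each TF, Spearman's rho (average-rank ties) is computed between the TF's
log-normalized expression and every other gene across all QC-passing
cells; genes with rho > 0.1 (one-sided positive, strict; an `absolute_rho`
flag adds |rho| mode) become targets, the TF itself is excluded, and
regulons with fewer than 10 targets are dropped. Constant-expression TFs
have undefined rho and are dropped with a warning.

Per-cell activity is the rank-recovery AUC (the AUCell statistic). Genes
are ranked by descending expression; ties — ubiquitous because of zeros —
are broken by a single permutation drawn from `tie_seed` and shared by
every cell, which makes scores bit-reproducible where per-cell random
tie-breaking would not be. With maxRank = ceil(0.05 * G) (floor mode
available),

    rawAUC = sum_{k=1..maxRank} hits(k),  hits(k) = #targets with rank <= k,
    AUC    = rawAUC / sum_{k=1..maxRank} min(k, |targets|)  in [0, 1].

The scored set is the target list; the TF is excluded by construction.
AUC is invariant under any strictly increasing transform of a cell's
expression vector, and moving a target to a better rank never decreases
it; both properties are tested, and the implementation is checked for
exact equality against a literal step-curve summation oracle on hundreds
of random instances.

Differential activity uses the same Wilcoxon test on AUC values per
regulon, BH FDR across regulons, `log2((mean_case + 1e-6) /
(mean_control + 1e-6))` (AUC means are bounded, so the epsilon only guards
the all-zero corner), and percent change `100 * (case - control) /
control` of mean activity (means, not medians — a documented choice).
Direction is assigned only below the FDR threshold. Direction summaries
report counts and one-decimal percentages of significant regulons
increased/decreased, overall and for the cardiac subset (TFs belonging to
any supplied cardiac-development gene set).

## Enrichment

Over-representation of a gene list against GMT collections uses the
hypergeometric upper tail P[X >= k], with the conservative EASE variant
(tail at k − 1) behind a flag, BH FDR across terms, and fold enrichment
(k/n)/(K/N). The background defaults to all post-QC genes of the matrix —
a deliberate divergence from web-service backends whose species-wide
backgrounds are not reproducible offline. Per regulon, the top 3
significant terms are retained (ties by p, then term id), and an
input-driven term-to-category map produces circos-ready links weighted by
-log10(FDR); the category grouping is input because such groupings are
inherently manual.

## Synthetic data

The generator emulates the pooled case-control design: control lines and
case lines, cells drawn into clusters by group-specific proportions, and
planted regulons. Per cell, each TF has latent activity a ~ Normal(0, 1);
case cells subtract `shift_size` from a for the shifted TF subset
(`shift_frac` of TFs). The TF gene and each of its targets have log-mean
`baseline + coupling_strength * a`; weights `exp(log-mean)` are softmax-
normalized, scaled by a lognormal library size, and counts drawn from a
negative binomial with shared dispersion (a standard single-cell noise
model that is sufficient for the rank-based statistics downstream). A
designated `MT-` block receives a per-cell mitochondrial fraction, and an
optional fraction of cells is made deliberately QC-failing (starved
libraries or 50% mitochondrial content) so filters have positive and
negative cases. Group effects act on latent activity, not directly on
counts, so "decreased regulon activity" has a well-defined planted truth.

Defaults are desk-scale study conditions: 3,000 genes, 40 TFs with 25
targets each, 4 control + 4 case lines at 500 cells per line, 14 clusters,
coupling 1.5, shift fraction 0.5 of TFs at shift size 1.0, library size
lognormal with mean 5,000 and sigma 0.35, NB dispersion 2.0, mitochondrial
fraction Normal(0.05, 0.02). Baselines are Normal(1.0, 0.5) for TF genes,
Normal(0.5, 0.75) for targets and Normal(0, 1) for background genes:
regulon genes are modelled as moderately expressed because correlation-
based target prediction is only informative for genes that are actually
detected. Cluster marker offsets (+1 log-mean on ten dedicated background
genes per cluster) are kept disjoint from TF/target genes so cluster
structure cannot masquerade as planted correlation. A matched null
generator zeroes the shifts and equalizes cluster proportions while
keeping the regulon coupling.

What the generator does not emulate: ambient RNA, doublets, batch/
integration artefacts, UMI saturation, gene-specific dispersion, or any
real regulatory network topology. Passing recovery tests therefore shows
the pipeline detects the structure it claims to detect under its stated
noise model — not that it would recover any particular biological network.

### Two deliberate measurement choices

*Regulon recovery is scored on shift-free data.* When many TFs shift
together in the case group, every shifted TF co-varies with every other
shifted TF's targets through the shared group factor, and the correlation
definition correctly picks those genes up; they are not false positives of
the method, but they are not planted members either. Recovery
(recall/precision against planted membership, thresholds 0.9/0.8 at 2,000
cells) is therefore measured with shifts disabled.

*Rank-based activity is compositional.* Ranking within a cell means that
when most regulons lose activity, the few unshifted regulons' targets
rise in relative rank, so unshifted regulons can show a significant
apparent increase. With 90% of TFs shifted down, the fraction of
significant regulons called decreased settles at the shifted fraction
(~90%), which is the behaviour the direction-recovery suite asserts.

## Numerical and reproducibility choices

Same seed, same output, bit-identically: the generator uses one
`numpy` Generator in a fixed traversal order; AUCell tie-breaking is a
seeded permutation; the pipeline runner stamps outputs with the package
version, a config hash (excluding the output path) and the seed, and
re-running an identical config produces byte-identical TSV bodies — this
is enforced by a test. Monte-Carlo calibration uses the empirical
per-replicate standard error of crossing fractions rather than a binomial
error, because tests within one replicate are correlated. Degenerate
inputs fail loudly: empty matrices, all-filtered results, zero-total
cells at normalization, maxRank < 1, empty TF lists and empty gene-set
collections are all explicit errors, not silent empties.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
rank statistics are stable while the whole suite stays in the minutes
range: 2,000 cells for regulon recovery, 500 + 500 cells for direction
recovery, and 20 replicate seeds of a 600-gene / 600-cell configuration
for null calibration.

## Known limitations

Cluster labels, dataset integration and embedding are out of scope (labels
are inputs). The Bonferroni family is per call, not per dataset, unless
overridden. The hypergeometric background is the post-QC gene universe,
so term-level results will not be count-identical to web services with
species-wide backgrounds. The simulator's shared NB dispersion understates
gene-specific noise heterogeneity. Exact Wilcoxon mode is limited to
groups of at most 10 cells by design.
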