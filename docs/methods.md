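# Methods

This note documents the statistical models, parameter choices, and numerical
conventions behind each pipeline stage, what the synthetic-data generator
does and does not emulate, and the design decisions taken where more than one
reasonable convention exists.

## Coordinates and containers

All interval arithmetic is 0-based half-open internally. GTF is read/written
1-based closed; BED 0-based half-open; a CTSS is a single 1-based base (the
5′ end of a CAGE read) stored as FANTOM-style single-base BED6 with the tag
count in the score column. Duplicate CTSS rows within one sample are an
error rather than being summed silently, so any upstream aggregation has to
be explicit. The central container is `ExpressionMatrix`: an integer gene ×
sample count table bound to sample metadata (region, age, sex) and gene
annotation (exonic length, class label), with RPKM derived on demand.
Correlation, PCA, and all hypothesis tests operate on log₂(RPKM+1), a
conventional variance-stabilizing scale for bulk RNA-seq.

## Transcript filtering

A candidate transcript is kept as a lncRNA only if it is ≥ 200 nt of spliced
length, multi-exonic, free of any ATG-to-stop ORF of ≥ 100 codons, and free
of same-strand exonic overlap with a known mRNA; survivors split into
antisense (≥ 1 bp exonic overlap with an mRNA exon on the opposite strand)
and intergenic. The ORF scan counts only stop-terminated ORFs in the three
forward frames — transcripts are already stranded, and an open-ended ORF is
not evidence of coding capacity under this convention. This rule chain is a
deterministic, oracle-checkable proxy for trained coding-potential models
(CPC/CPAT-style classifiers are out of scope); on synthetic data whose mRNAs
carry planted ORFs it separates the classes perfectly by construction.
Overlap is defined on exons, not gene spans, because antisense pairing is an
exon-level complementarity statement.

## Differential expression between adjacent ages

Within one region, counts from the two age groups are library-size
normalized (scaled to the mean library), summed per group, and the first
group's sum `y₁` is tested against its conditional distribution given the
pooled total `T`. Sums of i.i.d. NB(μ, φ) counts over n replicates are
NB(nμ, size n/φ), so the conditional law of `y₁ | T` follows from two NB
probability mass functions; with dispersion φ = 0 it reduces to the
conditional binomial (the classical Poisson exact test). Two-sided p-values
sum the probabilities of all outcomes no more likely than the observed one.

Two numerical choices matter:

- **Dispersion** is a single common value estimated by the method of moments
  (`φ̂ = Σ(v − m) / Σ m²` over genes and replicate cells), pooled over *all*
  (region, age) cells of the experiment rather than only the four contrasted
  samples — a 2-vs-2 moment estimate is far too noisy and visibly
  mis-calibrates the exact test. When the pooled estimate is ≤ 0 the test
  falls back to Poisson.
- **Mid-p by default.** Discrete exact tests are conservative; in particular
  they place an atom at p = 1 of roughly the central outcome probability,
  which makes the null p-value distribution detectably non-uniform at a few
  thousand genes. The mid-p variant (half-weighting outcomes exactly as
  likely as the observed one) restores near-uniformity and is the default;
  `mid_p=False` gives the strictly conservative exact test, under which two
  identical groups score exactly p = 1.

Fold changes are log₂ of group means with a 0.5 pseudocount. Significance
requires p < α (default 0.01) and |LFC| ≥ 1. Exact replication of a
particular DE package's output is a non-goal; the test is defined fully by
the equations above.

## Tissue specificity

Gene profiles are mean RPKM per region (collapsing age and sex),
renormalized to a distribution; the score against region t is
1 − √JSD(p, e_t) with the Jensen–Shannon divergence in bits, computed via
relative entropy to the mixture (numerically safer than squaring a
Jensen–Shannon *distance*, which can return NaN for identical inputs).
All-zero genes are skipped with a warning — the specificity of nothing is
undefined, and scoring it 0 would contaminate distribution comparisons.
Non-normalized inputs are an error, never renormalized silently. Score
distributions are compared by the two-sample two-sided Kolmogorov–Smirnov
test. Specificity defaults to the 8 anatomical regions; any sample grouping
column can be substituted.

## Co-expression modules

Unsigned adjacency `a_ij = |cor(x_i, x_j)|^β`, topological overlap
`w_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij)`, average-linkage
hierarchical clustering on 1 − TOM, and a static cut. Static cutting (rather
than the dynamic hybrid tree cut) keeps the operation deterministic and
directly checkable against closed forms (a perfect clique has TOM ≡ 1; a
3-node chain has w₁₃ = 0.5).

Defaults: soft power β = 4, cut height 0.95, minimum module size 30. The
geometry of unsigned TOM drives these numbers: for a module of m genes with
within-module |r| ≈ ρ and negligible outside connectivity, TOM ≈ E[ρ^β], so
even strongly correlated modules (ρ ≈ 0.7) sit at dissimilarities of
0.8–0.97, while between-module dissimilarities are ≈ 1. The cut therefore
belongs high on the tree, and a moderate power keeps the within/between gap
wide; a very high power (or a low cut) collapses everything into the
unassigned label. `pick_soft_threshold` implements the standard scale-free
criterion (smallest β with signed fit R² ≥ 0.8, else the argmax with a
warning) for data where that criterion is meaningful; block-structured
synthetic data are not scale-free, so the fixed default is used unless the
caller opts in.

Eigengenes are the first right-singular vector of the per-gene standardized
module submatrix (unit norm over samples), sign-oriented to correlate
positively with the module's mean expression. Module classification computes
η² (between-group sum of squares over total) of each eigengene for region,
for age, and for the sex×age cell combination; because the sex×age cells
refine the age groups, the sex×age η² is reported *incrementally* — its raw
value minus the age η² — so a purely age-driven eigengene does not register
as sex-driven. A module is sex-temporal when that incremental value is at
least as large as both the region and age η²; otherwise region vs age
decides spatiotemporal vs tempo-spatial (ties go to spatiotemporal).

## CAGE tag clusters

Positions are retained when their TPM (count / sample tag total × 10⁶)
reaches 0.5 in at least one sample, then sorted per chromosome and strand
and merged while consecutive retained positions differ by ≤ 19 bp — the
strict reading of "< 20 bp apart". Clustering operates on the pooled
retained positions across samples, with per-sample detection counted inside
each cluster; this gives every TC a single identity (the alternative —
clustering per sample and consolidating by overlap — yields equivalent
summaries but ambiguous TC identities). The summit is the position of
maximum pooled TPM, ties broken toward the 5′-most position. A brute-force
O(n²) merge reproduces the clustering exactly on random small inputs, and
clustering is idempotent and order-independent.

Gene assignment: a TC belongs to a gene when it shares the strand and its
summit lies in the gene span or within 2 kb upstream of the annotated TSS;
a summit matching several genes goes to the nearest TSS (deterministic
single assignment). "Alternative TC reads" are tags in a gene's non-dominant
TCs, the dominant TC being the one with the highest pooled tag count (ties
to the 5′-most summit) — the natural reading of an otherwise undefined
phrase. Full-length frequency treats RNA-seq detection (RPKM > 0.1) as
polyA evidence and an assigned TC with ≥ 1 tag in the same sample as cap
evidence. TSS profiles use strand-oriented summit-to-nearest-TSS distances
(negative = upstream). Genomic-region classification uses the precedence
5′UTR > 3′UTR > CDS > intron > intergenic on summit positions and tests
5′UTR enrichment against control positions with a two-sided Fisher exact
test; annotations without UTR/CDS sub-features fall back to
{exon, intron, intergenic} with a warning.

## Co-expression network

Edges are Pearson correlations on log₂(RPKM+1) kept at |r| ≥ 0.7 *and*
p ≤ 0.01, with p from t = r√(n−2)/√(1−r²) on n−2 degrees of freedom (the
permutation distribution agrees at small n). Constant genes are excluded
with a warning; within-set networks store each unordered pair once.
Interaction strength sums |r| over a partner's edges to the focal set —
absolute values, so strong negative regulators rank as strong rather than
cancelling. A lncRNA counts as a negative regulator of a target module when
it has at least k (default 1) negative edges into it; counts are
non-increasing in k. Gene-set enrichment is the one-sided hypergeometric
upper tail with Benjamini–Hochberg adjustment across sets. Whole-transcriptome
within-class networks are quadratic in gene count; the CLI subsamples beyond
a configurable cap and warns.

## Sex bias

Each (region, age) cell with both sexes contributes one F−M pair (32 pairs
in the full design); the per-gene statistic is the paired two-sided t-test
on log₂(RPKM+1) differences across all pairs jointly, so consistent sex bias
is detected regardless of where or when it occurs. Pairing within one age
group is available for the sex-temporal contrast. Zero-variance edge cases
are explicit: all-zero differences give t = 0, p = 1; constant nonzero
differences are flagged degenerate with p = 0 and a warning (the statistic
diverges, and silently dropping such genes would hide planted signal).
Swapping the sex labels flips every direction and leaves every p unchanged.
Class frequencies of biased genes are compared with the two-sided Fisher
exact test (conditional maximum-likelihood odds ratio).

## Synthetic studies: what they do and do not emulate

The generator emits a full factorial design (8 regions × 4 ages × 2 sexes),
with per-gene counts drawn NB(μ, φ) around class-specific log-normal
baselines — lncRNAs centered at 30 (log-sd 1) vs mRNAs at 150, so lncRNAs
are lower-expressed — multiplied by planted effects and a log-normal
(sd 0.1) library factor. Defaults: dispersion φ = 0.05 (a typical bulk
biological-replicate value); four planted lncRNA modules of 30–40 genes
(cerebellum- and CA1-driven, age-1-driven, and female×age-4-driven, all at
4-fold) plus two mRNA modules (one *down* at age 1, planting negative
lncRNA–mRNA correlations); 30 sex-biased lncRNAs at 2-fold, alternating
direction. Transcript models place mRNAs with planted 200-codon ORFs and
UTR/CDS sub-features, lncRNAs shorter and at GC 0.40 vs 0.50 with no ORF
≥ 100 codons (rejection sampling with a deterministic stop-insertion
fallback), 13% of lncRNAs antisense to an mRNA exon, and optional decoys
that each violate one filter. CAGE tags (50,000 per sample, 5% uniform
background) pile up at the annotated TSS with discretized 1-bp Gaussian
jitter; 30% of genes carry a second internal promoter taking 30% of their
tags. One `numpy` generator seeded from the config drives everything, so a
config reproduces its study byte for byte.

Not emulated: read-level data (FASTQ, alignment), sequence-realistic
genomes, GC- or length-dependent quantification bias, batch effects, and
between-gene correlation beyond the planted modules. Consequently, passing
recovery and calibration checks on these studies demonstrates correctness of
the statistics under their stated models — not robustness to alignment
artifacts or confounding in real tissue data.

Two composition effects of the planted design are worth knowing: planted
modules shift the library sizes of their target samples, so after RPKM
normalization (i) raw-count fold changes of planted genes exceed their
normalized fold changes, and (ii) the non-planted genes of a planted study
are not exactly null. False-positive-rate calibration is therefore assessed
on the dedicated null study (no planted effects), where gene-level tests are
also far less cross-correlated.

## Problem sizes

The default synthetic study uses 1,000 genes (200 lncRNA + 800 mRNA) over
64 samples and ~3.2 M CAGE tags; null calibration uses 2,000 genes; the
network null check uses 1,000 genes (≈ 500k pairs). These sizes give the
recovery and calibration statistics comfortable precision (binomial standard
errors of a few per mille) while keeping a full pipeline run under a minute
on one CPU.

## Known limitations

- The exact-test DE stage models a common dispersion; per-gene (tagwise)
  shrinkage is out of scope, so strongly heteroskedastic genes are tested
  slightly mis-calibrated.
- Static tree cutting requires the within-module dissimilarity to sit below
  one global height; modules of very heterogeneous tightness may need the
  dynamic cut of a full WGCNA implementation.
- The t-transform p-value for Pearson correlation assumes approximate
  bivariate normality on the log scale; at n = 64 this is mild, but edge
  p-values near the threshold inherit the approximation.
- TC assignment is summit-based; a very wide TC straddling two genes is
  attributed wholly to the nearest TSS.
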