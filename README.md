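# lncbrain

Analysis pipeline for spatiotemporal and sex-related long noncoding RNA
(lncRNA) expression in brain tissue surveys — the kind of study that profiles
bulk RNA-seq and CAGE-seq across many brain regions, postnatal ages, and both
sexes (e.g. 8 regions × 4 ages × 2 sexes = 64 samples).

It is written for computational biologists who want each analysis stage as a
tested, reusable library function (plus a thin CLI), together with a fully
seeded synthetic-study generator so every stage can be validated against a
known ground truth without downloading any external data.

## What it computes

- **Transcript filtering** (`lncbrain.transcript_filter`): classify assembled
  transcripts into `lnc_intergenic` / `lnc_antisense` / `rejected` by spliced
  length (≥ 200 nt), exon count (multi-exonic), longest open reading frame
  (ORF < 100 codons, ATG-to-stop over the 3 forward frames), and exon-level
  overlap with known mRNAs (same-strand overlap rejects; opposite-strand
  overlap defines the antisense class).
- **Quantification and differential expression** (`expression_quant`): RPKM
  (reads · kb⁻¹ · 10⁶ reads⁻¹), the [0.1, 20] moderate-expression band
  filter, super-group exclusive expression (neocortex / hippocampus /
  cerebellum Venn partition), PCA and sample correlation on log₂(RPKM+1), and
  adjacent-age differential expression by a conditional negative-binomial
  exact test (common dispersion by method of moments; mid-p by default).
- **Tissue specificity** (`specificity`): Jensen–Shannon scores,
  `score(g, t) = 1 − √JSD(p_g, e_t)` in bits, where `p_g` is the gene's
  expression distribution over regions and `e_t` the unit vector of region
  `t`; a perfectly region-restricted gene scores 1.
- **Co-expression modules** (`modules`): WGCNA-style detection — unsigned
  soft-threshold adjacency `|r|^β`, topological overlap matrix
  `w_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, average-linkage
  clustering on 1 − TOM with a static cut, unit-norm first-PC eigengenes, and
  classification of each module as spatiotemporal (region-driven),
  tempo-spatial (age-driven), or sex-temporal (sex×age-driven) by an η²
  variance decomposition of its eigengene.
- **CAGE promoter metrics** (`cage`): CTSS tables (single-base 5′-end tag
  counts) are TPM-normalized, filtered at ≥ 0.5 TPM in at least one sample,
  and clustered into tag clusters (TCs) whenever neighboring positions are
  < 20 bp apart; TCs get summits, per-sample counts, gene assignments (gene
  body or ≤ 2 kb upstream of the TSS, strand-aware), alternative-promoter
  ratios, full-length (cap + polyA) frequencies, TSS-distance profiles, and
  genomic-region distributions with a 5′UTR Fisher enrichment test.
- **Signed co-expression network** (`network`): all gene pairs with
  |Pearson r| ≥ 0.7 and p ≤ 0.01 (t-transform, n − 2 df) on log₂(RPKM+1);
  positive/negative partitions per class pair, module–module edge counts,
  interaction strength (Σ|r|), negative-regulator summaries, and a generic
  hypergeometric gene-set enrichment with Benjamini–Hochberg q-values.
- **Sex bias** (`sex_bias`): per-gene paired two-sided t-tests of F−M
  log₂(RPKM+1) differences across matched (region, age) sample pairs, and a
  Fisher exact comparison of biased-gene frequencies between lncRNAs and
  mRNAs.
- **Synthetic studies** (`synthetic_data`): a seeded generator emitting GTF +
  FASTA annotation (mRNAs with planted ORFs; shorter, lower-GC lncRNAs, some
  antisense), negative-binomial counts with planted region/age/sex×age
  modules and sex-biased genes, and per-sample CTSS BED files with tags
  jittered around true TSSs plus planted alternative promoters and uniform
  background.

## Worked example

Simulate the default 64-sample study, detect lncRNA co-expression modules,
classify them, and call sex-biased genes:

```python
from lncbrain import simulate_study, SimulationConfig
from lncbrain import modules as mm, sex_bias as sb

annotation, expr, ctss, truth = simulate_study(SimulationConfig(seed=42))

lnc = expr.genes_of_class("lnc_intergenic", "lnc_antisense")
log_expr = expr.log_rpkm().loc[lnc]
module_set = mm.detect_modules(log_expr[log_expr.std(axis=1) > 0])
print(mm.classify_modules(module_set, expr.samples).round(3))

res = sb.paired_sex_test(expr)
print(sb.sex_bias_summary(res))
print(sb.frequency_comparison(307, 9904, 219, 26654))
```

This prints (seed 42):

```
 module          class  eta2_region  eta2_age  eta2_sex_age  n_genes
      1 spatiotemporal        0.979     0.003          0.00       43
      2  tempo-spatial        0.012     0.984          0.00       41
      3 spatiotemporal        0.991     0.001          0.00       40
      4   sex-temporal        0.022     0.430          0.54       30
{'n_biased': 52, 'n_female_biased': 33, 'n_male_biased': 19}
(9.043346097799746e-52, 3.8592...)
```

The four detected modules recover the four planted lncRNA modules (two
region-driven, one age-driven, one sex×age-driven), each classified by the
design factor that explains its eigengene's variance. The sex-bias summary
contains the 30 planted sex-biased genes plus a handful of borderline calls
at p < 0.01, and the final line is the Fisher test on the published
lncRNA-vs-mRNA sex-bias counts (307/9904 vs 219/26654): the lncRNA class is
enriched for sex bias with an odds ratio near 3.9 at p ≈ 9×10⁻⁵².

The same pipeline is available from the shell, one subcommand per stage:

```bash
lncbrain run --out-dir demo --seed 42           # simulate + all stages
lncbrain simulate --out study --seed 7          # or stage by stage
lncbrain modules --counts study/counts.tsv --metadata study/samples.tsv --out-dir mods
lncbrain --help
```

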