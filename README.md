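# phylomark

Phylostratigraphic gene-age dating and coexpression-network analysis of
multi-tissue transcriptomes.

`phylomark` is for researchers who have (a) a genes × samples FPKM matrix
from a multi-tissue bulk RNA-Seq study with biological replicates and (b)
ortholog groups over a species taxonomy, and who want to answer: *when in
evolution did each expressed gene arise, and do coexpressed genes share an
evolutionary age?*

## What it computes

* **Gene ages.** Each gene is dated by the lowest common ancestor (LCA) of
  the species in its ortholog group. Since the focal species belongs to its
  own group, the LCA lies on the root-to-focal lineage; each gene maps to
  one lineage clade with a divergence age (Mya, TimeTree-style calibration).
  For human the shipped lineage has 31 clades, *cellular organisms* →
  *Homo sapiens*, binned into eight contiguous "hallmark" stages
  (st1 Prokaryota … st8 Primates → *Homo sapiens*). Per-stage counts,
  percentages and cumulative emergence curves are produced per gene class.
* **Gene classes.** A gene is *expressed* in a tissue when ≥ 1 replicate has
  FPKM ≥ 1. House-keeping genes (HK) are expressed in every sample and
  present in a curated reference list; tissue-enriched genes (TE) are
  expressed in ≤ 3 tissues. The HK-reference overlap is summarised in a 2×2
  table with the conditional-MLE odds ratio (the `fisher.test` estimator)
  and exact confidence interval.
* **Sample structure.** 1 − Spearman distances between samples and
  `hclust`-style agglomerative clustering (complete linkage by default),
  exported as Newick.
* **Coexpression network.** Candidate edges with all-sample Spearman
  r ≥ 0.85 on log2(FPKM+1), cross-validated on 100 random subsamples of two
  replicates per tissue; only pairs passing all 100 are kept. Dense modules
  are found with MCODE and summarised by the stage composition of their
  members, with a permutation test of age homogeneity.
* **Enrichment.** Hypergeometric over-representation with
  Benjamini–Hochberg correction against user-supplied annotations.
* **Synthetic studies.** A seed-driven generator plants HK/TE classes,
  gene ages and coexpression modules so the whole pipeline is testable
  end-to-end without any download.

## Worked example

Per-stage counts of dated genes go in; shares and the cumulative emergence
profile come out:

```python
>>> from phylomark.phylostrata import StageProfile
>>> prof = StageProfile.from_stage_counts(
...     [1178, 2178, 1395, 2333, 5070, 1953, 2821, 509])
>>> print(prof.to_frame().round(2))
     count  pct_of_total  cumulative_pct
st1   1178          6.76            6.76
st2   2178         12.49           19.25
st3   1395          8.00           27.25
st4   2333         13.38           40.63
st5   5070         29.08           69.70
st6   1953         11.20           80.90
st7   2821         16.18           97.08
st8    509          2.92          100.00
```

Reading: 6.76 % of the 17,437 dated genes trace back to the prokaryotic
stage; the largest single step is st5 (jawed/bony vertebrates, 29 % of
genes); 97.08 % of the gene complement predates the primate radiation.

The overlap between an all-sample-expressed set (7,668 genes) and a
3,804-gene house-keeping reference, with 3,524 shared, in an 18,545-gene
universe:

```python
>>> from phylomark.gene_classes import overlap_stats_from_counts
>>> s = overlap_stats_from_counts(3524, 4144, 280, 10597)
>>> print(f"OR = {s.odds_ratio:.2f}  95% CI = ({s.ci_low:.2f}, {s.ci_high:.2f})"
...       f"  overlap = {s.overlap_pct:.1f}%")
OR = 32.18  95% CI = (28.33, 36.66)  overlap = 92.6%
```

An odds ratio of 32 means membership in the reference multiplies the odds
of being expressed in every sample about 32-fold — the two definitions of
"house-keeping" agree strongly.

End-to-end on synthetic data:

```sh
phylomark run --config run.yaml     # simulate → classes → ages → network
```

writes expression calls, the sample dendrogram, gene ages, stage profiles,
the validated edge list, a GraphML network, module memberships and a
`summary.json` whose totals are mutually consistent (stage counts sum to
dated genes, modules live inside the network). Subcommands
(`simulate`, `expression`, `classes`, `ages`, `coexpress`, `enrich`) expose
each stage separately.

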