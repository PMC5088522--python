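# Methods

## Overview

phylomark combines two analyses of a multi-tissue transcriptome:

1. **Phylostratigraphic gene-age dating.** Every protein-coding gene of a
   focal species is placed in an ortholog group (the set of species in which
   orthologs are found). The lowest common ancestor (LCA) of those species on
   the taxonomy is the gene's *phylostratum*. Because the focal species is a
   member of its own group, the LCA always lies on the root-to-focal lineage,
   so each gene maps to exactly one lineage clade. Clades carry divergence
   ages (Mya) from a user-editable TimeTree-style calibration file, and are
   binned into a small number of contiguous "hallmark" stages; cumulative
   emergence curves per clade summarise when the gene complement arose. For
   the human lineage the package ships the 31-clade NCBI chain from
   *cellular organisms* to *Homo sapiens* and an eight-stage scheme whose
   boundaries are the clades cellular organisms | Eukaryota | Metazoa |
   Vertebrata | Euteleostomi | Mammalia | Primates | Homo sapiens.

2. **Expression classes and a validated coexpression network.** On the FPKM
   scale, a gene is *expressed* in a tissue when at least one biological
   replicate reaches the threshold (default FPKM >= 1). House-keeping genes
   (HK) are expressed in every sample and are members of a curated reference
   list; tissue-enriched genes (TE) are expressed in at most three tissues.
   On log2(FPKM + 1) values, candidate coexpression edges are gene pairs with
   all-sample Spearman r >= 0.85; they are cross-validated by recomputing r on
   100 random subsamples of two replicates per tissue and keeping only pairs
   that pass the threshold in all 100. Dense regions of the resulting graph
   are detected with MCODE and summarised by the evolutionary-age composition
   of their members.

## Models and procedures

### LCA dating

`TaxonomyTree.lca` aligns node depths and walks parents pairwise; it is
checked against a brute-force root-path-intersection oracle in the test
suite. An LCA that falls between lineage clades (possible when the taxonomy
has intermediate nodes) is lifted to the nearest lineage clade at or above
it. Ortholog groups lacking the focal species cannot be dated and are
skipped with a warning and a reported count; when several groups map to one
gene the first mapping wins and duplicates are logged.

### Stage profiles

For a gene class (all, HK, TE) the stage profile holds per-clade and
per-stage counts, the percentage of the class total, and the cumulative
percentage in lineage order; by construction the cumulative curve is
nondecreasing and ends at 100%. `time_axis` pairs each clade's cumulative
value with its calibration age to give the emergence-over-time curve.
`collapse_to_common_strata` re-bins two assignments onto a shared stratum
scheme so that datings made on different lineages can be compared.

### Overlap odds ratio

The overlap between the all-sample-expressed set and the HK reference is
tabulated as a 2x2 table over the expressed-gene universe (reference genes
outside the universe are dropped first — the universe is the population at
risk). Two estimators are exposed:

* `cmle` (default): the conditional maximum-likelihood odds ratio of the
  noncentral hypergeometric model with the exact, asymmetric confidence
  interval — the estimator printed by `fisher.test`. It handles zero cells
  natively.
* `sample`: the cross-product ratio ad/bc with the Woolf log-normal interval
  and the Haldane 0.5 correction when a cell is zero.

On tables with every cell >= 100 the two agree within 2%; the test suite
verifies the cmle route against an independent maximization of the
noncentral-hypergeometric likelihood.

### Coexpression validation

Spearman correlations use average ranks for ties. Candidate screening at
full-sample r >= r_min happens before validation, so the validation cost is
O(|candidates| x n_iter) rather than all-pairs. Each validation iteration
draws its tissues in sorted order from one seeded generator, iteration i
completing before i+1, which makes runs reproducible and invariant to gene
and edge order. Tissues with exactly two replicates contribute both in every
subsample (sampling 2 of 2 is deterministic); tissues with fewer replicates
raise an error unless `on_small="use_all"` is chosen. Genes with zero
variance have undefined rank correlations and are excluded from the
candidate scan (the count is reported); a gene that degenerates only inside
a subsample contributes r = 0 for that iteration.

### MCODE

Vertex weight = (highest k-core number of the closed neighborhood) x
(density of that k-core). Modules grow outward from the highest-weight
unvisited seed, admitting unvisited neighbors whose weight is at least
(1 - node_score_cutoff) x seed weight, to at most `max_depth` hops. Modules
without a 2-core are discarded; the haircut iteratively removes
singly-connected members; fluff is off, so modules are disjoint; ranking is
by density x size. Defaults are the published ones (degree cutoff 2, node
score cutoff 0.2, 2-core, haircut on). One documented consequence of the
core-density weighting: two cliques joined by a single bridge edge have
equal weights everywhere, so seeded expansion crosses the bridge and reports
one module covering both cliques. This is the faithful behaviour of the
algorithm, and it does not affect planted-module recovery because validated
modules appear as separate components.

### Age homogeneity of modules

Statistic: the dominant-stage proportion among a module's age-assigned
members. Null: stage labels permuted over all assigned network nodes;
p = (1 + #{perm >= obs}) / (n_perm + 1), BH-adjusted across modules. Because
the statistic is discrete, the conservative p is not exactly uniform under
the null; `p_mode="randomized"` breaks ties uniformly, the standard device
that restores exact null uniformity, and is what the calibration checks use.

### Enrichment

Over-representation p = P[X >= k] for X ~ Hypergeometric(N, K, n), with the
observed overlap included in the tail (the standard convention), followed by
Benjamini-Hochberg across terms. Annotations are restricted to the declared
universe before testing; a query gene outside the universe is an error. The
pipeline, when no annotation file is supplied, builds a self-contained
annotation whose terms are the hallmark stages themselves.

## Synthetic-data generator

The generator emulates the *shape* of a tissue compendium, not its biology:

* Design: default 10 tissues x 3 replicates (32-tissue, 2-5-replicate
  configurations are supported), 2,000 genes, seed-driven and byte-identical
  across reruns of the same configuration.
* HK genes: log-normal FPKM with log2 baseline mean 5 (sd 1 across genes),
  per-sample log2 noise `noise_sd`, floored at FPKM 1 so the class contract
  (expressed in every sample) holds by construction.
* TE genes: expressed in 1-3 random tissues at log2 mean 3, floored at
  FPKM 1 there; elsewhere Uniform[0, 0.5) FPKM. TE expression is lower and
  more variable than HK by construction.
* Background genes: silent (15%) or expressed in >= 4 tissues with
  independent per-gene-per-tissue levels, so cross-gene correlations stay
  low.
* Modules: groups of background-class genes sharing a latent per-tissue
  profile broadcast to replicates plus per-sample noise. The profile is a
  seeded permutation of an evenly spaced log2 ladder (1 to 7), which fixes
  the cross-tissue variance and therefore guarantees — for every module, not
  just on average — that pairwise Spearman correlations exceed the 0.85
  threshold in expectation at the default noise (expected r about 0.98 at
  noise_sd 0.25).
* Ages: HK genes draw stages with weights proportional to (9 - s)^2 (old-
  biased), TE genes proportional to s^2 (young-biased), background uniform;
  module genes take their module's planted stage; the clade within a stage
  is uniform. The old-HK / young-TE bias makes the synthetic cumulative
  curves separate the way the real HK/TE profiles do.
* Taxonomy: the lineage (default 31 clades, root age 4,000 Mya, strictly
  decreasing Dirichlet-spaced ages) is embedded in a tree with
  `species_per_clade` off-path leaf species per non-focal clade. Ortholog
  groups contain the focal species, at least one species attached at the
  planted clade, and a random sprinkle of species attached strictly below
  it — so the group LCA equals the planted clade exactly and planted-age
  recovery is a sharp round-trip, not a statistical one.

What the generator does **not** emulate: read counts or FPKM estimation
noise, correlated tissue blocks (each tissue profile is independent),
annotation structure, gene length or GC effects, or the heavy right tail of
real FPKM distributions. Passing tests therefore demonstrate correctness of
the pipeline's logic and calibration of its statistics under a clean
generative model — not performance on real compendium data.

## Problem sizes and defaults

| Parameter | Default | Notes |
|---|---|---|
| FPKM expression threshold | 1.0 | "equal or higher" boundary is inclusive |
| TE tissue maximum | 3 | physiologically related tissues share genes |
| Spearman edge threshold r_min | 0.85 | one-sided (positive) |
| Validation iterations | 100 | pass-all-100 rule |
| Replicates per subsample | 2 | per tissue |
| Minimum component size | 5 | network subset for module detection |
| MCODE | degree 2, cutoff 0.2, 2-core, haircut | published defaults |
| Simulated design | 10 tissues x 3 reps, 2,000 genes | keeps a full run in seconds-to-minutes |
| noise_sd | 0.25 | log2-scale replicate noise |

The default simulated design (10 tissues rather than 32, 2,000 genes rather
than ~18,500) is the package's own choice of a desk-scale study; 32-tissue
configurations are supported through `SimulationConfig`.

## Out of scope / known limitations

The magnitudes of the real compendium analysis — 18,545 expressed genes from
E-MTAB-2836, the 8,961 / 7,668 / 2,459 ubiquitous-and-TE class counts, the
2,298-node / 20,005-edge validated network and its 1,691 / 19,615 displayed
subset, and the observed 1.61 log2 HK-TE mean difference — are **not**
reproduced and are not targets: they require the real expression study
(ArrayExpress E-MTAB-2836) and a contemporaneous OMA ortholog release.
The package instead verifies the arithmetic those figures rest on (stage
percentages from printed counts, the overlap odds ratio from printed set
sizes) and the behaviour of every procedure on planted synthetic data.
Functional-enrichment results are framework-level: no GO/KEGG snapshots are
shipped, so term-for-term agreement with any specific annotation service is
out of scope. Hierarchical clustering defaults to complete linkage (the
`hclust` default); average linkage is available. The ambiguous "mean FPKM
>= 1 in all selected tissues" retention rule is implemented with both
readings (`rule="any_tissue"`, the default, and `rule="all_tissues"`); the
any-tissue reading is the default because the all-tissue reading would make
every retained gene ubiquitous, contradicting the observed per-tissue
expression spectrum.
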