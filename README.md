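# woundchrom

Integrative RNA-seq/ChIP-seq analysis of how histone-mark chromatin states
shape wound-induced transcription, built for plant wounding time courses
(e.g. *Arabidopsis* root explants) and validated end-to-end on synthetic
data with planted ground truth.

Wounding triggers a transcriptional reprogramming in which thousands of
genes are induced or repressed within hours. Whether a gene responds — and
how fast — depends on its chromatin state before the wound (permissive
H3K9/14ac, H3K27ac, H3K4me3, H3K36me3; repressive Polycomb H3K27me3) and on
the marking changes that follow. `woundchrom` implements the complete
analysis chain that links the two:

- **Differential expression** per post-wounding time *t* vs 0 h: TMM
  library normalization, a conditional negative-binomial exact test (the
  two group sums, conditioned on their total, follow a beta-binomial
  BB(s, n₁/φ, n₂/φ) law), BH FDR per contrast. Wound-responsive genes
  satisfy |FC| > 1.5 and FDR < 0.001 at ≥ 1 time point.
- **Timing clusters**: k-means (k = 8) on mean-centered log₂ profiles of
  induced genes, relabelled 1…8 from earliest to latest induction by the
  centroid half-maximum time.
- **Chromatin states**: a gene is *marked* when a significant peak
  (Q < 0.001) overlaps its analysis window (strand-aware 1-kb promoter +
  gene body) in **both** ChIP replicates; its *level* is mark read depth /
  histone H3 depth over the same window.
- **Differential marking**: per mark and time, M = log₂(level_t/level₀) and
  A = mean log₂ level; a robust (Tukey-bisquare) line fitted on anchor
  genes (marked at both times) recenters M, and |M′| > 0.15 calls a gain or
  loss — the MAnorm-style rescaling translated to gene space.
- **Enrichment statistics**: representation factors
  RF = (k/n)/(K/N) with both one-sided hypergeometric tails, co-marking
  (bivalency) enrichment among marked genes, per-cluster category
  enrichment, Wilcoxon level comparisons, generic term enrichment.
- **Timing integration**: rank-LOESS of induction timing on pre-wound mark
  level, PCA of level ranks vs timing, acetylation-history categories, and
  the precedence tally of genes gaining H3K9/14ac before vs after H3K4me3.
- **Treatment mode**: the same DE + marking machinery applied
  treated-vs-control per matched time point (e.g. a
  histone-acetyltransferase inhibitor arm), ending in the triple overlap
  wound-induced × treatment-down × acetylation-decreased.

The synthetic-data generator (`woundchrom.simulate`) is first-class, tested
code: it plants six gene classes (pre-acetylated rapid responders, slow
gainers whose H3K9/14ac arrives one time step before H3K4me3, inducible
bivalent PRC2 targets, silent PRC2-only genes, repressed acetylation
losers, stable genes) and emits a file-backed dataset — BED6 genes,
narrowPeak calls per mark/time/replicate, coverage and count TSVs, a truth
table — that is byte-identical across runs at the same seed.

## Worked example

```sh
python analysis/01_simulate_dataset.py        # control + inhibitor arms
python analysis/02_differential_expression.py
python analysis/03_prewound_states.py
python analysis/04_differential_marking.py
python analysis/05_timing_integration.py
python analysis/06_treatment_contrast.py
```

At the default conditions (2000 genes, seed 17) this prints, among others:

```
386 wound-induced and 265 wound-repressed genes (FC > 1.5, FDR < 0.001 at >= 1 time point)
bivalent (H3K27me3 + >= 1 active mark): 110 of 427 PRC2-target genes (26%)
rank-LOESS Spearman rho(H3K9_14ac level, timing cluster) = -0.611
precedence: 197 genes gain H3K9/14ac before H3K4me3, 0 the reverse
295 of 386 wound-induced genes (76%) gain H3K9/14ac, H3K27ac and/or H3K4me3
triple overlap (wound-induced x inhibitor-down x ac-decreased): 173 genes (of 386 wound-induced)
```

Reading the numbers: the planted structure is recovered — genes with high
pre-wound H3K9/14ac are induced earliest (strongly negative rank-LOESS
rho), acetylation gains precede H3K4me3 gains essentially always in the
slow-gain class, a quarter of Polycomb targets are bivalent, and the
inhibitor arm's down-regulated genes are heavily enriched for wound-induced
genes that lose acetylation. Equivalent single commands:
`woundchrom simulate`, `woundchrom run`, `woundchrom contrast`.

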