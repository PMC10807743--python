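# lncpath

Predicting which long noncoding RNAs (lncRNAs) participate in
cytokine-response pathways, from expression and sequence.

lncRNAs regulate protein-coding genes and are strongly dysregulated in
inflammatory skin disease, but their low, tissue-specific expression makes
their functions hard to assign. `lncpath` implements an expression-based
functional-inference pipeline for this problem:

1. **Catalog merging** — combine gene annotations from several GTF sources,
   adding a gene only when none of its exons overlaps an exon already in
   the reference.
2. **Differential expression** — log2-CPM normalization and per-gene OLS
   tests, calling genes with |log2FC| ≥ 1 and Benjamini–Hochberg FDR ≤ 0.05.
3. **Positive-unlabeled pathway prediction** — genes as instances, samples
   as features (rank inverse-normalized). Pathway-member coding genes are
   positives, other coding genes negatives, lncRNAs scored but never
   trained on. The classifier is a *balanced random forest*: every tree
   trains on all positives plus an equal-size negative subsample, and a
   gene's score is the fraction of trees voting positive, averaged over
   repeated trials. Cutoffs come from the F1-maximizing score threshold on
   the labeled genes, minus 0.01.
4. **k-mer clustering** — standardized 6-mer profiles, a Pearson-threshold
   adjacency graph, Louvain communities, and Fisher enrichment of predicted
   lncRNA sets within communities.
5. **Statistics** — exact Fisher tests with sample odds ratios,
   Spearman/Pearson, Wilcoxon tests, Bonferroni, and genomic
   nearest-feature distances.

A synthetic-data module generates catalogs, counts, gene sets, sequences
and interval tracks with planted ground truth, so the full pipeline is
testable without any downloads.

## Worked example

`examples/04_predict_pathways.py` simulates 800 coding genes and 200
lncRNAs with one pathway (80 members, 30 planted lncRNAs, effect size 2,
50 samples), then trains, calibrates and calls:

```
10-fold CV pooled AUROC (coding genes): 1.000
max F = 1.000, applied threshold = 0.722
lncRNAs called for IFNG: 25 of 200
planted-lncRNA recall: 0.83; enrichment of planted among called: OR = inf, p = 3.2e-27
```

The AUROC says pathway members are cleanly separable from other coding
genes on this simulation; the threshold is the F1-optimal score cutoff
(computed from held-out scores of the labeled genes) minus 0.01; the
called set of 25 lncRNAs recovers 83% of the planted ones and contains no
false positives (infinite odds ratio). The other examples demonstrate
catalog merging, the generator, differential expression and k-mer
clustering the same way, each printing what it computes.

The `lncpath` console script exposes the same stages as thin subcommands
(`merge`, `de`, `predict`, `kmer`, `run`), with `run` driving the full
pipeline from a YAML config and writing a reproducibility manifest.

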