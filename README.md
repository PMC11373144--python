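# promsplice

Genome-wide analysis linking transcription-factor occupancy of promoter open
chromatin to the splicing pattern of the downstream **first cassette exon**.

Alternative splicing is usually studied from sequence around the spliced exon
itself. `promsplice` implements the complementary question: do the
transcription-factor binding sites (TFBSs) sitting in a gene's promoter —
restricted to open chromatin and to TFs actually expressed in a tissue —
carry information about whether that gene's first cassette exon is included
(PSI > 0.8) or skipped (PSI < 0.2), and about how its usage shifts between
tissues? It is aimed at computational biologists who want a tested,
end-to-end reference for this promoter-centric analysis, together with a
synthetic-data generator that plants a known promoter→splicing signal so
every stage can be validated against ground truth.

## The analysis

1. **Occupancy encoding** (`motifscan`, `occupancy`). Promoter windows
   ([−2000, +500) around the TSS) are scanned with JASPAR-style PWMs; a
   window is a hit when P(score ≥ s) < 10⁻³ under the background model
   (computed exactly by a lattice dynamic program). Hits are kept only when
   fully inside an open-chromatin peak, and only for TFs with TPM > 1 in the
   tissue. Each (gene, tissue) yields a binary per-TF vector and a binary
   2500 × n_TF positional matrix. Expression specificity uses the tau index,
   τ = Σᵢ(1 − x̂ᵢ)/(n − 1), x̂ᵢ = xᵢ/max xᵢ, with τ ≥ 0.8 called
   tissue-specific.
2. **Splicing representation** (`splicing`). Genes with PSI range > 0.2 in
   ≥ 3 tissues are standardised per gene (Z_Ψ); the top/bottom 20 % of each
   gene's Z_Ψ are the high/low **splicing phases**. For every unordered
   tissue pair, the XOR of the two occupancy encodings (ΔTFα / ΔData)
   together with |ΔZ_Ψ| forms a **delta event**, labelled *concordance*
   (same phase) or *discordance* (phase change).
3. **Enrichment** (`association`). Per-TF 2×2 tables (occupancy change ×
   phase change, or TFBS presence × splice form) with odds ratios
   (Haldane–Anscombe 0.5 for empty cells), Pearson χ² (df = 1), and
   Bonferroni-adjusted p (significant < 10⁻³).
4. **Classifiers** (`models`). Logistic regression, gradient-boosted trees
   (max depth 6, η = 1), a 512/256/128 dense network, and a 1-D CNN
   (conv → ReLU → maxpool(10, 10) → two 128-unit dense blocks, dropout 25 %,
   sigmoid output), all behind a class-balanced sampler. The neural networks
   are a compact in-package numpy implementation (Adam, binary
   cross-entropy, deterministic per seed).
5. **Evaluation** (`evaluation`). Event-wise (10 % holdout + 10-fold CV),
   tissue-wise (leave-one-tissue-out with *identical-feature
   decontamination*), and gene-wise (90/10 by gene) splits; F1, AUROC,
   AUPRC, accuracy; per-(tissue, gene-group) accuracy breakdown
   (one-sided / both-sided / singleton genes).
6. **Importance** (`importance`). Zero-out occlusion: N_changed/N_total per
   TF, IQR outlier calling (Q3 + 1.5·IQR), and a Wilcoxon rank-sum test
   comparing |ΔZ_Ψ| of knockdown target vs non-target genes.
7. **Synthetic studies** (`synthetic_data`, `pipeline`). A generator that
   emits sequences, peaks, motifs, TPM and PSI with bimodal PSI, largely
   tissue-conserved occupancy, planted causal TFs (optionally acting only
   near the TSS), singleton genes, and an in-silico shRNA knockdown.

## Worked example

```python
from promsplice import pipeline
from promsplice.synthetic_data import SimConfig, generate_dataset

bundle = generate_dataset(SimConfig(
    n_genes=500, n_tissues=10, n_tfs=50, n_causal_tfs=5,
    effect_size=2.0, seed=1,
))
events, zpsi = pipeline.delta_events(bundle)
result = pipeline.delta_association(events, sorted(bundle.tf_ids))
top = result.sort_values("adj_pvalue").head(5)
print(top[["a", "b", "c", "d", "odds_ratio", "adj_pvalue"]])
print("planted causal TFs:", sorted(bundle.truth["causal_tfs"]))
```

```
        a  b    c    d  odds_ratio  adj_pvalue
tf
TF026  56  3  300  153    9.520000    0.000334
TF034  55  3  301  153    9.318937    0.000440
TF006  61  6  295  150    5.169492    0.002032
TF019  47  7  309  149    3.237633    0.156314
TF003   7  4  349  152    0.762178    1.000000
planted causal TFs: ['TF006', 'TF019', 'TF026', 'TF034', 'TF047']
```

Reading the table: for TF026, 56 delta events changed its occupancy *and*
changed splicing phase against 3 that changed occupancy without a phase
change — an odds ratio of 9.5 over the unchanged background, Bonferroni
significant at adjusted p < 10⁻³. The four smallest adjusted p-values are
all planted causal TFs; the fifth (TF047) is missed on this seed because
its occupancy happens to vary in too few events to test. Across ten seeds,
all five causal TFs land inside the top ten in at least eight — the rate
the acceptance study quantifies.

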