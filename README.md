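# allomix

Does briefly pooling PBMCs from unrelated donors — as every
donor-multiplexed single-cell RNA-seq experiment does — trigger a
detectable alloreactive transcriptional response?  `allomix` implements
the complete analysis needed to answer that question and to audit the
multiplexing workflow itself:

* **Sample-tag demultiplexing** — Hamming-corrected barcode counting, a
  deterministic mode-seeking threshold classifier (donor / Doublet /
  Negative), concordance metrics against external donor assignments,
  and per-cell-type classification-bias tables.
* **QC and annotation** — UMI filters (cells < 250 UMIs, genes < 3
  UMIs), median-depth log2 normalization, PCA/UMAP embedding, and
  marker-rule annotation of PBMC types and CD4 T subtypes
  (SELL / S100A4 / GPR183 high–low patterns).
* **Composition testing** — pairwise chi-square tests of cell-type
  proportions between donor/lane groups (Yates correction, Holm
  adjustment).
* **Mixing-effect test** — the core contribution: repeated balanced
  subsampling of each cell type across groups, per-subsample 2-D
  embedding, group-wise kernel density estimation on a shared grid,
  pairwise Jensen–Shannon divergence (base 2, min-max scaled), and a
  donor-label permutation null with a conservative verdict rule.
* **Synthetic data** — a negative-binomial multi-donor PBMC generator
  reproducing the four-lane mixing design (lane 1 = donor A unmixed,
  lane 2 = A–D, lane 3 = A–H, lane 4 = donor A technical replicate),
  with donor-specific expression offsets, marker structure, tag counts
  with cell-type-dependent capture efficiency, and an optional injected
  alloreactivity signature as a positive control.

## The statistic

For groups *i*, *j* of one cell type, with kernel density estimates
*P*, *Q* on a shared 2-D grid:

    JSD(P, Q) = 1/2 KL(P || M) + 1/2 KL(Q || M),   M = (P + Q)/2,  log base 2

Per iteration the pairwise JSD matrix over all donor/lane groups is
min-max scaled to [0, 1]; summaries are means over (default) 100
balanced-subsample iterations for three contrasts: inter-donor
(A1 vs B2/B3/C2/C3), mixing status (A1/A4 vs A2/A3), technical
(A1 vs A4).  A mixing effect is declared only when

    mean(mixing JSD) − mean(technical JSD)  >  mean + 1 SD of permuted JSD scores

where the permuted scores recompute the mixing contrast after shuffling
donor A's lane labels.  See `docs/methods.md` for the full model.

## Worked example

```python
from allomix.pipeline import mixing_study

out = mixing_study(seed=1, n_iterations=20, n_permutations=20)
print(out["jsd_summary"].round(4).to_string(index=False))
for ct in sorted(out["verdicts"]):
    print(ct, round(out["observed_diff"][ct], 4), out["verdicts"][ct])
```

prints (exact output for seed 1):

```
    cell_type  comparison   mean     sd
            B inter_donor 0.9255 0.0153
            B      mixing 0.0153 0.0059
            B   technical 0.0119 0.0070
CD14 Monocyte inter_donor 0.8910 0.0077
CD14 Monocyte      mixing 0.0130 0.0028
CD14 Monocyte   technical 0.0015 0.0021
        CD4 T inter_donor 0.9378 0.0089
        CD4 T      mixing 0.0077 0.0027
        CD4 T   technical 0.0095 0.0064
        CD8 T inter_donor 0.9436 0.0080
        CD8 T      mixing 0.0127 0.0030
        CD8 T   technical 0.0325 0.0060
           NK inter_donor 0.9013 0.0136
           NK      mixing 0.0338 0.0087
           NK   technical 0.0089 0.0096

B 0.0034 not significant
CD14 Monocyte 0.0116 not significant
CD4 T -0.0018 not significant
CD8 T -0.0198 not significant
NK 0.0249 not significant
```

Inter-donor divergence (~0.9 after scaling) towers over both the mixing
and technical contrasts (~0.01–0.03), and no cell type's mixing
differential beats the permutation threshold: with no injected effect,
mixed and unmixed donor A cells are indistinguishable beyond technical
noise.  Passing `allo_effect=AlloEffectSpec(...)` injects a fold-4
signature into mixed-lane CD4 T cells and flips the CD4 verdict to
`significant mixing effect`.

The same pipeline runs from the shell:

```bash
allomix simulate --seed 1 --out sim/
allomix demux --tags sim/tag_counts.csv --whitelist sim/whitelist.csv --out demux/
allomix run --seed 1 --iterations 20 --permutations 20 \
            --annotation-source truth --out run1/
```

Real 10x-style matrices (MTX + features/barcodes TSVs) plus a tag-count
CSV are analysed with `allomix run-real`; external donor assignments
(e.g. from in-silico genotyping) can be supplied for concordance.

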