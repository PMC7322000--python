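# retroquant

Quantitative analytics for DNA-methylation-directed silencing of
retrotransposons. In mouse embryonic stem cells, methylated retroelement
promoters and imprinting control regions (ICRs) recruit the corepressor
TRIM28 together with O-GlcNAcylated chromatin factors; removing either DNA
methylation or the O-GlcNAc mark reactivates IAP-type endogenous
retroviruses. `retroquant` implements the three measurement procedures
such a study rests on, as a tested, reusable library:

1. **Interaction screen** — ranking proteins by methylation-dependent
   association from two-condition unique-peptide counts, with the
   pseudocounted ratio statistic

   R = (n_ref + c) / (n_cmp + c),  c = 1,

   a display filter (≥ 3 peptides) and a hit filter (> 6 peptides and
   R > 2).
2. **ChIP-seq repeat enrichment** — fragment counts per RepeatMasker-style
   repeat subfamily (midpoint assignment, duplicates removed), the
   enrichment ratio E = mean cpm(ChIP replicates) / mean cpm(input or IgG
   replicates), ICR occupancy cross-classification, and a 5′LTR–internal–
   3′LTR coverage metaprofile that exposes promoter-biased occupancy.
3. **Repeat RNA quantification** — rRNA/mRNA read filtering, FPKM
   (count × 10⁹ / (unit bp × library)), subtraction of the pooled FPKM of
   transpositionally dead DNA transposons as nonspecific background,
   rescaling to cpm, and median-of-ratios-normalized log2 fold changes
   used to call subfamily reactivation.

A synthetic-data generator plants every quantity the pipeline estimates
(per-subfamily enrichment, promoter boost, per-subfamily log2FC, the
identity of the methylation-dependent interactor) in toy genomes at desk
scale, so every stage is verifiable end to end without downloads.

## Worked example

```python
from retroquant import presets, screen, simulate_peptide_table, top_dependent

table, truth = simulate_peptide_table(presets.screen_config(0).proteomics, seed=0)
result = screen(table)          # pseudocount 1; shown >= 3 peptides; hit > 6 and R > 2
print(result.table.head(3))
print(top_dependent(result))
```

prints

```
         n_ref  n_cmp      ratio  log2_ratio  shown    hit  rank
protein
OGT         21      0  22.000000    4.459432   True   True     1
BG21         5      3   1.500000    0.584963   True  False     2
BG27         7      5   1.333333    0.415037   True  False     3

{'protein': 'OGT', 'ratio': 22.0, 'runner_up': 'BG21',
 'separation': 14.67, 'clear_top': True, 'margin': 2.0}
```

The planted interactor (here named OGT, detected by 21 peptides in
methylated cells and 0 after demethylation) ranks first with a 14.7-fold
separation from the best background protein — a "clear top" by the
two-fold-margin criterion. The scripts in `examples/` walk through the
other capabilities the same way: `02_chip_enrichment.py` recovers a
planted 4-fold subfamily enrichment as E ≈ 3.84 (the small deficit is the
composition effect of normalizing both samples to fixed depth),
`03_ltr_metaprofile.py` recovers a planted 3× promoter boost as a 5′/3′
LTR contrast ≈ 2.8, and `04_rna_reactivation.py` calls exactly the one
subfamily whose reactivation was planted.

## Command line

A thin CLI wraps the library for shell use:

```sh
retroquant run-all --preset demo --seed 7 --outdir runs/demo
retroquant simulate --preset icr --seed 1 --outdir runs/icr
retroquant chip-enrich --outdir runs/icr --tau 1.5
retroquant screen --outdir runs/demo
```

Runs are driven by one seed expanded into per-stage substreams; each
output directory receives the verbatim run config and a SHA-256 checksum
manifest, and re-running any stage on saved intermediates reproduces the
end-to-end result byte for byte. YAML configs are validated strictly
(unknown keys are rejected by name).

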