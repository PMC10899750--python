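# dicerscan

Analysis toolkit for high-throughput dicing assays of two-loop shRNA
libraries: from (synthetic) OS/DC/SC sequencing reads to per-variant
DICER cleavage-site calls, efficiency/accuracy scores, 6-symbol
structure classes, mWCU/YCR motif scores and pre-miRNA applications
(SNP score deltas, upstream motif enrichment, isomiR DCx
classification). A built-in simulator embodies the two-motif cleavage
model so every stage is testable offline.

## Modules

| Module | What it does |
| --- | --- |
| `dicerscan.synthetic_data` | Enumerates the randomized hairpin library (six 3-bp windows on pair positions 14–21; 4,096 variants per group, 23,296 unique overall), simulates cleavage under a multinomial site model with enzyme-gated mWCU/YCR effects (WT, dsRBD_del, R1855A, E1859A), and emits OS/DC/SC FASTQ plus ground truth. |
| `dicerscan.read_processing` | Adapter stripping, terminal-UMI trimming, duplicate collapsing, 32N-barcode splitting, the unique FL-OS/32N dictionary, perfect-match reference assignment, CPM. |
| `dicerscan.cleavage_mapping` | Local-alignment product localization and (x, y) → mode/site classification (DC at x when y = 72 − x; Other; 5′-SC; 3′-SC at 72 − y). |
| `dicerscan.scoring` | log2 efficiency scores with the 0.1 pseudocount, per-site accuracy (NP/∑NP), log2(DC/SC), Cohen's d with √(SD1²/2 + SD2²/2) pooling, replicate averaging. |
| `dicerscan.structure_annotation` | Dot-bracket → L/b/M/A/B/T positional code, stem length (b + M on the 5′ strand), ≥50-variant structure-class selection, mismatch-aware pair registry. |
| `dicerscan.motif_scoring` | Per-window motif accuracies, min-max rescaling to 0–100, averaged mWCU/YCR scores (with the two-window YCR fallback), top-percentile composition, class predicates. |
| `dicerscan.premirna_analysis` | Cleavage sites from mature-arm annotations (2-nt overhang geometry), positional score assignment, SNP |Δ| ≥ 20 selection, 1–5 / 1–7 nt upstream enrichment windows, DCx isomiR calls with >10-read and >5 %-DC filters. |
| `dicerscan.pipeline` | Glue: three FASTQ libraries → score table for one replicate. |

Folding is delegated: structure and pre-miRNA modules consume
dot-bracket strings from any MFE folder (RNAfold output works
directly); the simulator provides a design-based pairing model so the
test suite needs no folder.

## CLI

```sh
# emit a synthetic run (OS/DC/SC FASTQ + ground truth)
dicerscan simulate --seed 7 --out sim/ --n-variants 200 --n-reads 2000

# process one replicate into a per-variant score table
dicerscan process --os-fastq sim/os.fastq --dc-fastq sim/dc.fastq \
    --sc-fastq sim/sc.fastq --out run1/

# motif scores from a per-variant accuracy table
dicerscan motifs --scores run1/scores_with_meta.tsv --enzyme mWCU --out mwcu.tsv

# structure annotation and pre-miRNA scoring
dicerscan annotate --structures folds.tsv --out profiles.tsv
dicerscan premirna score --records premirnas.tsv --mwcu-table mwcu.tsv --out scored.tsv
```

YAML configs (`--config`) can override the library design (backbone,
windows, delimiters, UMI/adapter layout) and the cleavage model
(per-site logits, motif effect sizes, enzyme).

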