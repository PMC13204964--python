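# dualbcr

Identification and characterization of **dual BCR B cells** — B cells
that express more than one functional receptor chain configuration
through incomplete V(D)J allelic exclusion (allelic inclusion) — from
paired single-cell transcriptome (scRNA-seq) and single-cell B cell
receptor (scBCR-seq) data, of the kind produced by 10x Genomics 5'
VDJ + gene-expression assays.

The package is aimed at immunologists analysing B cell repertoires in
autoimmunity (e.g. lupus models and patients), where the proportion,
pairing types, clonality and effector profile of dual-receptor B cells
are of direct interest.

## What it computes

Starting from per-contig V(D)J annotation tables (10x
`filtered_contig_annotations.csv` or AIRR Rearrangement TSV):

1. **Functional-contig filter** — contigs must be called cells,
   high-confidence, productive, and on an immunoglobulin locus
   (IGH/IGK/IGL); barcodes with a single functional chain are dropped.
2. **Pairing classification** — each cell's chain-count triple
   (n<sub>IGH</sub>, n<sub>IGK</sub>, n<sub>IGL</sub>) maps to:
   * *single BCR* — exactly one heavy + one light chain (H+κ, H+λ);
   * *dual BCR* — ≥3 functional chains with ≥1 heavy and ≥1 light,
     reported as H+κ1+κ2, H+λ1+λ2, H+κ+λ, or "others" (multi-heavy
     configurations such as H1+H2+κ, H1+H2+κ1+κ2, …);
   * *unpairable* — no heavy or no light chain; excluded from the
     single/dual denominator.
3. **Clonotypes** — cells with identical CDR3 sequences (nucleotide by
   default, over all functional chains) form one clone; clonal
   expansion is the fraction of cells in clones of size ≥ 2.
4. **Repertoire statistics** —
   * inverse Simpson diversity `1/DS = (Σ nᵢ)² / Σ nᵢ²`,
   * Gini clonality `G = Σᵢⱼ |pᵢ − pⱼ| / (2 n² μ)` over clone
     frequencies (scale-invariant),
   * V/J gene usage at gene or subfamily resolution, with a
     sample-size-driven Pearson chi-square / Fisher's exact comparison,
   * heavy-chain isotype composition (IGHM/IGHD/IGHG/IGHA/IGHE).
5. **Compartment overlap** — unique IGH CDR3 (amino-acid) sharing
   between compartments and the Jaccard index |A∩B| / |A∪B|.
6. **Transcriptome link** — per-cell QC (200 ≤ genes ≤ 3000,
   counts ≥ 1000, mitochondrial fraction ≤ 5%), log-normalization
   (`ln(1 + 10⁴·count/total)`), marker-score B subset labels (Naive_B,
   Memory_B, Breg, Plasma), the barcode join between RNA and VDJ cells,
   and Wilcoxon rank-sum differential expression with
   Benjamini–Hochberg correction (significant: adjusted p < 0.05 and
   |log₂FC| > 0.5).

A synthetic-data module generates contig tables and expression
matrices with known ground truth (dual fraction, pairing mix, clone
sizes, planted markers and differential genes) so the whole pipeline is
testable without sequencing data.

## Worked example

```python
from dualbcr import (SimConfig, simulate_repertoire,
                     filter_functional_contigs, group_cells,
                     classify_pairing, summarize_pairing,
                     assign_clonotypes, expansion_stats, CloneSizeVector,
                     inverse_simpson, gini_index)

cfg = SimConfig(n_cells=2000, seed=42, dual_fraction=0.09)
table, truth = simulate_repertoire(cfg)

filtered, log = filter_functional_contigs(table)
cells, n_dropped = group_cells(filtered)
calls = [classify_pairing(c) for c in cells]
summ = summarize_pairing(calls)
```

This prints, step by step:

```
contigs: 4654
functional contigs: 4270 (removed: 85 non-cell, 85 low-confidence,
                          43 off-locus, 171 non-productive)
cells with >=2 chains: 2000 (60 single-chain barcodes dropped)
pairable cells: 1967  dual-BCR: 9.46%
dominant dual pairing H+κ1+κ2: 6.46%
clonotypes: 1776  expanded cells: 15.00%
inverse Simpson 1/DS: 1467.2  Gini: 0.0931
```

The dual-BCR estimate (9.46%) recovers the generated 9% fraction; the
dominant pairing type is H+κ1+κ2, as in real spleen repertoires; the
expansion estimate hits the generator's 15% target exactly, and the
high 1/DS with low Gini describe the mostly-singleton clone structure
of a healthy repertoire.

For real data, replace the simulation with
`read_contig_table("filtered_contig_annotations.csv", "tenx_csv", sample_id=...)`,
or drive everything from the shell:

```sh
dualbcr simulate --seed 7 --out sim/
dualbcr classify --contigs sim/contigs.csv:s1 --out calls/
dualbcr stats --calls calls/calls.tsv --chains calls/chains.tsv --out stats/
dualbcr run --config run.yaml        # full multi-sample pipeline
```

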