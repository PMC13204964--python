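# Methods

## Scope and model

`dualbcr` operationalizes the identification of dual-receptor B cells
from droplet-based single-cell V(D)J data. The underlying biological
model is allelic inclusion: incomplete allelic exclusion during V(D)J
recombination leaves a minority of peripheral B cells transcribing more
than one productively rearranged heavy or light chain. At the mRNA
level such cells present as barcodes carrying three or more functional
immunoglobulin contigs. The package's unit of analysis is therefore the
cell barcode and its multiset of functional chains; no protein-level
co-expression is inferred, and the well-known caveat applies that mRNA
detection of a second rearrangement does not prove surface expression
of two receptors.

### Contig filter

A contig is *functional* when all four predicates hold: `is_cell` true,
`high_confidence` true, `productive` true, and the chain is IGH, IGK or
IGL. Flags parse ternary (true/false/unknown): Cell Ranger emits
"None" for uncalled columns and "Non" for some productivity values,
and both are treated as failing their rule rather than being coerced at
parse time. The filter attributes each removal to the first failing
rule in the fixed order (cell call → confidence → locus → productivity)
so that attrition reports are additive; the filter is idempotent.
Barcodes retaining a single functional chain cannot be
pairing-classified and are dropped (counted separately).

### Pairing classification

Classification is a pure function of the chain-count triple
(n_IGH, n_IGK, n_IGL):

| condition | class | reported as |
|---|---|---|
| no heavy, or no light | unpairable | (own column) |
| exactly H + one light | single | H+κ or H+λ |
| ≥3 chains, ≥1 H, ≥1 light | dual | H+κ1+κ2 / H+λ1+λ2 / H+κ+λ / others |

"Can pair and assemble" is operationalized as requiring at least one
heavy and one light chain; two-chain cells failing this (κ+κ, H+H,
κ+λ) are unpairable and excluded from the single/dual denominator,
since a surface receptor cannot form without both chains. Any dual
configuration outside the three named codes — all multi-heavy
configurations (2H1K, 2H2K, 2H1K1L, …) and single-heavy cells with ≥3
copies of one light chain (1H3K) — is reported as "others", with the
exact fine code (e.g. `2H1K1L`) always preserved alongside. Every
retained chain counts equally; no UMI ranking enters classification,
because the classifier counts rearrangements, not expression levels.

Proportions are reported over pairable cells (single + dual);
unpairable cells appear in their own column. The classifier is verified
against an exhaustive, independently coded truth table over all triples
with 2–5 total chains.

### Clonotypes

Cells with identical CDR3 sequences form one clonotype. The key is the
lexicographically sorted join of `chain:cdr3` pairs, making assignment
invariant to input order and within-cell chain order. Defaults follow
the two conventions in use: *nucleotide* CDR3 over *all* functional
chains for clonotype assignment and expansion/diversity, *amino-acid*
CDR3 for the Gini statistic and overlap; both level (nt/aa) and scope
(all chains / IGH only) are arguments. Cells with an empty CDR3 on any
in-scope chain are excluded from clonotyping and counted. Clonal
expansion is the fraction of cells in clones of size ≥ 2.

### Repertoire statistics

* **Inverse Simpson** `1/DS = (Σ nᵢ)² / Σ nᵢ²` over clone sizes; equals
  the clone count under perfect evenness, 1 for a monoclonal
  compartment.
* **Gini** `G = Σᵢⱼ |pᵢ − pⱼ| / (2 n² μ)` over clone frequencies, with
  μ the mean frequency. Computed via the sorted-vector identity
  `Σᵢⱼ|pᵢ−pⱼ| = 2 Σᵢ (2i−n−1) p₍ᵢ₎` (O(n log n)), which tests verify
  equals the brute-force double loop to 1e-12. Frequencies default to
  absolute clone counts; the statistic is scale-invariant, so counts
  and normalized proportions give identical values (asserted by test).
* **Gene usage** counts each retained chain's call (a two-heavy cell
  contributes two IGH calls; a per-cell mode is available). Family
  resolution strips the IMGT allele suffix (`*01`), upper-cases (mouse
  symbols are mixed-case), and truncates at the first hyphen
  (`Ighv1-85 → IGHV1`).
* **Isotypes** collapse constant-gene subclasses
  (Ighg1/2a/2b/2c/3, IGHG1-4 → IGHG); for multi-heavy cells the
  highest-UMI chain decides, UMI ties breaking to the lexicographically
  smallest constant-gene name for determinism.
* **Proportion tests** follow a sample-size rule: Pearson chi-square
  (no continuity correction) when total n ≥ 40 and every expected count
  is ≥ 5, Fisher's exact otherwise. The regime 1 ≤ min-expected < 5
  with n ≥ 40 is assigned to Fisher's exact as the conservative choice.
  For tables wider than 2×2 where the exact branch fires, no closed-form
  Freeman–Halton implementation is available in the scientific Python
  stack, so the p-value is estimated by Monte-Carlo sampling of
  fixed-margin tables (`scipy.stats.random_table`, 20 000 resamples,
  fixed internal seed, +1-corrected) — repeated calls are
  deterministic.

### Overlap

The unit of sharing is the unique CDR3 sequence (default: IGH,
amino-acid), not the cell; a dual cell with two heavy chains
contributes both sequences to its compartment's set. Reported per pair:
unique counts, intersection size, Jaccard `|A∩B|/|A∪B|`, and the shared
sequences with each side's carrying-cell counts, flagged when either
side's count is ≥ 2 (sharing that involves clonal expansion).

### Transcriptome link

QC keeps cells with 200 ≤ detected genes ≤ 3000, total counts ≥ 1000
and mitochondrial fraction ≤ 5%; the 5% boundary itself passes, and the
comparison is exact integer arithmetic (`20·mito ≤ total`) so boundary
cells are never lost to float rounding. Mitochondrial genes are matched
by prefix (`mt-` mouse, `MT-` human). Normalization is
`ln(1 + 10⁴ · count / cell_total)`.

Subset labels replace graph clustering + reference annotation with a
direct marker-score arg-max: the score of a subset is the mean
normalized expression of its markers (Naive_B: Cd19, Ighd; Memory_B:
Cd19, Cd40, Tnfrsf13b, Aim2; Breg: Cd19, Il10; Plasma: Cd19, Jchain,
Xbp1). Cells with zero Cd19 are unassigned (not B-lineage-assignable),
as are exact score ties — a strict arg-max with no margin, chosen for
determinism. This is adequate where the final subsets are *defined* by
those markers; it does not reproduce de-novo cluster discovery.

The RNA↔VDJ join is an inner join on barcode with an optional
suffix-stripping normalizer (`-1`-style GEM suffixes sometimes differ
between processing chains); a zero-overlap join is a hard error that
suggests the normalizer. Differential expression per gene: genes
expressed in ≥10% of either group and passing a |log₂FC| ≥ 0.25 screen
are tested by Wilcoxon rank-sum; BH adjustment runs over the tested
genes; significance requires adjusted p < 0.05 and |log₂FC| > 0.5.
log₂FC compares group means of the de-logged normalized expression with
pseudocount 1 — the dominant single-cell convention; the pseudocount is
an argument.

## Synthetic data: what it emulates, and what it does not

The generator produces, per sample: a contig table whose cells carry
chain multisets drawn from a configurable dual fraction (default 0.09)
and pairing mix (H+κ1+κ2 dominant at 0.72 of dual cells, multi-heavy
codes 0.18, H+κ+λ 0.08, minor λ codes the rest), an unpairable fraction
(0.02), single-chain barcodes (0.03) and contaminant contigs carrying
each failing QC flag (rates 0.01–0.04) — so every filter rule is
exercised. Clone sizes come from a geometric law (p = 0.5, support ≥2)
truncated to hit an expanded-cells target (default 0.15) exactly, with
the remainder singletons; clone members share all CDR3s and gene calls.
CDR3s are random stop-free codon strings of 30–60 nt, translated for
the amino-acid level. Class draws are i.i.d. per cell, so realized
dual counts are exactly binomial — which is what makes the
binomial-interval recovery checks in the tests well-calibrated. A
configurable fraction of dual clones (default 0.05) copies a heavy CDR3
from a single-BCR clone, planting the single/dual sharing that the
overlap module measures.

The expression model is negative-binomial (dispersion 2 for background
genes, 10 for markers — cell-type-defining genes are consistently
detected, which is what makes them usable markers) around per-gene
means drawn once per *study* from a shared panel seed, so multi-sample
comparisons are not confounded by panel resampling. Markers are set to
mean 12 in their subset against a 0.05 background, Cd19 to 4
everywhere; planted differential genes are multiplied by the effect
size (default 2.5×, 20 genes) in the disease group; mitochondrial
pseudo-genes are drawn Poisson at a 2% target fraction, with planted
high-mito cells forced above — and all others below — the 5% QC
boundary by integer adjustment, so boundary behavior is deterministic.

Not emulated: real germline V/D/J sequence content, somatic
hypermutation, isotype–subset coupling, doublets, ambient RNA, batch
effects, or biologically structured co-expression. Passing tests
therefore demonstrate the *pipeline's* correctness on data with the
assumed statistical structure, not robustness to every artefact of real
droplet data.

## Problem sizes and numerical choices

Tests run the generator at 300–5000 cells; the study-scale recovery
check uses 5000 cells, where binomial 99% intervals around the
generated fractions are a few tenths of a percentage point wide. The
acceptance script simulates 2 groups × 2 samples × 1200 cells with a
~630-gene panel, sizes at which the full pipeline (including DE and
overlap) completes in well under a minute while keeping per-compartment
cell counts in the hundreds. Summary tables serialize floats with
`%.10g`, which round-trips all reported statistics and keeps repeated
runs byte-identical; the manifest contains no timestamps for the same
reason. Clone identifiers are assigned in lexicographic key order, and
all tie-breaks in the package (clone keys, isotype UMI ties, subset
score ties) are resolved deterministically.

## Known limitations

* Dual-BCR identification from mRNA overcounts surface-level dual
  expression and is sensitive to upstream cell-calling; the unpairable
  category absorbs some real doublets but no doublet caller is
  included.
* The marker-score annotator cannot discover subsets beyond its marker
  table and leaves low-depth cells unassigned.
* The Monte-Carlo exact test for wide tables has resampling error of
  order 1/√20000 ≈ 0.007 on p; for borderline decisions at α = 0.05
  this is visible in the third decimal.
* Group-level statistics are offered both pooled and as per-subject
  mean ± sd; with 2–3 subjects per group, the sd is descriptive, not
  inferential.
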