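"""Repertoire-level statistics for classified B cell compartments.

Implements the diversity and clonality measures used to compare single
and dual BCR B cells:

* **inverse Simpson diversity** ``1/DS = (Σ n_i)² / Σ n_i²`` over clone
  sizes ``n_i``; equals the number of clones under perfect evenness and
  1 when a single clone holds every cell;
* **Gini index** ``G = Σ_{i,j} |p_i − p_j| / (2 n² μ)`` over clone
  frequencies ``p_i`` (``n`` clones, mean frequency ``μ``); 0 for a
  perfectly even repertoire, approaching 1 under extreme clonal
  dominance.  The statistic is scale-invariant, so absolute clone
  counts and normalized proportions give the same value;
* **V/J gene usage** per chain, at gene or subfamily resolution;
* a **two-group proportion test** with the sample-size-driven choice
  between Pearson's chi-square and Fisher's exact test: chi-square when
  the total count is at least 40 and every expected cell count is at
  least 5, Fisher's exact otherwise;
* **isotype composition** of heavy chains (IGHM/IGHD/IGHG/IGHA/IGHE,
  subclasses collapsed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .bcr_core import CellChainSet, PairingCall
from .io_formats import strip_allele

__all__ = [
    "CloneSizeVector",
    "ProportionTestResult",
    "ISOTYPE_CLASSES",
    "inverse_simpson",
    "gini_index",
    "gene_usage",
    "parse_gene_family",
    "compare_proportions",
    "select_test",
    "isotype_composition",
    "isotype_class",
]


@dataclass
class CloneSizeVector:
    """Clone sizes / frequencies of one compartment.

    ``counts`` holds the positive integer clone sizes; ``freqs`` holds
    the frequency values fed to the Gini formula (absolute counts by
    default — scale invariance makes the choice immaterial).
    """

    counts: np.ndarray
    freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("clone-size vector must be 1-D and non-empty")
        if (self.counts < 1).any():
            raise ValueError("clone sizes must be >= 1; filter invalid "
                             "entries before construction")
        if self.freqs is None:
            self.freqs = self.counts.copy()
        else:
            self.freqs = np.asarray(self.freqs, dtype=float)
            if (self.freqs <= 0).any():
                raise ValueError("clone frequencies must be positive")

    @property
    def n_clones(self) -> int:
        return len(self.counts)

    @property
    def total_cells(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_freq(self) -> float:
        return float(self.freqs.mean())

    @classmethod
    def from_sizes(cls, sizes) -> "CloneSizeVector":
        return cls(counts=np.asarray(sizes))


def inverse_simpson(clones: CloneSizeVector) -> float:
    """Inverse Simpson diversity ``(Σ n_i)² / Σ n_i²``."""
    n = clones.counts
    return float(n.sum() ** 2 / np.square(n).sum())


def gini_index(clones: CloneSizeVector) -> float:
    """Gini index of clone-frequency inequality.

    Equals the mean absolute difference between all ordered frequency
    pairs divided by ``2 n² μ / n²`` — computed via the sorted-vector
    identity ``Σ_{i,j}|p_i−p_j| = 2 Σ_i (2i − n − 1) p_(i)`` (1-based
    ascending order), which is O(n log n) and exactly equals the
    brute-force double loop.
    """
    p = np.sort(clones.freqs)
    n = len(p)
    if n == 1:
        return 0.0
    i = np.arange(1, n + 1)
    pairwise_sum = 2.0 * np.sum((2 * i - n - 1) * p)
    return float(pairwise_sum / (2.0 * n * n * p.mean()))


_FAMILY_RE = re.compile(r"^([A-Z0-9]+?)(?:-.*)?$")


def parse_gene_family(gene: str) -> str:
    """Collapse a V/J gene call to its subfamily.

    Strips the IMGT allele suffix, upper-cases (mouse calls are
    mixed-case, e.g. ``Ighv1-85``), then truncates at the first hyphen:
    ``Ighv1-85*01`` -> ``IGHV1``; ``IGHV4-34`` -> ``IGHV4``.  Empty
    input -> ``unknown``.
    """
    g = strip_allele(gene).upper()
    if not g:
        return "unknown"
    m = _FAMILY_RE.match(g)
    return m.group(1) if m else g


def gene_usage(cells: list[CellChainSet],
               calls: list[PairingCall],
               segment: str = "V",
               chain: str = "IGH",
               resolution: str = "family",
               compartment_of: dict[str, str] | None = None,
               per_cell: bool = False) -> pd.DataFrame:
    """V/J gene usage per compartment.

    Counts each retained chain's gene call (a two-heavy-chain cell
    contributes two IGH calls; set ``per_cell`` to count unique calls
    once per cell).  Compartments default to the pairing class
    (single/dual) from ``calls``; pass ``compartment_of`` (barcode ->
    label) to stratify differently.  Empty gene calls are binned as
    ``unknown``.

    Returns a tidy frame: compartment, gene (or family), count,
    proportion; proportions sum to 1 within each compartment.
    """
    if segment not in ("V", "J"):
        raise ValueError(f"unknown segment {segment!r}")
    if resolution not in ("family", "gene"):
        raise ValueError(f"unknown resolution {resolution!r}")
    col = "v_gene" if segment == "V" else "j_gene"
    if compartment_of is None:
        compartment_of = {c.barcode: c.bcr_class for c in calls}

    rows = []
    for cell in cells:
        label = compartment_of.get(cell.barcode)
        if label is None:
            continue
        sub = cell.chains[cell.chains["chain"] == chain]
        genes = [strip_allele(g).upper() if resolution == "gene"
                 else parse_gene_family(g)
                 for g in sub[col]]
        genes = [g if g else "unknown" for g in genes]
        if per_cell:
            genes = sorted(set(genes))
        rows.extend((label, g) for g in genes)
    if not rows:
        return pd.DataFrame(columns=["compartment", "gene", "count", "proportion"])
    df = pd.DataFrame(rows, columns=["compartment", "gene"])
    out = (df.value_counts(["compartment", "gene"]).rename("count")
           .reset_index().sort_values(["compartment", "gene"]))
    out["proportion"] = out.groupby("compartment")["count"].transform(
        lambda s: s / s.sum())
    return out.reset_index(drop=True)


@dataclass
class ProportionTestResult:
    """Outcome of the chi-square / Fisher proportion comparison."""

    statistic: float
    p_value: float
    test_used: str       # "chi2" | "fisher" | "fisher_mc" | "degenerate"
    n: int
    min_expected: float
    table: np.ndarray
    flagged: bool = False


def select_test(n: int, min_expected: float) -> str:
    """The sample-size decision rule for two-group proportion tests.

    Pearson's chi-square when the total count is >= 40 and the smallest
    expected cell count is >= 5; Fisher's exact test otherwise (this
    covers both the stated small-sample branch and the intermediate
    1 <= T_min < 5 regime, where the exact test is the conservative
    choice).
    """
    if n >= 40 and min_expected >= 5:
        return "chi2"
    return "fisher"


def _fisher_mc_pvalue(table: np.ndarray, n_resamples: int = 20000,
                      seed: int = 20_240_101) -> float:
    """Monte-Carlo Fisher p-value for tables wider than 2x2.

    Samples tables with the observed margins (multivariate
    hypergeometric null) and estimates the probability of a table at
    most as probable as the observed one, with the +1 correction so the
    estimate is never exactly 0.  The seed is fixed: repeated calls on
    the same table return the same p-value.
    """
    rng = np.random.default_rng(seed)
    dist = scipy.stats.random_table(table.sum(axis=1), table.sum(axis=0))
    logp_obs = dist.logpmf(table)
    samples = dist.rvs(n_resamples, random_state=rng)
    logp = dist.logpmf(samples)
    extreme = int(np.sum(logp <= logp_obs + 1e-9))
    return (extreme + 1) / (n_resamples + 1)


def compare_proportions(counts_a, counts_b) -> ProportionTestResult:
    """Compare two groups' category counts with the chi-square/Fisher rule.

    ``counts_a`` and ``counts_b`` are same-length vectors of
    non-negative integer counts over the same categories; they form the
    two rows of the contingency table.  Zero-margin categories are
    allowed in the input but a fully degenerate table (a zero row or a
    single non-zero column) yields a flagged, undefined result.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    table = np.vstack([a, b])
    # drop all-zero categories; they carry no information
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    n = int(table.sum())
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return ProportionTestResult(np.nan, np.nan, "degenerate", n,
                                    np.nan, table, flagged=True)
    expected = scipy.stats.contingency.expected_freq(table)
    min_expected = float(expected.min())
    rule = select_test(n, min_expected)
    if rule == "chi2":
        stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        return ProportionTestResult(float(stat), float(p), "chi2", n,
                                    min_expected, table)
    if table.shape == (2, 2):
        res = scipy.stats.fisher_exact(table)
        return ProportionTestResult(float(res.statistic), float(res.pvalue),
                                    "fisher", n, min_expected, table)
    p = _fisher_mc_pvalue(table)
    return ProportionTestResult(np.nan, p, "fisher_mc", n, min_expected, table)


ISOTYPE_CLASSES = ["IGHM", "IGHD", "IGHG", "IGHA", "IGHE", "unknown"]


def isotype_class(c_gene: str) -> str:
    """Collapse a heavy-chain constant-gene call to its isotype class.

    Case-insensitive; subclasses collapse (Ighg1/2a/2b/2c/3 and IGHG1-4
    -> IGHG).  Empty or non-IGH constant calls -> ``unknown``.
    """
    g = strip_allele(c_gene).upper()
    for cls in ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE"):
        if g.startswith(cls):
            return cls
    return "unknown"


def isotype_composition(cells: list[CellChainSet],
                        calls: list[PairingCall] | None = None,
                        compartment_of: dict[str, str] | None = None
                        ) -> pd.DataFrame:
    """Per-cell isotype class composition per compartment.

    Each cell contributes the class of its heavy chain's constant gene;
    for cells with several IGH chains the chain with the highest UMI
    count decides (UMI ties break to the lexicographically smallest
    constant-gene name).  Cells without an IGH chain are skipped.
    Proportions are over cells within the compartment and include the
    ``unknown`` class.
    """
    if compartment_of is None:
        if calls is None:
            raise ValueError("provide calls or compartment_of")
        compartment_of = {c.barcode: c.bcr_class for c in calls}
    rows = []
    for cell in cells:
        label = compartment_of.get(cell.barcode)
        if label is None:
            continue
        igh = cell.chains[cell.chains["chain"] == "IGH"]
        if len(igh) == 0:
            continue
        ranked = igh.assign(_norm=igh["c_gene"].str.upper()).sort_values(
            ["umis", "_norm"], ascending=[False, True], kind="stable")
        rows.append((label, isotype_class(ranked.iloc[0]["c_gene"])))
    if not rows:
        return pd.DataFrame(
            columns=["compartment", "isotype_class", "count", "proportion"])
    df = pd.DataFrame(rows, columns=["compartment", "isotype_class"])
    out = (df.value_counts(["compartment", "isotype_class"]).rename("count")
           .reset_index())
    out["isotype_class"] = pd.Categorical(out["isotype_class"],
                                          categories=ISOTYPE_CLASSES,
                                          ordered=True)
    out = out.sort_values(["compartment", "isotype_class"]).reset_index(drop=True)
    out["proportion"] = out.groupby("compartment", observed=True)["count"] \
        .transform(lambda s: s / s.sum())
    out["isotype_class"] = out["isotype_class"].astype(str)
    return out
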