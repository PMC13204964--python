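"""CDR3 sharing between B cell compartments.

The unit of overlap is the unique CDR3 sequence (by default heavy-chain,
amino-acid level), not the cell: a compartment's repertoire is the set
of distinct CDR3s its cells carry, and a dual-BCR cell with two heavy
chains contributes both.  Sharing between two compartments is reported
as the intersection size and the Jaccard index |A∩B| / |A∪B|, together
with the shared sequences and their clone sizes (cell counts) on each
side — shared sequences carried by a clone of size >= 2 on either side
mark sharing that involves clonally expanded cells.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .bcr_core import CellChainSet

__all__ = ["OverlapResult", "cdr3_overlap", "pairwise_overlap_matrix",
           "compartment_cdr3_counts"]


@dataclass
class OverlapResult:
    """CDR3 sharing between two compartments."""

    set_a_label: str
    set_b_label: str
    n_a: int
    n_b: int
    n_shared: int
    jaccard: float
    shared_sequences: pd.DataFrame  # cdr3, clone_size_a, clone_size_b, expanded


def compartment_cdr3_counts(cells: list[CellChainSet],
                            chain: str = "IGH",
                            level: str = "aa") -> Counter:
    """Unique CDR3s of a compartment with their cell counts.

    The count of a CDR3 is the number of cells carrying it on the given
    chain (a cell with two identical heavy CDR3s still counts once).
    """
    if level not in ("aa", "nt"):
        raise ValueError(f"unknown CDR3 level {level!r}")
    col = "cdr3_aa" if level == "aa" else "cdr3_nt"
    counts: Counter = Counter()
    for cell in cells:
        sub = cell.chains[cell.chains["chain"] == chain]
        for seq in set(sub[col]) - {""}:
            counts[seq] += 1
    return counts


def cdr3_overlap(compartment_a: list[CellChainSet],
                 compartment_b: list[CellChainSet],
                 chain: str = "IGH",
                 level: str = "aa",
                 label_a: str = "A",
                 label_b: str = "B") -> OverlapResult:
    """CDR3 sharing and Jaccard index between two compartments."""
    if not compartment_a or not compartment_b:
        raise ValueError("cdr3_overlap requires two non-empty compartments")
    counts_a = compartment_cdr3_counts(compartment_a, chain, level)
    counts_b = compartment_cdr3_counts(compartment_b, chain, level)
    shared = sorted(set(counts_a) & set(counts_b))
    union = len(set(counts_a) | set(counts_b))
    table = pd.DataFrame(
        {"cdr3": shared,
         "clone_size_a": [counts_a[s] for s in shared],
         "clone_size_b": [counts_b[s] for s in shared]})
    table["expanded"] = (table["clone_size_a"] >= 2) | (table["clone_size_b"] >= 2)
    return OverlapResult(
        set_a_label=label_a, set_b_label=label_b,
        n_a=len(counts_a), n_b=len(counts_b), n_shared=len(shared),
        jaccard=len(shared) / union if union else 0.0,
        shared_sequences=table)


def pairwise_overlap_matrix(compartments: dict[str, list[CellChainSet]],
                            chain: str = "IGH",
                            level: str = "aa"
                            ) -> tuple[pd.DataFrame, pd.DataFrame,
                                       dict[tuple[str, str], OverlapResult]]:
    """All-pairs overlap over labelled compartments.

    Returns the symmetric Jaccard matrix (diagonal 1), the symmetric
    shared-count matrix (diagonal = compartment's unique-CDR3 count),
    and the per-pair :class:`OverlapResult` objects.
    """
    labels = list(compartments)
    if len(labels) < 2:
        raise ValueError("pairwise overlap requires >= 2 compartments")
    jac = pd.DataFrame(1.0, index=labels, columns=labels)
    nsh = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    results: dict[tuple[str, str], OverlapResult] = {}
    for lab in labels:
        nsh.loc[lab, lab] = len(
            compartment_cdr3_counts(compartments[lab], chain, level))
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            res = cdr3_overlap(compartments[la], compartments[lb],
                               chain=chain, level=level,
                               label_a=la, label_b=lb)
            results[(la, lb)] = res
            jac.loc[la, lb] = jac.loc[lb, la] = res.jaccard
            nsh.loc[la, lb] = nsh.loc[lb, la] = res.n_shared
    return jac, nsh, results
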