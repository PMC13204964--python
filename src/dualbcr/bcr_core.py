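"""Contig filtering, cell assembly, BCR pairing classification, clonotypes.

The analytical unit is the cell barcode.  Contigs first pass a functional
filter (called cell, high confidence, productive, immunoglobulin locus);
barcodes with at least two retained chains become cells; each cell's
chain-count triple over (IGH, IGK, IGL) determines its pairing call:

* exactly one heavy + one light chain -> **single BCR** B cell
  (``H+κ`` or ``H+λ``);
* three or more functional chains containing at least one heavy and one
  light chain -> **dual BCR** B cell, reported as ``H+κ1+κ2``,
  ``H+λ1+λ2``, ``H+κ+λ``, or ``others`` (any configuration with two
  heavy chains, or three-plus copies of one chain);
* everything else (no heavy chain, or no light chain) cannot pair and
  assemble a receptor and is **unpairable** — counted, but excluded from
  the single/dual denominator.

Clonotypes are equivalence classes of cells with identical CDR3
sequences; by default the nucleotide CDR3s of all functional chains form
the key, with amino-acid level and IGH-only scope as options.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CONTIG_COLUMNS, ContigTable

#: column layout of the flat chain table used for stage handoff
CONTIG_FRAME_COLUMNS = CONTIG_COLUMNS + ["sample_id"]

__all__ = [
    "FUNCTIONAL_CHAINS",
    "CellChainSet",
    "PairingCall",
    "Clonotype",
    "ClonotypeAssignment",
    "FilterLog",
    "CAT_H_KAPPA",
    "CAT_H_LAMBDA",
    "CAT_H_2KAPPA",
    "CAT_H_2LAMBDA",
    "CAT_H_KAPPA_LAMBDA",
    "CAT_OTHERS",
    "REPORT_CATEGORIES",
    "filter_functional_contigs",
    "group_cells",
    "classify_pairing",
    "classify_triple",
    "summarize_pairing",
    "assign_clonotypes",
    "expansion_stats",
    "calls_frame",
]

FUNCTIONAL_CHAINS = ("IGH", "IGK", "IGL")

CAT_H_KAPPA = "H+κ"
CAT_H_LAMBDA = "H+λ"
CAT_H_2KAPPA = "H+κ1+κ2"
CAT_H_2LAMBDA = "H+λ1+λ2"
CAT_H_KAPPA_LAMBDA = "H+κ+λ"
CAT_OTHERS = "others"

#: fixed reporting order for pairing-category tables
REPORT_CATEGORIES = [
    CAT_H_KAPPA, CAT_H_LAMBDA,
    CAT_H_2KAPPA, CAT_H_2LAMBDA, CAT_H_KAPPA_LAMBDA, CAT_OTHERS,
]


@dataclass
class FilterLog:
    """Removal counts per rule of the functional-contig filter."""

    n_input: int = 0
    n_not_cell: int = 0
    n_low_confidence: int = 0
    n_bad_chain: int = 0
    n_not_productive: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class CellChainSet:
    """All retained functional chains of one barcode."""

    barcode: str
    sample_id: str
    chains: pd.DataFrame  # rows are retained ContigRecords

    @property
    def n_igh(self) -> int:
        return int((self.chains["chain"] == "IGH").sum())

    @property
    def n_igk(self) -> int:
        return int((self.chains["chain"] == "IGK").sum())

    @property
    def n_igl(self) -> int:
        return int((self.chains["chain"] == "IGL").sum())

    def __len__(self) -> int:
        return len(self.chains)


@dataclass
class PairingCall:
    """Pairing classification of one cell."""

    barcode: str
    sample_id: str
    fine_code: str          # e.g. "1H2K", "2H1K1L"
    report_category: str    # one of REPORT_CATEGORIES, or "" if unpairable
    bcr_class: str          # single | dual | unpairable


@dataclass
class Clonotype:
    """Equivalence class of cells sharing one CDR3 key."""

    clone_id: str
    key: str
    size: int
    member_barcodes: frozenset[str]


@dataclass
class ClonotypeAssignment:
    """Result of clonotyping: the clones plus the per-cell mapping."""

    clones: list[Clonotype]
    cell_table: pd.DataFrame  # barcode, sample_id, clone_id, clone_size
    n_excluded: int           # cells with an empty CDR3 in scope

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clones], dtype=int)


def filter_functional_contigs(table: ContigTable) -> tuple[ContigTable, FilterLog]:
    """Apply the functional-contig filter cascade.

    Retains contigs that are called cells, high confidence, productive,
    and on an immunoglobulin locus (IGH/IGK/IGL).  Flags that are
    unknown ("None"/"Non"/empty in the source table) fail their rule.
    Rules are applied in sequence and each removal is attributed to the
    first rule that fires, mirroring a stepwise QC report.  Idempotent.
    """
    df = table.records
    log = FilterLog(n_input=len(df))

    is_cell = df["is_cell"].fillna(False).to_numpy(dtype=bool)
    high_conf = df["high_confidence"].fillna(False).to_numpy(dtype=bool)
    good_chain = df["chain"].isin(FUNCTIONAL_CHAINS).to_numpy()
    productive = df["productive"].fillna(False).to_numpy(dtype=bool)

    alive = np.ones(len(df), dtype=bool)
    log.n_not_cell = int((alive & ~is_cell).sum())
    alive &= is_cell
    log.n_low_confidence = int((alive & ~high_conf).sum())
    alive &= high_conf
    log.n_bad_chain = int((alive & ~good_chain).sum())
    alive &= good_chain
    log.n_not_productive = int((alive & ~productive).sum())
    alive &= productive
    log.n_retained = int(alive.sum())

    out = ContigTable.__new__(ContigTable)
    out.records = df.loc[alive].reset_index(drop=True)
    out.source_dialect = table.source_dialect
    out.sample_id = table.sample_id
    return out, log


def group_cells(table: ContigTable) -> tuple[list[CellChainSet], int]:
    """Group filtered contigs into cells; drop single-chain barcodes.

    A B cell for which only one functional chain was recovered cannot be
    pairing-classified and is discarded.  Returns the retained cells and
    the number of single-chain barcodes dropped.
    """
    df = table.records
    cells: list[CellChainSet] = []
    n_single = 0
    if len(df) == 0:
        return cells, 0
    for (sample_id, barcode), chains in df.groupby(
            ["sample_id", "barcode"], sort=True):
        if len(chains) < 2:
            n_single += 1
            continue
        cells.append(CellChainSet(barcode=str(barcode),
                                  sample_id=str(sample_id),
                                  chains=chains.reset_index(drop=True)))
    return cells, n_single


def _fine_code(n_igh: int, n_igk: int, n_igl: int) -> str:
    parts = []
    for n, letter in ((n_igh, "H"), (n_igk, "K"), (n_igl, "L")):
        if n:
            parts.append(f"{n}{letter}")
    return "".join(parts)


def classify_triple(n_igh: int, n_igk: int, n_igl: int) -> tuple[str, str, str]:
    """Classify a chain-count triple -> (fine_code, report_category, bcr_class).

    Pure function of the counts; :func:`classify_pairing` wraps it for a
    cell.  Requires at least two chains in total.
    """
    total = n_igh + n_igk + n_igl
    if total < 2:
        raise ValueError("pairing classification requires >= 2 chains")
    fine = _fine_code(n_igh, n_igk, n_igl)
    n_light = n_igk + n_igl
    if n_igh == 0 or n_light == 0:
        # no heavy chain, or no light chain: cannot pair and assemble
        return fine, "", "unpairable"
    if total == 2:
        # with >=1 heavy and >=1 light, two chains is exactly H+one light
        cat = CAT_H_KAPPA if n_igk == 1 else CAT_H_LAMBDA
        return fine, cat, "single"
    named = {(1, 2, 0): CAT_H_2KAPPA,
             (1, 0, 2): CAT_H_2LAMBDA,
             (1, 1, 1): CAT_H_KAPPA_LAMBDA}
    cat = named.get((n_igh, n_igk, n_igl), CAT_OTHERS)
    return fine, cat, "dual"


def classify_pairing(cell: CellChainSet) -> PairingCall:
    """Classify one cell's BCR pairing type from its chain counts.

    Every retained functional chain counts equally; no UMI ranking is
    applied.
    """
    fine, cat, klass = classify_triple(cell.n_igh, cell.n_igk, cell.n_igl)
    return PairingCall(barcode=cell.barcode, sample_id=cell.sample_id,
                       fine_code=fine, report_category=cat, bcr_class=klass)


def calls_frame(calls: list[PairingCall]) -> pd.DataFrame:
    """Per-cell calls as a DataFrame (one row per classified cell)."""
    return pd.DataFrame(
        {"barcode": [c.barcode for c in calls],
         "sample_id": [c.sample_id for c in calls],
         "fine_code": [c.fine_code for c in calls],
         "report_category": [c.report_category for c in calls],
         "bcr_class": [c.bcr_class for c in calls]})


def summarize_pairing(calls: list[PairingCall],
                      by: str | dict[str, str] = "sample_id") -> pd.DataFrame:
    """Pairing-type proportions per stratum.

    ``by`` is either the name of a PairingCall field (``sample_id``) or a
    mapping barcode -> stratum label (e.g. a group assignment).  The
    denominator is single + dual cells; unpairable cells are counted in
    their own column and excluded from every proportion.  Returns one
    row per stratum with counts and proportions for each report category
    and for the single/dual split.
    """
    if not calls:
        raise ValueError("summarize_pairing requires at least one call")
    df = calls_frame(calls)
    if isinstance(by, dict):
        df["stratum"] = df["barcode"].map(by)
    else:
        df["stratum"] = df[by]

    rows = []
    for stratum, sub in df.groupby("stratum", sort=True):
        n_unpairable = int((sub["bcr_class"] == "unpairable").sum())
        pairable = sub[sub["bcr_class"] != "unpairable"]
        denom = len(pairable)
        row: dict[str, object] = {
            "stratum": stratum,
            "n_pairable": denom,
            "n_unpairable": n_unpairable,
            "n_single": int((pairable["bcr_class"] == "single").sum()),
            "n_dual": int((pairable["bcr_class"] == "dual").sum()),
        }
        if denom == 0:
            warnings.warn(f"stratum {stratum!r} has no pairable cells; "
                          "proportions undefined")
            row["prop_single"] = np.nan
            row["prop_dual"] = np.nan
            for cat in REPORT_CATEGORIES:
                row[f"n_{cat}"] = 0
                row[f"prop_{cat}"] = np.nan
        else:
            row["prop_single"] = row["n_single"] / denom
            row["prop_dual"] = row["n_dual"] / denom
            cat_counts = Counter(pairable["report_category"])
            for cat in REPORT_CATEGORIES:
                row[f"n_{cat}"] = cat_counts.get(cat, 0)
                row[f"prop_{cat}"] = cat_counts.get(cat, 0) / denom
        rows.append(row)
    return pd.DataFrame(rows)


def assign_clonotypes(cells: list[CellChainSet],
                      level: str = "nt",
                      scope: str = "all_chains") -> ClonotypeAssignment:
    """Group cells into clonotypes by identical CDR3 sequences.

    Parameters
    ----------
    level
        ``nt`` (default) keys on nucleotide CDR3s, ``aa`` on amino-acid
        CDR3s.
    scope
        ``all_chains`` keys on every functional chain of the cell;
        ``igh_only`` restricts the key to heavy chains.

    The key is the lexicographically sorted join of ``chain:cdr3``
    pairs, so it is invariant to input and within-cell chain order.
    Cells with an empty CDR3 on any in-scope chain are excluded from
    clonotyping and counted in ``n_excluded``.
    """
    if level not in ("nt", "aa"):
        raise ValueError(f"unknown clonotype level {level!r}")
    if scope not in ("all_chains", "igh_only"):
        raise ValueError(f"unknown clonotype scope {scope!r}")
    col = "cdr3_nt" if level == "nt" else "cdr3_aa"

    keys: dict[str, list[CellChainSet]] = {}
    n_excluded = 0
    for cell in cells:
        chains = cell.chains
        if scope == "igh_only":
            chains = chains[chains["chain"] == "IGH"]
        seqs = list(zip(chains["chain"], chains[col]))
        if len(seqs) == 0 or any(s == "" for _, s in seqs):
            n_excluded += 1
            continue
        key = "|".join(f"{ch}:{s}" for ch, s in sorted(seqs))
        keys.setdefault(key, []).append(cell)

    clones: list[Clonotype] = []
    records = []
    for idx, key in enumerate(sorted(keys)):
        members = keys[key]
        clone_id = f"c{idx:06d}"
        clones.append(Clonotype(clone_id=clone_id, key=key,
                                size=len(members),
                                member_barcodes=frozenset(
                                    m.barcode for m in members)))
        for m in members:
            records.append((m.barcode, m.sample_id, clone_id, len(members)))
    cell_table = pd.DataFrame(
        records, columns=["barcode", "sample_id", "clone_id", "clone_size"])
    return ClonotypeAssignment(clones=clones, cell_table=cell_table,
                               n_excluded=n_excluded)


def cells_to_frame(cells: list[CellChainSet]) -> pd.DataFrame:
    """All retained chains of all cells as one flat table (stage handoff)."""
    if not cells:
        return pd.DataFrame(columns=CONTIG_FRAME_COLUMNS)
    return pd.concat([c.chains for c in cells], ignore_index=True)


def cells_from_frame(df: pd.DataFrame) -> list[CellChainSet]:
    """Rebuild CellChainSets from a flat chain table written by a prior stage."""
    cells = []
    for (sample_id, barcode), chains in df.groupby(["sample_id", "barcode"],
                                                   sort=True):
        cells.append(CellChainSet(barcode=str(barcode),
                                  sample_id=str(sample_id),
                                  chains=chains.reset_index(drop=True)))
    return cells


def expansion_stats(clones: list[Clonotype]) -> dict[str, float]:
    """Clonal-expansion summary over one compartment.

    Returns the proportion of cells in clones of size >= 2 (expanded)
    and its complement (singleton cells); the two sum to 1.
    """
    if not clones:
        raise ValueError("expansion_stats requires at least one clone")
    sizes = np.array([c.size for c in clones], dtype=float)
    total = sizes.sum()
    expanded = sizes[sizes >= 2].sum()
    return {
        "n_clones": int(len(sizes)),
        "total_cells": int(total),
        "expanded_cells": int(expanded),
        "prop_expanded": expanded / total,
        "prop_singleton": (total - expanded) / total,
    }
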