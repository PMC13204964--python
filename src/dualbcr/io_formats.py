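"""Readers and writers for the file formats the pipeline touches.

Contig annotation tables come in two dialects:

* the 10x Cell Ranger ``filtered_contig_annotations.csv`` /
  ``all_contig_annotations.csv`` layout (comma-delimited), and
* AIRR Rearrangement TSVs (one row per rearrangement, AIRR community
  schema column names).

Both are normalized into one internal table of contig records so that
downstream filtering and classification never needs to know the source
dialect.  Quality flags (``is_cell``, ``high_confidence``, ``productive``)
are *ternary*: true, false, or unknown.  Cell Ranger writes "None" for
columns it could not call and "Non" appears for non-productive contigs;
both map to unknown and are treated as failing by the downstream filter,
never silently coerced to false at parse time.

Expression matrices are read from the MTX triplet convention
(``matrix.mtx`` + gene and barcode lists) into an :class:`anndata.AnnData`
with cells as observations.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ContigTable",
    "FormatError",
    "CONTIG_COLUMNS",
    "read_contig_table",
    "write_contig_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_summary_tables",
    "parse_ternary",
    "ternary_to_text",
    "strip_allele",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


#: canonical column order of the internal contig table
CONTIG_COLUMNS = [
    "barcode",
    "contig_id",
    "is_cell",
    "high_confidence",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "cdr3_aa",
    "cdr3_nt",
    "productive",
    "umis",
    "reads",
]

_FLAG_COLUMNS = ("is_cell", "high_confidence", "productive")

# 10x CSV header -> internal name
_TENX_MAP = {
    "barcode": "barcode",
    "contig_id": "contig_id",
    "is_cell": "is_cell",
    "high_confidence": "high_confidence",
    "chain": "chain",
    "v_gene": "v_gene",
    "d_gene": "d_gene",
    "j_gene": "j_gene",
    "c_gene": "c_gene",
    "cdr3": "cdr3_aa",
    "cdr3_nt": "cdr3_nt",
    "productive": "productive",
    "umis": "umis",
    "reads": "reads",
}

# AIRR Rearrangement column -> internal name
_AIRR_MAP = {
    "cell_id": "barcode",
    "sequence_id": "contig_id",
    "locus": "chain",
    "v_call": "v_gene",
    "d_call": "d_gene",
    "j_call": "j_gene",
    "c_call": "c_gene",
    "junction_aa": "cdr3_aa",
    "junction": "cdr3_nt",
    "productive": "productive",
    "cell": "is_cell",
    "is_cell": "is_cell",
    "high_confidence": "high_confidence",
    "duplicate_count": "umis",
    "consensus_count": "reads",
}

_TRUE_TOKENS = {"true", "t", "1", "yes"}
_FALSE_TOKENS = {"false", "f", "0", "no"}
_UNKNOWN_TOKENS = {"", "none", "non", "na", "nan", "null"}


def parse_ternary(value) -> object:
    """Parse one flag token into True / False / pd.NA.

    Any casing of true/false (and the AIRR single-letter "T"/"F") is
    accepted; "None", "Non", empty and NA-like tokens map to unknown.
    Unrecognized tokens also map to unknown rather than raising: real
    Cell Ranger exports contain version-dependent vocabulary.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return pd.NA
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    if token in _UNKNOWN_TOKENS:
        return pd.NA
    return pd.NA


def ternary_to_text(value, dialect: str = "tenx_csv") -> str:
    """Serialize a ternary flag back to the dialect's vocabulary."""
    if pd.isna(value):
        return "None" if dialect == "tenx_csv" else ""
    if dialect == "airr_tsv":
        return "T" if value else "F"
    return "True" if value else "False"


def strip_allele(call: str) -> str:
    """Drop an IMGT allele suffix: ``IGHV4-34*01`` -> ``IGHV4-34``."""
    if not isinstance(call, str):
        return ""
    return call.split("*", 1)[0].strip()


@dataclass
class ContigTable:
    """An ordered table of contig records from one sample.

    ``records`` is a DataFrame with :data:`CONTIG_COLUMNS` plus a
    ``sample_id`` column so that tables concatenated across samples keep
    their provenance.  Flag columns use pandas' nullable boolean dtype
    (``pd.NA`` = unknown).
    """

    records: pd.DataFrame
    source_dialect: str = "tenx_csv"
    sample_id: str = ""

    def __post_init__(self) -> None:
        dup = self.records["contig_id"].duplicated()
        if dup.any():
            first = self.records.loc[dup, "contig_id"].iloc[0]
            raise FormatError(f"duplicate contig_id in table: {first!r}")
        if "sample_id" not in self.records.columns:
            self.records = self.records.assign(sample_id=self.sample_id)

    def __len__(self) -> int:
        return len(self.records)

    def concat(self, other: "ContigTable") -> "ContigTable":
        """Merge two samples' tables; records keep their own sample_id."""
        merged = pd.concat([self.records, other.records], ignore_index=True)
        out = ContigTable.__new__(ContigTable)
        out.records = merged
        out.source_dialect = self.source_dialect
        out.sample_id = f"{self.sample_id}+{other.sample_id}"
        return out


def _finalize_frame(df: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    for col in CONTIG_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA if col in _FLAG_COLUMNS else ("" if col not in ("umis", "reads") else 0)
    for col in _FLAG_COLUMNS:
        df[col] = df[col].map(parse_ternary).astype("boolean")
    for col in ("umis", "reads"):
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(np.int64)
        if (df[col] < 0).any():
            raise FormatError(f"negative values in column {col!r}")
    for col in ("barcode", "contig_id", "chain", "v_gene", "d_gene", "j_gene",
                "c_gene", "cdr3_aa", "cdr3_nt"):
        df[col] = df[col].fillna("").astype(str)
        df.loc[df[col].isin(["nan", "None"]), col] = ""
    df["sample_id"] = sample_id
    return df[CONTIG_COLUMNS + ["sample_id"]]


def read_contig_table(path: str | os.PathLike | io.IOBase,
                      dialect: str = "tenx_csv",
                      sample_id: str = "") -> ContigTable:
    """Read one per-contig annotation table.

    Parameters
    ----------
    path
        CSV (10x) or TSV (AIRR) file.
    dialect
        ``tenx_csv`` or ``airr_tsv``.
    sample_id
        Label attached to every record; used downstream for per-sample
        stratification.

    Raises
    ------
    FormatError
        If a mandatory column (barcode / chain, under the dialect's own
        name) is missing.
    """
    if dialect not in ("tenx_csv", "airr_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "tenx_csv" else "\t"
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read contig table {path}: {exc}") from exc

    colmap = _TENX_MAP if dialect == "tenx_csv" else _AIRR_MAP
    mandatory = (("barcode", "chain") if dialect == "tenx_csv"
                 else ("cell_id", "locus"))
    for col in mandatory:
        if col not in raw.columns:
            raise FormatError(
                f"mandatory column {col!r} missing from {dialect} table")

    df = pd.DataFrame(index=raw.index)
    for src, dst in colmap.items():
        if src in raw.columns and dst not in df.columns:
            df[dst] = raw[src]
    if dialect == "airr_tsv":
        for col in ("v_gene", "d_gene", "j_gene", "c_gene"):
            if col in df.columns:
                df[col] = df[col].map(strip_allele)
        # AIRR files rarely carry contig QC flags; absent -> unknown,
        # which the functional filter treats as failing.
    if "contig_id" not in df.columns:
        df["contig_id"] = [f"{sample_id or 'contig'}_{i}" for i in range(len(df))]
    df = _finalize_frame(df, sample_id)
    return ContigTable(records=df, source_dialect=dialect, sample_id=sample_id)


def write_contig_table(table: ContigTable, path: str | os.PathLike,
                       dialect: str | None = None) -> None:
    """Write a contig table back out in either dialect (round-trip safe)."""
    dialect = dialect or table.source_dialect
    df = table.records
    if dialect == "tenx_csv":
        out = pd.DataFrame({src: df[dst] for src, dst in _TENX_MAP.items()})
        for col in ("is_cell", "high_confidence", "productive"):
            out[col] = df[col].map(lambda v: ternary_to_text(v, "tenx_csv"))
        out.to_csv(path, index=False)
    elif dialect == "airr_tsv":
        cols = {"cell_id": "barcode", "sequence_id": "contig_id",
                "locus": "chain", "v_call": "v_gene", "d_call": "d_gene",
                "j_call": "j_gene", "c_call": "c_gene",
                "junction_aa": "cdr3_aa", "junction": "cdr3_nt",
                "duplicate_count": "umis", "consensus_count": "reads"}
        out = pd.DataFrame({src: df[dst] for src, dst in cols.items()})
        for src, dst in (("productive", "productive"), ("is_cell", "is_cell"),
                         ("high_confidence", "high_confidence")):
            out[src] = df[dst].map(lambda v: ternary_to_text(v, "airr_tsv"))
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_expression_matrix(matrix_path: str | os.PathLike,
                           genes_path: str | os.PathLike,
                           barcodes_path: str | os.PathLike) -> ad.AnnData:
    """Read an MTX triplet into an AnnData (cells x genes).

    The on-disk matrix follows the 10x convention of genes as rows and
    cell barcodes as columns; it is transposed into the cells-as-obs
    orientation used throughout single-cell tooling.  Duplicate (row,
    col) coordinate entries are summed, the MatrixMarket general
    convention.
    """
    genes = [line.split("\t")[0].strip()
             for line in Path(genes_path).read_text().splitlines() if line.strip()]
    barcodes = [line.strip() for line in
                Path(barcodes_path).read_text().splitlines() if line.strip()]
    mat = scipy.io.mmread(str(matrix_path))
    mat = sp.coo_matrix(mat)  # dense fallback for array mtx files
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix dimensions {mat.shape} do not match gene/barcode lists "
            f"({len(genes)}, {len(barcodes)})")
    x = sp.csr_matrix(mat.T)  # coo->csr sums duplicate entries
    if (x.data < 0).any():
        raise FormatError("expression matrix contains negative counts")
    adata = ad.AnnData(X=x,
                       obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return adata


def write_expression_matrix(adata: ad.AnnData, out_dir: str | os.PathLike) -> None:
    """Write an AnnData back to the MTX triplet (genes x cells on disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = sp.coo_matrix(adata.X).T
    scipy.io.mmwrite(str(out / "matrix.mtx"), x, field="integer")
    (out / "genes.txt").write_text("\n".join(adata.var_names) + "\n")
    (out / "barcodes.txt").write_text("\n".join(adata.obs_names) + "\n")


#: file name per statistic family written by write_summary_tables
SUMMARY_FILES = {
    "pairing": "pairing_proportions.tsv",
    "fine_codes": "pairing_fine_codes.tsv",
    "expansion": "expansion.tsv",
    "diversity": "diversity.tsv",
    "gini": "gini.tsv",
    "usage": "usage.tsv",
    "isotypes": "isotypes.tsv",
    "overlap": "overlap.tsv",
    "tests": "tests.tsv",
}


def write_summary_tables(summary: dict[str, pd.DataFrame],
                         out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write one UTF-8 tab-delimited file per statistic family.

    ``summary`` maps family names (keys of :data:`SUMMARY_FILES`; unknown
    keys get ``<key>.tsv``) to DataFrames.  Empty frames produce
    header-only files.  Returns the written paths.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: dict[str, Path] = {}
    for family, frame in summary.items():
        path = out / SUMMARY_FILES.get(family, f"{family}.tsv")
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written[family] = path
    return written


def read_summary_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back one summary TSV written by :func:`write_summary_tables`."""
    return pd.read_csv(path, sep="\t")
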