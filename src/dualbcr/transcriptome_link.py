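"""Transcriptome QC, marker-based B subset labels, barcode join, DE.

This module carries the scRNA-seq side of the analysis and its
integration with the BCR calls:

* per-cell quality control on raw counts — cells are removed when the
  detected gene count is below 200 or above 3000, the total count is
  below 1000, or the mitochondrial fraction exceeds 5%;
* log-normalization ``ln(1 + scale * count / cell_total)`` with a scale
  factor of 10,000;
* B cell subset labels from canonical marker scores (Naive_B, Memory_B,
  Breg, Plasma), assigned by strict arg-max of mean marker expression
  among Cd19-positive cells;
* the barcode inner join between transcriptome cells and
  pairing-classified BCR cells ("tracked" cells);
* Wilcoxon rank-sum differential expression with Benjamini–Hochberg
  correction; genes are pre-filtered to those expressed in at least 10%
  of either group with a fold-change screen of |log2FC| >= 0.25, and
  significance requires adjusted p < 0.05 and |log2FC| > 0.5.

Subset labelling here replaces the graph-clustering + reference
annotation machinery usual in full transcriptome studies: the final
subsets are defined by the marker genes themselves, which is the level
at which the downstream tracking statistics operate.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_MARKERS",
    "MITO_PREFIX",
    "qc_filter",
    "normalize_log",
    "assign_subsets",
    "join_by_barcode",
    "differential_expression",
    "strip_barcode_suffix",
]

#: canonical B subset markers (mouse symbol casing)
DEFAULT_MARKERS: dict[str, list[str]] = {
    "Naive_B": ["Cd19", "Ighd"],
    "Memory_B": ["Cd19", "Cd40", "Tnfrsf13b", "Aim2"],
    "Breg": ["Cd19", "Il10"],
    "Plasma": ["Cd19", "Jchain", "Xbp1"],
}

MITO_PREFIX = {"mouse": "mt-", "human": "MT-"}

SUBSETS = list(DEFAULT_MARKERS)


def markers_for_species(species: str) -> dict[str, list[str]]:
    """Marker table in the species' symbol casing."""
    if species == "mouse":
        return {k: list(v) for k, v in DEFAULT_MARKERS.items()}
    if species == "human":
        return {k: [g.upper() for g in v] for k, v in DEFAULT_MARKERS.items()}
    raise ValueError(f"unknown species {species!r}")


def _counts_matrix(adata: ad.AnnData) -> sp.csr_matrix:
    x = adata.X
    if not sp.issparse(x):
        x = sp.csr_matrix(np.asarray(x))
    return x.tocsr()


def qc_filter(adata: ad.AnnData, species: str = "mouse") -> pd.DataFrame:
    """Per-cell QC metrics and pass/fail flags on raw counts.

    A cell passes when 200 <= genes detected <= 3000, total counts >=
    1000, and the mitochondrial count fraction is at most 5% (the 5%
    boundary itself passes; the comparison is done in exact integer
    arithmetic, ``20 * mito_counts <= total_counts``).
    """
    if species not in MITO_PREFIX:
        raise ValueError(f"unknown species {species!r}")
    x = _counts_matrix(adata)
    total = np.asarray(x.sum(axis=1)).ravel().astype(np.int64)
    n_genes = np.asarray((x > 0).sum(axis=1)).ravel().astype(np.int64)
    mito_mask = np.array([g.startswith(MITO_PREFIX[species])
                          for g in adata.var_names])
    if not mito_mask.any():
        warnings.warn(f"no genes with mitochondrial prefix "
                      f"{MITO_PREFIX[species]!r}; mito fraction set to 0")
        mito = np.zeros(adata.n_obs, dtype=np.int64)
    else:
        mito = np.asarray(x[:, mito_mask].sum(axis=1)).ravel().astype(np.int64)
    with np.errstate(invalid="ignore"):
        mito_fraction = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    passes = ((n_genes >= 200) & (n_genes <= 3000)
              & (total >= 1000) & (20 * mito <= total))
    return pd.DataFrame({
        "barcode": list(adata.obs_names),
        "n_genes_detected": n_genes,
        "total_counts": total,
        "mito_fraction": mito_fraction,
        "passes_qc": passes,
    })


def normalize_log(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Log-normalize raw counts: ``ln(1 + scale * count / cell_total)``.

    Returns a new AnnData; the input is untouched.  Cells with zero
    total counts must be QC-filtered first.
    """
    x = _counts_matrix(adata).astype(np.float64)
    total = np.asarray(x.sum(axis=1)).ravel()
    if (total == 0).any():
        raise ValueError("zero-total cell encountered; run qc_filter first")
    x = sp.diags(scale / total) @ x
    x.data = np.log1p(x.data)
    return ad.AnnData(X=x.tocsr(), obs=adata.obs.copy(), var=adata.var.copy())


def assign_subsets(normalized: ad.AnnData,
                   markers: dict[str, list[str]] | None = None,
                   species: str = "mouse",
                   cd19_gene: str | None = None) -> pd.DataFrame:
    """Assign B subset labels by marker-score arg-max.

    The score of a subset is the mean normalized expression of its
    marker genes present in the matrix.  Cells with zero Cd19
    expression are B-lineage-unassignable; among the rest, the subset
    with the strictly largest score wins and exact ties (including the
    all-zero case) give ``unassigned``.

    Returns a frame with barcode, subset, and one ``score_<subset>``
    column per subset.
    """
    markers = markers or markers_for_species(species)
    if cd19_gene is None:
        common = set.intersection(*(set(v) for v in markers.values()))
        cd19_gene = sorted(common)[0] if common else None
    x = _counts_matrix(normalized)
    var_index = {g: i for i, g in enumerate(normalized.var_names)}

    scores = np.zeros((normalized.n_obs, len(markers)))
    subset_names = list(markers)
    for j, subset in enumerate(subset_names):
        idx = [var_index[g] for g in markers[subset] if g in var_index]
        missing = [g for g in markers[subset] if g not in var_index]
        if missing:
            warnings.warn(f"markers absent from matrix for {subset}: {missing}")
        if not idx:
            warnings.warn(f"all markers absent for {subset}; unassignable")
            scores[:, j] = -np.inf
            continue
        scores[:, j] = np.asarray(x[:, idx].mean(axis=1)).ravel()

    order = np.argsort(scores, axis=1)
    best = order[:, -1]
    best_score = scores[np.arange(len(best)), best]
    runner_up = scores[np.arange(len(best)), order[:, -2]]
    labels = np.array(subset_names, dtype=object)[best]
    labels[~(best_score > runner_up)] = "unassigned"  # strict arg-max
    labels[best_score <= 0] = "unassigned"
    if cd19_gene is not None and cd19_gene in var_index:
        cd19 = np.asarray(x[:, [var_index[cd19_gene]]].todense()).ravel()
        labels[cd19 == 0] = "unassigned"

    out = pd.DataFrame({"barcode": list(normalized.obs_names),
                        "subset": labels})
    for j, subset in enumerate(subset_names):
        out[f"score_{subset}"] = scores[:, j]
    return out


def strip_barcode_suffix(barcode: str) -> str:
    """Drop a 10x GEM-well suffix: ``ACGT...-1`` -> ``ACGT...``."""
    head, sep, tail = barcode.rpartition("-")
    if sep and tail.isdigit():
        return head
    return barcode


def join_by_barcode(bcr_calls: pd.DataFrame,
                    subset_labels: pd.DataFrame,
                    qc: pd.DataFrame | None = None,
                    normalize_suffix: bool = False
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inner-join BCR calls with transcriptome cells by barcode.

    ``bcr_calls`` needs a ``barcode`` column (plus whatever call columns
    it carries); ``subset_labels`` comes from :func:`assign_subsets`.
    When ``qc`` is given, only QC-passing transcriptome cells enter the
    join.  ``normalize_suffix`` strips "-1"-style GEM suffixes on both
    sides before matching (RNA and VDJ exports from different
    processing chains sometimes disagree on the suffix).

    Returns the tracked-cell table and a count report (cells on each
    side, joined, each-side-only).  Zero joined barcodes is a hard
    error.
    """
    left = bcr_calls.copy()
    right = subset_labels.copy()
    if qc is not None:
        passing = set(qc.loc[qc["passes_qc"], "barcode"])
        right = right[right["barcode"].isin(passing)]
    key = "_join_key"
    norm = strip_barcode_suffix if normalize_suffix else (lambda b: b)
    left[key] = left["barcode"].map(norm)
    right = right.rename(columns={"barcode": "barcode_rna"})
    right[key] = right["barcode_rna"].map(norm)
    joined = left.merge(right, on=key, how="inner").drop(columns=[key])
    report = {
        "n_bcr": len(left),
        "n_rna": len(right),
        "n_joined": len(joined),
        "n_bcr_only": len(left) - joined["barcode"].nunique(),
        "n_rna_only": len(right) - joined["barcode_rna"].nunique(),
    }
    if len(joined) == 0:
        raise ValueError(
            "no barcodes shared between BCR calls and transcriptome; "
            "if one side carries a '-1' suffix, retry with "
            "normalize_suffix=True")
    return joined, report


def differential_expression(normalized: ad.AnnData,
                            group_a: list[str],
                            group_b: list[str],
                            min_pct: float = 0.1,
                            lfc_prefilter: float = 0.25,
                            pseudocount: float = 1.0,
                            alpha: float = 0.05,
                            lfc_significant: float = 0.5) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between two barcode groups.

    Genes enter testing when expressed (count > 0) in at least
    ``min_pct`` of either group and the screening fold change passes
    ``|log2FC| >= lfc_prefilter``; log2FC compares group means of the
    de-logged normalized expression with a pseudocount:
    ``log2((mean_a + 1) / (mean_b + 1))``.  P-values are
    Benjamini–Hochberg adjusted over the tested genes, and a gene is
    called significant when adjusted p < ``alpha`` and |log2FC| >
    ``lfc_significant``.  Results are ordered by adjusted p.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("differential expression requires >= 3 cells per group")
    idx = {b: i for i, b in enumerate(normalized.obs_names)}
    try:
        ia = np.array([idx[b] for b in group_a])
        ib = np.array([idx[b] for b in group_b])
    except KeyError as exc:
        raise KeyError(f"barcode not in matrix: {exc.args[0]!r}") from exc
    x = _counts_matrix(normalized)
    xa, xb = x[ia], x[ib]

    pct_a = np.asarray((xa > 0).mean(axis=0)).ravel()
    pct_b = np.asarray((xb > 0).mean(axis=0)).ravel()
    expm = lambda m: np.asarray(m).ravel()
    mean_a = expm(sp.csr_matrix((np.expm1(xa.data), xa.indices, xa.indptr),
                                shape=xa.shape).mean(axis=0))
    mean_b = expm(sp.csr_matrix((np.expm1(xb.data), xb.indices, xb.indptr),
                                shape=xb.shape).mean(axis=0))
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    tested = np.flatnonzero(
        ((pct_a >= min_pct) | (pct_b >= min_pct))
        & (np.abs(log2fc) >= lfc_prefilter))
    pvals = np.ones(len(tested))
    xa_d = np.asarray(xa[:, tested].todense())
    xb_d = np.asarray(xb[:, tested].todense())
    for k in range(len(tested)):
        a_col, b_col = xa_d[:, k], xb_d[:, k]
        if np.all(a_col == a_col[0]) and np.all(b_col == b_col[0]) \
                and a_col[0] == b_col[0]:
            pvals[k] = 1.0
            continue
        pvals[k] = scipy.stats.ranksums(a_col, b_col).pvalue
    if len(tested):
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        p_adj = np.array([])

    genes = np.array(normalized.var_names)[tested]
    out = pd.DataFrame({
        "gene": genes,
        "log2_fold_change": log2fc[tested],
        "p_value": pvals,
        "p_adjusted": p_adj,
        "pct_expressed_a": pct_a[tested],
        "pct_expressed_b": pct_b[tested],
    })
    out["is_significant"] = ((out["p_adjusted"] < alpha)
                             & (out["log2_fold_change"].abs() > lfc_significant))
    return out.sort_values(["p_adjusted", "p_value", "gene"],
                           kind="stable").reset_index(drop=True)
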