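import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dualbcr import (SimConfig, assign_subsets, differential_expression,
                     join_by_barcode, normalize_log, qc_filter,
                     simulate_expression, simulate_repertoire)
from dualbcr.transcriptome_link import strip_barcode_suffix


def build_adata(rows, genes, barcodes=None):
    """AnnData from a dense count list (cells x genes)."""
    x = np.asarray(rows, dtype=np.int64)
    barcodes = barcodes or [f"bc{i}" for i in range(x.shape[0])]
    return ad.AnnData(
        X=sp.csr_matrix(x),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")))


class TestQCBoundaries:
    def _gene_count_cell(self, n_detected, n_genes, total=5000):
        """A cell detecting exactly n_detected genes with >= `total` counts."""
        row = np.zeros(n_genes, dtype=np.int64)
        row[:n_detected] = 1
        row[0] += total - n_detected
        return row

    def test_gene_count_boundaries(self):
        n_genes = 3100
        genes = [f"g{i}" for i in range(n_genes)]
        rows = [self._gene_count_cell(k, n_genes)
                for k in (199, 200, 3000, 3001)]
        qc = qc_filter(build_adata(rows, genes), species="mouse")
        assert list(qc["passes_qc"]) == [False, True, True, False]
        assert list(qc["n_genes_detected"]) == [199, 200, 3000, 3001]

    def test_total_count_boundary(self):
        n_genes = 300
        genes = [f"g{i}" for i in range(n_genes)]

        def cell(total):
            row = np.ones(n_genes, dtype=np.int64)  # 300 genes detected
            row[0] += total - n_genes
            return row

        qc = qc_filter(build_adata([cell(999), cell(1000)], genes), "mouse")
        assert list(qc["total_counts"]) == [999, 1000]
        assert list(qc["passes_qc"]) == [False, True]

    def test_mito_boundary_exact(self):
        genes = [f"g{i}" for i in range(250)] + ["mt-Co1"]

        def cell(total, mito):
            row = np.ones(251, dtype=np.int64)
            row[-1] = mito
            row[0] += total - mito - 250
            return row

        # 5.00% exactly kept; 5.01% removed (10000 total, 501 mito)
        qc = qc_filter(build_adata([cell(10000, 500), cell(10000, 501)],
                                   genes), "mouse")
        assert qc.loc[0, "mito_fraction"] == pytest.approx(0.05)
        assert list(qc["passes_qc"]) == [True, False]

    def test_all_zero_cell_removed(self):
        genes = [f"g{i}" for i in range(300)]
        row = np.ones(300, dtype=np.int64)
        row[0] += 2000
        qc = qc_filter(build_adata([np.zeros(300, dtype=np.int64), row],
                                   genes), "mouse")
        assert list(qc["passes_qc"]) == [False, True]

    def test_missing_mito_genes_warns(self):
        genes = [f"g{i}" for i in range(250)]
        row = np.ones(250, dtype=np.int64)
        row[0] += 2000
        with pytest.warns(UserWarning, match="mitochondrial"):
            qc = qc_filter(build_adata([row], genes), species="mouse")
        assert qc.loc[0, "mito_fraction"] == 0.0

    def test_human_prefix(self):
        genes = ["A", "MT-CO1"]
        row = np.array([900, 600], dtype=np.int64)
        qc = qc_filter(build_adata([row], genes), species="human")
        assert qc.loc[0, "mito_fraction"] == pytest.approx(0.4)
        assert not qc.loc[0, "passes_qc"]


class TestNormalizeLog:
    def test_direct_substitution(self):
        adata = build_adata([[10, 90]], ["g1", "g2"])
        norm = normalize_log(adata)
        x = np.asarray(sp.csr_matrix(norm.X).todense())
        assert x[0, 0] == pytest.approx(np.log(1 + 10000 * 10 / 100))
        assert x[0, 0] == pytest.approx(np.log(1001))

    def test_zero_count_stays_zero(self):
        adata = build_adata([[0, 100]], ["g1", "g2"])
        x = np.asarray(sp.csr_matrix(normalize_log(adata).X).todense())
        assert x[0, 0] == 0.0

    def test_depth_invariance(self):
        a = build_adata([[10, 90]], ["g1", "g2"])
        b = build_adata([[20, 180]], ["g1", "g2"])
        xa = np.asarray(sp.csr_matrix(normalize_log(a).X).todense())
        xb = np.asarray(sp.csr_matrix(normalize_log(b).X).todense())
        np.testing.assert_allclose(xa, xb)

    def test_zero_total_cell_rejected(self):
        adata = build_adata([[0, 0]], ["g1", "g2"])
        with pytest.raises(ValueError, match="zero-total"):
            normalize_log(adata)


MARKER_GENES = ["Cd19", "Ighd", "Cd40", "Tnfrsf13b", "Aim2", "Il10",
                "Jchain", "Xbp1", "Filler"]


def marker_cell(**levels):
    row = np.zeros(len(MARKER_GENES), dtype=np.int64)
    row[-1] = 500  # library depth filler
    for gene, value in levels.items():
        row[MARKER_GENES.index(gene)] = value
    return row


class TestAssignSubsets:
    def test_plasma_markers_win(self):
        adata = build_adata([marker_cell(Cd19=5, Jchain=40, Xbp1=40)],
                            MARKER_GENES)
        labels = assign_subsets(normalize_log(adata))
        assert labels.loc[0, "subset"] == "Plasma"

    def test_all_zero_scores_unassigned(self):
        adata = build_adata([marker_cell()], MARKER_GENES)
        labels = assign_subsets(normalize_log(adata))
        assert labels.loc[0, "subset"] == "unassigned"

    def test_cd19_negative_unassigned(self):
        adata = build_adata([marker_cell(Jchain=40, Xbp1=40)], MARKER_GENES)
        labels = assign_subsets(normalize_log(adata))
        assert labels.loc[0, "subset"] == "unassigned"

    def test_missing_marker_warns_but_assigns(self):
        genes = [g for g in MARKER_GENES if g != "Aim2"]
        row = np.zeros(len(genes), dtype=np.int64)
        row[genes.index("Cd19")] = 5
        row[genes.index("Il10")] = 50
        row[-1] = 500
        with pytest.warns(UserWarning, match="Aim2"):
            labels = assign_subsets(normalize_log(build_adata([row], genes)))
        assert labels.loc[0, "subset"] == "Breg"

    def test_planted_cohort_recovery(self):
        cfg = SimConfig(n_cells=2000, seed=17)
        _, truth = simulate_repertoire(cfg)
        adata = simulate_expression(truth, cfg)
        labels = assign_subsets(normalize_log(adata))
        m = labels.merge(truth.cells, on="barcode",
                         suffixes=("_pred", "_true"))
        recovery = (m["subset_pred"] == m["subset_true"]).mean()
        assert recovery >= 0.95


class TestJoinByBarcode:
    def _calls(self, barcodes):
        return pd.DataFrame({"barcode": barcodes,
                             "bcr_class": ["single"] * len(barcodes)})

    def _labels(self, barcodes):
        return pd.DataFrame({"barcode": barcodes,
                             "subset": ["Naive_B"] * len(barcodes)})

    def test_qc_gates_the_join(self):
        calls = self._calls(["a", "b", "c"])
        labels = self._labels(["a", "b", "c"])
        qc = pd.DataFrame({"barcode": ["a", "b", "c"],
                           "passes_qc": [True, True, False]})
        joined, report = join_by_barcode(calls, labels, qc=qc)
        assert report["n_joined"] == 2
        assert set(joined["barcode"]) == {"a", "b"}

    def test_suffix_normalizer(self):
        calls = self._calls(["ACGT-1", "TTTT-1"])
        labels = self._labels(["ACGT", "TTTT"])
        with pytest.raises(ValueError, match="suffix"):
            join_by_barcode(calls, labels)
        joined, report = join_by_barcode(calls, labels,
                                         normalize_suffix=True)
        assert report["n_joined"] == 2

    def test_output_not_larger_than_inputs(self):
        calls = self._calls(["a", "b", "x"])
        labels = self._labels(["a", "b", "y"])
        joined, _ = join_by_barcode(calls, labels)
        assert len(joined) <= min(len(calls), len(labels))

    def test_suffix_stripper(self):
        assert strip_barcode_suffix("ACGT-1") == "ACGT"
        assert strip_barcode_suffix("ACGT") == "ACGT"
        assert strip_barcode_suffix("s1_BC-12") == "s1_BC"


class TestDifferentialExpression:
    def _null_adata(self, n_per_group=30, n_genes=50, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.negative_binomial(2, 2 / 5, size=(2 * n_per_group, n_genes))
        x[:, 0] += 200  # depth anchor
        genes = [f"g{i}" for i in range(n_genes)]
        adata = build_adata(x, genes)
        obs = list(adata.obs_names)
        return normalize_log(adata), obs[:n_per_group], obs[n_per_group:]

    def test_identical_groups_nothing_significant(self):
        norm, ga, gb = self._null_adata(seed=1)
        de = differential_expression(norm, ga, gb)
        assert not de["is_significant"].any()

    def test_planted_gene_all_zero_in_b(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(3.0, size=(40, 30))
        x[:, 0] += 300
        x[:20, 5] = 60   # group A expresses gene 5
        x[20:, 5] = 0    # group B silent
        genes = [f"g{i}" for i in range(30)]
        adata = build_adata(x, genes)
        obs = list(adata.obs_names)
        de = differential_expression(normalize_log(adata), obs[:20], obs[20:])
        row = de[de["gene"] == "g5"].iloc[0]
        assert row["log2_fold_change"] > 0.5
        assert row["is_significant"]

    def test_bh_adjustment_is_monotone(self):
        norm, ga, gb = self._null_adata(n_per_group=20, n_genes=120, seed=3)
        de = differential_expression(norm, ga, gb)
        by_raw = de.sort_values("p_value")
        assert by_raw["p_adjusted"].is_monotonic_increasing

    def test_small_group_rejected(self):
        norm, ga, gb = self._null_adata()
        with pytest.raises(ValueError, match=">= 3"):
            differential_expression(norm, ga[:2], gb)

    def test_planted_effect_recovery(self):
        import anndata
        ca = SimConfig(n_cells=200, seed=31, sample_id="dis",
                       group="disease", n_background_genes=500)
        cb = SimConfig(n_cells=200, seed=32, sample_id="ctl",
                       group="control", n_background_genes=500)
        ta, tra = simulate_repertoire(ca)
        tb, trb = simulate_repertoire(cb)
        ea = simulate_expression(tra, ca)
        eb = simulate_expression(trb, cb)
        norm = normalize_log(anndata.concat([ea, eb], merge="same"))
        de = differential_expression(norm, list(ea.obs_names),
                                     list(eb.obs_names))
        planted = set(tra.gene_truth.loc[tra.gene_truth["is_de"], "gene"])
        nulls = set(tra.gene_truth.loc[
            tra.gene_truth["role"] == "background", "gene"])
        sig = set(de.loc[de["is_significant"], "gene"])
        assert len(sig & planted) >= 18
        assert len(sig & nulls) == 0
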