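import itertools

import numpy as np
import pandas as pd
import pytest

from dualbcr import (assign_clonotypes, classify_pairing, classify_triple,
                     expansion_stats, filter_functional_contigs, group_cells,
                     read_contig_table, summarize_pairing)
from dualbcr.bcr_core import Clonotype, calls_frame

from conftest import make_cell, make_contig_csv


class TestFunctionalFilter:
    def test_rule_enumeration(self, tmp_path):
        # five fabricated rows: one fails each of three rules, two pass
        path = make_contig_csv(tmp_path / "c.csv", [
            {"barcode": "A", "chain": "IGH"},
            {"barcode": "A", "chain": "IGK"},
            {"barcode": "B", "is_cell": "FALSE"},
            {"barcode": "B", "chain": "Multi"},
            {"barcode": "B", "productive": "Non"},
        ])
        table = read_contig_table(path, "tenx_csv")
        out, log = filter_functional_contigs(table)
        assert len(out) == 2
        assert log.n_not_cell == 1
        assert log.n_bad_chain == 1
        assert log.n_not_productive == 1

    def test_all_pass_is_identity(self, small_sim):
        _, table, _ = small_sim
        once, _ = filter_functional_contigs(table)
        again, log2 = filter_functional_contigs(once)
        assert len(again) == len(once)
        pd.testing.assert_frame_equal(again.records, once.records)
        assert log2.n_not_cell == log2.n_bad_chain == log2.n_not_productive == 0

    def test_productive_false_removed(self, tmp_path):
        path = make_contig_csv(tmp_path / "c.csv",
                               [{"productive": "FALSE"}])
        out, log = filter_functional_contigs(
            read_contig_table(path, "tenx_csv"))
        assert len(out) == 0 and log.n_not_productive == 1


class TestGroupCells:
    def test_single_chain_barcode_discarded(self, tmp_path):
        path = make_contig_csv(tmp_path / "c.csv", [
            {"barcode": "A", "chain": "IGH"},
            {"barcode": "A", "chain": "IGK"},
            {"barcode": "B", "chain": "IGH"},
        ])
        table, _ = filter_functional_contigs(read_contig_table(path, "tenx_csv"))
        cells, n_dropped = group_cells(table)
        assert [c.barcode for c in cells] == ["A"]
        assert n_dropped == 1

    def test_chain_counting(self, tmp_path):
        path = make_contig_csv(tmp_path / "c.csv", [
            {"barcode": "A", "chain": "IGH"},
            {"barcode": "A", "chain": "IGK"},
            {"barcode": "A", "chain": "IGK"},
        ])
        table, _ = filter_functional_contigs(read_contig_table(path, "tenx_csv"))
        cells, _ = group_cells(table)
        assert (cells[0].n_igh, cells[0].n_igk, cells[0].n_igl) == (1, 2, 0)

    def test_empty_table(self, tmp_path):
        path = make_contig_csv(tmp_path / "c.csv",
                               [{"is_cell": "FALSE"}])
        table, _ = filter_functional_contigs(read_contig_table(path, "tenx_csv"))
        cells, n_dropped = group_cells(table)
        assert cells == [] and n_dropped == 0


def oracle_pairing(h: int, k: int, l: int) -> tuple[str, str]:
    """Independent re-derivation of the pairing rules.

    A receptor needs one heavy and one light chain; a cell that cannot
    provide both is unpairable.  Two chains that pair -> single BCR;
    three or more functional chains -> dual BCR, reported under its
    named configuration or "others".
    """
    if h == 0 or k + l == 0:
        return "", "unpairable"
    total = h + k + l
    if total == 2:
        return ("H+κ" if k else "H+λ"), "single"
    name = {(1, 2, 0): "H+κ1+κ2", (1, 0, 2): "H+λ1+λ2",
            (1, 1, 1): "H+κ+λ"}.get((h, k, l), "others")
    return name, "dual"


class TestClassifyPairing:
    def test_exhaustive_truth_table(self):
        """Classifier agrees with the independent rule derivation for
        every chain-count triple with 2..5 total chains."""
        for h, k, l in itertools.product(range(6), repeat=3):
            if not 2 <= h + k + l <= 5:
                continue
            fine, cat, klass = classify_triple(h, k, l)
            exp_cat, exp_class = oracle_pairing(h, k, l)
            assert klass == exp_class, (h, k, l)
            assert cat == exp_cat, (h, k, l)

    @pytest.mark.parametrize("triple,cat,klass,fine", [
        ((1, 2, 0), "H+κ1+κ2", "dual", "1H2K"),
        ((2, 1, 1), "others", "dual", "2H1K1L"),
        ((0, 1, 1), "", "unpairable", "1K1L"),
        ((1, 3, 0), "others", "dual", "1H3K"),
        ((2, 0, 0), "", "unpairable", "2H"),
    ])
    def test_named_cases(self, triple, cat, klass, fine):
        got_fine, got_cat, got_class = classify_triple(*triple)
        assert (got_fine, got_cat, got_class) == (fine, cat, klass)

    def test_below_two_chains_rejected(self):
        with pytest.raises(ValueError):
            classify_triple(1, 0, 0)

    def test_cell_interface(self):
        cell = make_cell("A", ["IGH", "IGK", "IGK"])
        call = classify_pairing(cell)
        assert call.bcr_class == "dual"
        assert call.report_category == "H+κ1+κ2"

    def test_classes_partition_cells(self, small_sim_cells):
        cells, calls, _, _ = small_sim_cells
        assert len(calls) == len(cells)
        classes = {c.bcr_class for c in calls}
        assert classes <= {"single", "dual", "unpairable"}
        df = calls_frame(calls)
        assert df["barcode"].is_unique


class TestSummarizePairing:
    def test_dual_proportion(self):
        calls = ([classify_pairing(make_cell(f"s{i}", ["IGH", "IGK"]))
                  for i in range(80)]
                 + [classify_pairing(make_cell(f"d{i}", ["IGH", "IGK", "IGK"]))
                    for i in range(20)])
        summ = summarize_pairing(calls)
        assert summ.loc[0, "prop_dual"] == pytest.approx(0.20)
        assert summ.loc[0, "n_pairable"] == 100

    def test_category_proportions_sum_to_one(self):
        calls = ([classify_pairing(make_cell(f"a{i}", ["IGH", "IGK"]))
                  for i in range(70)]
                 + [classify_pairing(make_cell(f"b{i}", ["IGH", "IGK", "IGK"]))
                    for i in range(20)]
                 + [classify_pairing(make_cell(f"c{i}", ["IGH", "IGH", "IGK"]))
                    for i in range(10)])
        summ = summarize_pairing(calls)
        assert summ.loc[0, "prop_H+κ"] == pytest.approx(0.70)
        assert summ.loc[0, "prop_H+κ1+κ2"] == pytest.approx(0.20)
        assert summ.loc[0, "prop_others"] == pytest.approx(0.10)
        props = [summ.loc[0, f"prop_{c}"] for c in
                 ("H+κ", "H+λ", "H+κ1+κ2", "H+λ1+λ2", "H+κ+λ", "others")]
        assert sum(props) == pytest.approx(1.0)

    def test_unpairable_excluded_from_denominator(self):
        calls = [classify_pairing(make_cell("a", ["IGH", "IGK"])),
                 classify_pairing(make_cell("b", ["IGK", "IGL"]))]
        summ = summarize_pairing(calls)
        assert summ.loc[0, "n_unpairable"] == 1
        assert summ.loc[0, "prop_single"] == pytest.approx(1.0)

    def test_empty_stratum_warns(self):
        calls = [classify_pairing(make_cell("b", ["IGK", "IGL"]))]
        with pytest.warns(UserWarning, match="no pairable"):
            summ = summarize_pairing(calls)
        assert np.isnan(summ.loc[0, "prop_dual"])


class TestClonotypes:
    def test_identical_cdr3_share_clone(self):
        seqs = ["TGTGCTAGATGGCAA", "TGTCAGCAGTGGAAA"]
        a = make_cell("A", ["IGH", "IGK"], cdr3s=seqs)
        b = make_cell("B", ["IGH", "IGK"], cdr3s=seqs)
        asn = assign_clonotypes([a, b], level="nt")
        assert len(asn.clones) == 1 and asn.clones[0].size == 2

    def test_synonymous_difference_splits_nt_not_aa(self):
        # CTG and CTT both encode leucine
        a = make_cell("A", ["IGH", "IGK"],
                      cdr3s=["TGTCTGAGATGGCAA", "TGTCAGCAGTGGAAA"])
        b = make_cell("B", ["IGH", "IGK"],
                      cdr3s=["TGTCTTAGATGGCAA", "TGTCAGCAGTGGAAA"])
        for cell in (a, b):
            from Bio.Seq import Seq
            cell.chains["cdr3_aa"] = [str(Seq(s).translate())
                                      for s in cell.chains["cdr3_nt"]]
        assert len(assign_clonotypes([a, b], level="aa").clones) == 1
        assert len(assign_clonotypes([a, b], level="nt").clones) == 2

    def test_single_cell_is_singleton_clone(self):
        asn = assign_clonotypes([make_cell("A", ["IGH", "IGK"])])
        assert len(asn.clones) == 1 and asn.clones[0].size == 1

    def test_order_invariance(self, small_sim_cells):
        cells, _, _, _ = small_sim_cells
        fwd = assign_clonotypes(cells)
        rev = assign_clonotypes(list(reversed(cells)))
        assert sorted(c.key for c in fwd.clones) == \
            sorted(c.key for c in rev.clones)
        a = fwd.cell_table.sort_values("barcode").reset_index(drop=True)
        b = rev.cell_table.sort_values("barcode").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_chain_order_within_cell_irrelevant(self):
        seqs = ["TGTGCTAGATGGCAA", "TGTCAGCAGTGGAAA"]
        a = make_cell("A", ["IGH", "IGK"], cdr3s=seqs)
        b = make_cell("B", ["IGK", "IGH"], cdr3s=list(reversed(seqs)))
        asn = assign_clonotypes([a, b], level="nt")
        assert len(asn.clones) == 1

    def test_empty_cdr3_excluded(self):
        a = make_cell("A", ["IGH", "IGK"], cdr3s=["TGTGCTAGATGG", ""])
        asn = assign_clonotypes([a])
        assert asn.n_excluded == 1 and len(asn.clones) == 0

    def test_igh_only_scope(self):
        a = make_cell("A", ["IGH", "IGK"],
                      cdr3s=["TGTGCTAGATGG", "TGTAAACAGTGG"])
        b = make_cell("B", ["IGH", "IGK"],
                      cdr3s=["TGTGCTAGATGG", "TGTCCCCAGTGG"])
        assert len(assign_clonotypes([a, b], scope="igh_only").clones) == 1
        assert len(assign_clonotypes([a, b], scope="all_chains").clones) == 2

    def test_sizes_partition_cells(self, small_sim_cells):
        cells, _, _, _ = small_sim_cells
        asn = assign_clonotypes(cells)
        assert asn.sizes.sum() + asn.n_excluded == len(cells)

    def test_bad_tokens_rejected(self):
        with pytest.raises(ValueError):
            assign_clonotypes([], level="codon")
        with pytest.raises(ValueError):
            assign_clonotypes([], scope="light_only")


class TestExpansion:
    def _clones(self, sizes):
        return [Clonotype(f"c{i}", f"k{i}", s, frozenset())
                for i, s in enumerate(sizes)]

    def test_hand_enumeration(self):
        stats = expansion_stats(self._clones([3, 1, 1]))
        assert stats["prop_expanded"] == pytest.approx(0.6)
        assert stats["prop_singleton"] == pytest.approx(0.4)

    def test_all_singletons(self):
        assert expansion_stats(self._clones([1] * 7))["prop_expanded"] == 0.0

    def test_single_dominant_clone(self):
        assert expansion_stats(self._clones([9]))["prop_expanded"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            expansion_stats([])
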