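import numpy as np
import pytest

from mfclone.clonotype import (
    build_cell_clonotypes,
    call_malignant_clone,
    clone_key,
    partition_cells,
    reconcile_chain_subsets,
)
from mfclone.errors import NoTCRInformationError
from mfclone.io import ContigRecord


def contig(barcode, chain, cdr3, umis=10, productive=True, is_cell=True, hc=True):
    return ContigRecord(
        barcode=barcode, is_cell=is_cell, high_confidence=hc, chain=chain,
        productive=productive, cdr3_nt=cdr3, umis=umis,
    )


class TestBuildCellClonotypes:
    def test_paired_cell(self):
        cells = build_cell_clonotypes([contig("b1", "TRA", "AAA"), contig("b1", "TRB", "CCC")])
        assert cells["b1"].pairs == {("TRA", "AAA"), ("TRB", "CCC")}
        assert cells["b1"].is_paired

    def test_double_beta_kept_and_flagged_unpaired(self):
        cells = build_cell_clonotypes(
            [contig("b1", "TRB", "AAA", umis=12), contig("b1", "TRB", "CCC", umis=3)]
        )
        assert cells["b1"].pairs == {("TRB", "AAA"), ("TRB", "CCC")}
        assert not cells["b1"].is_paired

    def test_top2_per_chain_by_umis(self):
        recs = [
            contig("b1", "TRA", "AAA", umis=5),
            contig("b1", "TRA", "CCC", umis=30),
            contig("b1", "TRA", "GGG", umis=12),
        ]
        cells = build_cell_clonotypes(recs)
        assert cells["b1"].pairs == {("TRA", "CCC"), ("TRA", "GGG")}

    def test_filters_non_cell_low_confidence_and_missing_cdr3(self):
        recs = [
            contig("b1", "TRA", "AAA", is_cell=False),
            contig("b2", "TRB", "CCC", hc=False),
            contig("b3", "TRA", None),
            contig("b4", "IGH", "TTT"),
        ]
        assert build_cell_clonotypes(recs) == {}


class TestReconciliation:
    def test_single_chain_merged_into_unique_paired_clone(self):
        recs = [
            contig("full", "TRA", "AAA"), contig("full", "TRB", "CCC"),
            contig("beta_only", "TRB", "CCC"),
        ]
        assign = reconcile_chain_subsets(build_cell_clonotypes(recs))
        key = clone_key([("TRA", "AAA"), ("TRB", "CCC")])
        assert assign["beta_only"] == key == assign["full"]

    def test_ambiguous_chain_stays_own_clone(self):
        recs = [
            contig("c1", "TRA", "AAA"), contig("c1", "TRB", "CCC"),
            contig("c2", "TRA", "GGG"), contig("c2", "TRB", "CCC"),
            contig("amb", "TRB", "CCC"),
        ]
        assign = reconcile_chain_subsets(build_cell_clonotypes(recs))
        assert assign["amb"] == clone_key([("TRB", "CCC")])

    def test_fully_paired_cells_never_reassigned(self):
        recs = [
            contig("c1", "TRA", "AAA"), contig("c1", "TRB", "CCC"),
            contig("c2", "TRA", "AAA"),
        ]
        cells = build_cell_clonotypes(recs)
        assign = reconcile_chain_subsets(cells)
        assert assign["c1"] == clone_key([("TRA", "AAA"), ("TRB", "CCC")])

    def test_dropout_cells_merge_in_synthetic_sample(self, small_cohort):
        truth = small_cohort.truth.cells.set_index("barcode")
        data = small_cohort.samples["P1"]
        cells = build_cell_clonotypes(data.contigs)
        assign = reconcile_chain_subsets(cells)
        t = truth[truth.patient == "P1"]
        dropouts = t.index[
            t.is_malignant & t.tcr_status.isin(["alpha_only", "beta_only"])
        ]
        merged = [assign[b] == small_cohort.truth.clone_keys["P1"]
                  for b in dropouts if b in assign]
        assert merged and np.mean(merged) >= 0.99


class TestMalignantCall:
    def _cells(self, clone_sizes, productive=True, umis=10):
        recs = []
        for idx, (cdr3, n) in enumerate(clone_sizes.items()):
            for i in range(n):
                b = f"{cdr3}_{i}"
                recs += [
                    contig(b, "TRA", f"A{cdr3}", productive=productive, umis=umis),
                    contig(b, "TRB", f"B{cdr3}", productive=productive, umis=umis),
                ]
        return build_cell_clonotypes(recs)

    def test_dominant_clone_and_ratio(self):
        cells = self._cells({"X": 60, "Y": 5, "Z": 1})
        key, prod, ratio, tie = call_malignant_clone(cells, "s")
        assert key == clone_key([("TRA", "AX"), ("TRB", "BX")])
        assert prod and ratio == 12 and not tie

    def test_nonproductive_dominant_clone_called_with_flag_unset(self):
        recs = []
        for i in range(80):
            recs += [
                contig(f"m{i}", "TRA", "AM", productive=False),
                contig(f"m{i}", "TRB", "BM", productive=False),
            ]
        for i in range(2):
            recs += [
                contig(f"r{i}", "TRA", f"AR{i}"), contig(f"r{i}", "TRB", f"BR{i}"),
            ]
        key, prod, ratio, _ = call_malignant_clone(build_cell_clonotypes(recs), "s")
        assert key == clone_key([("TRA", "AM"), ("TRB", "BM")]) and prod is False

    def test_tie_broken_lexicographically_with_warning(self):
        cells = self._cells({"A": 10, "B": 10})
        with pytest.warns(UserWarning, match="tied"):
            key, _, ratio, tie = call_malignant_clone(cells, "s")
        assert tie and ratio == 1.0
        assert key == min(
            clone_key([("TRA", "AA"), ("TRB", "BA")]),
            clone_key([("TRA", "AB"), ("TRB", "BB")]),
        )

    def test_no_tcr_raises(self):
        with pytest.raises(NoTCRInformationError):
            call_malignant_clone({}, "empty")

    def test_polyclonal_sample_refused_by_dominance_policy(self):
        cells = self._cells({f"c{i}": 1 for i in range(30)})
        with pytest.raises(NoTCRInformationError, match="dominance"):
            call_malignant_clone(cells, "s", min_fraction=0.10)

    def test_order_invariance(self):
        recs = []
        for i in range(20):
            recs += [contig(f"m{i}", "TRA", "AM", umis=7), contig(f"m{i}", "TRB", "BM", umis=9)]
        for i in range(6):
            recs += [contig(f"r{i}", "TRA", f"AR{i}"), contig(f"r{i}", "TRB", f"BR{i}")]
        fwd = call_malignant_clone(build_cell_clonotypes(recs), "s")
        rev = call_malignant_clone(build_cell_clonotypes(recs[::-1]), "s")
        assert fwd == rev


class TestPartition:
    def _setup(self):
        recs = []
        for i in range(60):
            recs += [contig(f"m{i}", "TRA", "AM"), contig(f"m{i}", "TRB", "BM")]
        for i in range(30):
            recs += [contig(f"r{i}", "TRA", f"AR{i}"), contig(f"r{i}", "TRB", f"BR{i}")]
        barcodes = [f"m{i}" for i in range(60)] + [f"r{i}" for i in range(30)]
        barcodes += [f"n{i}" for i in range(10)]  # T cells without recovered TCR
        return recs, barcodes

    def test_labels_partition_and_fraction(self):
        recs, barcodes = self._setup()
        call = partition_cells(barcodes, build_cell_clonotypes(recs), "s")
        counts = call.labels.value_counts()
        assert counts["malignant"] == 60 and counts["reactive"] == 30
        assert counts["unassigned"] == 10
        assert call.malignant_fraction == pytest.approx(60 / 90)

    def test_partition_covers_all_t_cells_disjointly(self):
        recs, barcodes = self._setup()
        call = partition_cells(barcodes, build_cell_clonotypes(recs), "s")
        assert sorted(call.labels.index) == sorted(barcodes)
        assert set(call.labels.unique()) <= {"malignant", "reactive", "unassigned"}

    def test_single_clone_sample_has_fraction_one(self):
        recs = []
        for i in range(50):
            recs += [contig(f"m{i}", "TRA", "AM"), contig(f"m{i}", "TRB", "BM")]
        call = partition_cells([f"m{i}" for i in range(50)],
                               build_cell_clonotypes(recs), "s")
        assert call.malignant_fraction == 1.0
        assert (call.labels == "reactive").sum() == 0

    def test_fraction_recovered_on_synthetic_sample(self, small_cohort):
        truth = small_cohort.truth.cells.set_index("barcode")
        data = small_cohort.samples["P1"]
        t = truth[(truth.patient == "P1") & truth.is_t_cell]
        call = partition_cells(t.index.tolist(),
                               build_cell_clonotypes(data.contigs), "P1")
        assert call.malignant_fraction == pytest.approx(0.5, abs=0.02)
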