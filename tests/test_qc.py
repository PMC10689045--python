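"""Per-barcode QC metrics, threshold cell calling and matrix filtering."""

import json

import numpy as np
import pandas as pd
import pytest

from atacprep.features import FeatureSet, count_matrix, make_bins
from atacprep.qc import (
    FilterThresholds,
    barcode_metrics,
    call_cells_filter,
    filter_matrix,
    qc_summary,
)


def frag_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])


def feature_set(rows, chrom_order=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["id"] = df.chrom + ":" + df.start.astype(str) + "-" + df.end.astype(str)
    return FeatureSet(df, chrom_order=chrom_order)


class TestBarcodeMetrics:
    def test_eight_of_ten_in_peaks(self):
        peaks = feature_set([("chr1", 100, 200)])
        rows = [("chr1", 100 + i, 150 + i, "BC", 1) for i in range(8)]
        rows += [("chr1", 5000, 5100, "BC", 1), ("chr1", 9000, 9100, "BC", 1)]
        qc = barcode_metrics(frag_df(rows), peaks)
        assert qc.loc["BC", "total_fragments"] == 10
        assert qc.loc["BC", "frac_in_peaks"] == pytest.approx(0.8)

    def test_annotation_columns_absent_when_not_supplied(self):
        qc = barcode_metrics(frag_df([("chr1", 0, 50, "BC", 1)]),
                             feature_set([("chr1", 100, 200)]))
        assert not any(c.startswith("frac_tss") for c in qc.columns)
        assert "frac_mito" not in qc.columns

    def test_annotation_and_mito_fractions(self):
        peaks = feature_set([("chr1", 100, 200)])
        tss = feature_set([("chr1", 0, 60)])
        rows = [("chr1", 10, 50, "BC", 1), ("chr1", 120, 160, "BC", 1),
                ("chrM", 5, 40, "BC", 1), ("chrM", 50, 90, "BC", 1)]
        qc = barcode_metrics(frag_df(rows), peaks, {"tss": tss}, ["chrM"])
        assert qc.loc["BC", "frac_tss"] == pytest.approx(0.25)
        assert qc.loc["BC", "frac_mito"] == pytest.approx(0.5)
        assert qc.loc["BC", "frac_in_peaks"] == pytest.approx(0.25)

    def test_fraction_in_peaks_is_an_exact_count_ratio(self, truth, peaks):
        """Recovered per-barcode FRiP equals a brute-force recount of the truth."""
        frags = truth.fragments.rename(columns={"n_reads": "count"})
        qc = barcode_metrics(frags, peaks)
        ivs = peaks.intervals()
        sample = list(truth.cell_barcodes)[:8] + list(truth.ambient_barcodes)[:8]
        for bc in sample:
            sub = frags[frags.barcode == bc]
            if not len(sub):
                continue
            hits = sum(
                any(c == r.chrom and r.start < e and r.end > s for c, s, e, _ in ivs)
                for r in sub.itertuples()
            )
            assert qc.loc[bc, "total_fragments"] == len(sub)
            assert qc.loc[bc, "frac_in_peaks"] == pytest.approx(hits / len(sub))
            assert (qc.loc[bc, "frac_in_peaks"] * len(sub)) == pytest.approx(
                round(qc.loc[bc, "frac_in_peaks"] * len(sub)))

    def test_region_fractions_bounded(self, truth, peaks):
        frags = truth.fragments.rename(columns={"n_reads": "count"})
        qc = barcode_metrics(frags, peaks, mito_contigs=["chrM"])
        assert qc.frac_in_peaks.between(0, 1).all()
        assert qc.frac_mito.between(0, 1).all()

    def test_empty_input(self):
        qc = barcode_metrics(frag_df([]), feature_set([("chr1", 0, 10)]))
        assert len(qc) == 0


class TestCallCells:
    def test_vacuous_thresholds_admit_everything(self, truth, peaks):
        frags = truth.fragments.rename(columns={"n_reads": "count"})
        qc = barcode_metrics(frags, peaks)
        cells, labelled = call_cells_filter(
            qc, FilterThresholds(min_total_fragments=0, min_frac_in_peaks=0.0,
                                 max_frac_mito=1.0))
        assert cells == set(qc.index)
        assert (labelled.label == "cell").all()

    def test_low_total_is_non_cell(self):
        qc = pd.DataFrame({"total_fragments": [5], "frac_in_peaks": [0.9]},
                          index=pd.Index(["BC"], name="barcode"))
        cells, labelled = call_cells_filter(
            qc, FilterThresholds(min_total_fragments=10, min_frac_in_peaks=0.1))
        assert cells == set() and labelled.loc["BC", "label"] == "non-cell"

    def test_mito_threshold_applies_only_when_available(self):
        qc = pd.DataFrame(
            {"total_fragments": [100, 100], "frac_in_peaks": [0.5, 0.5],
             "frac_mito": [0.1, 0.9]},
            index=pd.Index(["A", "B"], name="barcode"))
        cells, _ = call_cells_filter(qc, FilterThresholds(
            min_total_fragments=10, min_frac_in_peaks=0.1, max_frac_mito=0.2))
        assert cells == {"A"}
        cells2, _ = call_cells_filter(qc.drop(columns="frac_mito"),
                                      FilterThresholds(min_total_fragments=10,
                                                       min_frac_in_peaks=0.1,
                                                       max_frac_mito=0.2))
        assert cells2 == {"A", "B"}

    def test_monotone_in_every_threshold(self, truth, peaks):
        frags = truth.fragments.rename(columns={"n_reads": "count"})
        qc = barcode_metrics(frags, peaks, mito_contigs=["chrM"])
        rng = np.random.default_rng(0)
        for _ in range(10):
            base = FilterThresholds(
                min_total_fragments=int(rng.integers(0, 120)),
                min_frac_in_peaks=float(rng.uniform(0, 0.8)),
                max_frac_mito=float(rng.uniform(0.05, 1.0)),
            )
            n_base = len(call_cells_filter(qc, base)[0])
            for raised in (
                FilterThresholds(base.min_total_fragments + 20,
                                 base.min_frac_in_peaks, base.max_frac_mito),
                FilterThresholds(base.min_total_fragments,
                                 min(base.min_frac_in_peaks + 0.1, 1.0),
                                 base.max_frac_mito),
                FilterThresholds(base.min_total_fragments,
                                 base.min_frac_in_peaks,
                                 base.max_frac_mito * 0.5),
            ):
                assert len(call_cells_filter(qc, raised)[0]) <= n_base


class TestFilterMatrix:
    def _matrix(self, truth):
        frags = truth.fragments.rename(columns={"n_reads": "count"})
        return count_matrix(frags, make_bins(truth.reference.chrom_sizes, 5000))

    def test_min_one_cell_per_feature_drops_exactly_zero_rows(self, truth):
        m = self._matrix(truth)
        out = filter_matrix(m, set(m.barcodes), FilterThresholds(
            min_cells_per_feature=1, min_features_per_cell=0))
        dense = m.to_dense()
        assert out.shape[0] == int((dense.sum(axis=1) > 0).sum())
        assert out.shape[1] == m.shape[1]

    def test_identity_with_full_set_and_zero_thresholds(self, truth):
        m = self._matrix(truth)
        out = filter_matrix(m, set(m.barcodes), FilterThresholds(
            min_cells_per_feature=0, min_features_per_cell=0))
        assert out.shape == m.shape
        assert (out.matrix != m.matrix).nnz == 0

    def test_matches_dense_refilter(self, truth):
        m = self._matrix(truth)
        cells = set(list(truth.cell_barcodes)[:15])
        th = FilterThresholds(min_cells_per_feature=3, min_features_per_cell=5)
        out = filter_matrix(m, cells, th)

        dense = pd.DataFrame(m.to_dense(), index=m.feature_ids, columns=m.barcodes)
        dense = dense[[b for b in m.barcodes if b in cells]]
        dense = dense[(dense > 0).sum(axis=1) >= th.min_cells_per_feature]
        dense = dense.loc[:, (dense > 0).sum(axis=0) >= th.min_features_per_cell]
        assert out.feature_ids == dense.index.tolist()
        assert out.barcodes == dense.columns.tolist()
        np.testing.assert_array_equal(out.to_dense(), dense.to_numpy())

    def test_idempotent_at_fixed_thresholds(self, truth):
        m = self._matrix(truth)
        th = FilterThresholds(min_cells_per_feature=2, min_features_per_cell=3)
        once = filter_matrix(m, set(m.barcodes), th)
        twice = filter_matrix(once, set(once.barcodes), th)
        assert once.feature_ids == twice.feature_ids
        assert once.barcodes == twice.barcodes

    def test_empty_result_warns_not_raises(self, truth):
        m = self._matrix(truth)
        with pytest.warns(UserWarning, match="empty"):
            out = filter_matrix(m, set(), FilterThresholds())
        assert out.shape[1] == 0


class TestQcSummary:
    def test_parameters_logged_verbatim_and_totals_conserved(self, truth, peaks,
                                                             tmp_path):
        frags = truth.fragments.rename(columns={"n_reads": "count"})
        qc = barcode_metrics(frags, peaks)
        _, labelled = call_cells_filter(qc)
        params = {"bin_size": 2000, "min_mapq": 30, "flavour": "test-run"}
        summary = qc_summary(labelled, tmp_path, parameters=params,
                             demux_stats={"complete_match": 123})
        on_disk = json.loads((tmp_path / "qc_summary.json").read_text())
        assert on_disk["parameters"] == params
        assert on_disk["demux_stats"] == {"complete_match": 123}
        assert summary["total_fragments"] == int(qc.total_fragments.sum())
        table = pd.read_csv(tmp_path / "qc_per_barcode.tsv", sep="\t",
                            index_col="barcode")
        assert len(table) == len(qc)

    def test_empty_experiment_is_a_valid_report(self, tmp_path):
        qc = pd.DataFrame(columns=["total_fragments", "frac_in_peaks"],
                          ).rename_axis("barcode")
        summary = qc_summary(qc, tmp_path)
        assert summary["n_barcodes"] == 0 and summary["total_fragments"] == 0

    def test_plots_and_html_render(self, truth, peaks, tmp_path):
        frags = truth.fragments.rename(columns={"n_reads": "count"})
        qc = barcode_metrics(frags, peaks)
        _, labelled = call_cells_filter(qc)
        qc_summary(labelled, tmp_path, plots=True, html=True)
        assert (tmp_path / "report.html").exists()
        assert (tmp_path / "frip_vs_fragments.png").exists()


class TestThresholdValidation:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_frac_in_peaks=1.5)
        with pytest.raises(ValueError):
            FilterThresholds(min_total_fragments=-1)
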