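"""Barcode correction semantics and the four-way read partition."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from atacprep._utils import revcomp
from atacprep.demux import BarcodeSpec, Whitelist, demultiplex
from atacprep.simulate import emit_reads

Q = lambda *vals: list(vals)  # noqa: E731


class TestCorrectBarcode:
    def test_exact_identity(self):
        wl = Whitelist(["ACGT"])
        res = wl.correct("ACGT", Q(30, 30, 30, 30))
        assert res.status == "exact" and res.barcode == "ACGT"

    def test_single_mismatch_is_rescued(self):
        wl = Whitelist(["ACGT"])
        res = wl.correct("ACGA", Q(30, 30, 30, 30))
        assert res.status == "corrected"
        assert res.barcode == "ACGT" and res.mismatch_position == 3

    def test_lowest_q_at_mismatch_position_wins(self):
        # candidates: TCGA (mismatch at 0, Q40) vs ACGT (mismatch at 3, Q10)
        wl = Whitelist(["TCGA", "ACGT"])
        res = wl.correct("ACGA", Q(40, 30, 30, 10))
        assert res.status == "corrected" and res.barcode == "ACGT"
        assert res.mismatch_position == 3

    def test_symmetric_tie_is_ambiguous(self):
        wl = Whitelist(["ACGT", "ATGT"])
        res = wl.correct("AGGT", Q(30, 30, 30, 30))
        assert res.status == "ambiguous" and res.barcode is None

    def test_two_or_more_mismatches_unmatched(self):
        wl = Whitelist(["ACGT"])
        assert wl.correct("TTGT", Q(30, 30, 30, 30)).status == "unmatched"

    def test_length_mismatch_is_an_error(self):
        wl = Whitelist(["ACGT"])
        with pytest.raises(ValueError, match="length"):
            wl.correct("ACGTA", Q(30, 30, 30, 30, 30))

    def test_n_is_never_exact_and_counts_as_mismatch(self):
        wl = Whitelist(["ACGT"])
        res = wl.correct("ACGN", Q(30, 30, 30, 2))
        assert res.status == "corrected" and res.barcode == "ACGT"

    def test_quality_string_accepted(self):
        wl = Whitelist(["ACGT"])
        res = wl.correct("ACGA", "IIII")
        assert res.status == "corrected"

    @given(st.text(alphabet="ACGT", min_size=6, max_size=6))
    def test_valid_barcode_never_moved(self, bc):
        wl = Whitelist([bc, "A" * 6])
        assert wl.correct(bc, [30] * 6).status == "exact"

    @given(
        st.lists(st.text(alphabet="ACGT", min_size=5, max_size=5),
                 min_size=1, max_size=8, unique=True),
        st.text(alphabet="ACGTN", min_size=5, max_size=5),
    )
    def test_correction_contract(self, wl_entries, observed):
        """exact => verbatim member; corrected => Hamming distance exactly 1."""
        res = Whitelist(wl_entries).correct(observed, [30] * 5)
        if res.status == "exact":
            assert res.barcode == observed and observed in wl_entries
        elif res.status == "corrected":
            assert sum(a != b for a, b in zip(observed, res.barcode)) == 1
        else:
            assert res.barcode is None


class TestBatchMatchesScalar:
    def test_batch_equals_scalar_on_fixture(self, truth, emission):
        wl = Whitelist(truth.whitelist)
        sample = emission.expected.head(200)
        batch = wl.correct_batch(
            sample.observed_barcode.tolist(),
            ["I" * 12] * len(sample),
        )
        for row, res in zip(sample.itertuples(), batch):
            assert res == wl.correct(row.observed_barcode, "I" * 12)


class TestDemultiplex:
    def test_clean_reads_all_complete(self, truth, tmp_path):
        em = emit_reads(truth, tmp_path / "r", barcode_error_rate=0.0, seed=5)
        part = demultiplex(
            em.r1, em.r2, tmp_path / "d", index_fastq=em.index_fastq,
            whitelist=Whitelist(truth.whitelist),
        )
        assert part.counts["complete_match"] == truth.n_read_pairs
        assert part.counts["partial_match"] == 0
        assert part.counts["no_match"] == 0

    def test_partition_sums_to_input(self, truth, emission, tmp_path):
        part = demultiplex(
            emission.r1, emission.r2, tmp_path, index_fastq=emission.index_fastq,
            whitelist=Whitelist(truth.whitelist),
        )
        assert part.total == truth.n_read_pairs

    def test_matched_read_names_start_with_whitelist_barcode(
        self, truth, emission, tmp_path
    ):
        import pysam

        part = demultiplex(
            emission.r1, emission.r2, tmp_path, index_fastq=emission.index_fastq,
            whitelist=Whitelist(truth.whitelist),
        )
        wl = set(truth.whitelist)
        for cat in ("complete_match", "partial_match"):
            with pysam.FastxFile(part.files[cat][0]) as fh:
                for rec in fh:
                    assert rec.name.split("#")[0] in wl

    def test_full_data_is_the_concatenation(self, truth, emission, tmp_path):
        part = demultiplex(
            emission.r1, emission.r2, tmp_path, index_fastq=emission.index_fastq,
            whitelist=Whitelist(truth.whitelist),
        )

        def names(path):
            import pysam

            with pysam.FastxFile(path) as fh:
                return [r.name for r in fh]

        cat_names = sum((names(part.files[c][0]) for c in
                         ("complete_match", "partial_match", "no_match")), [])
        assert sorted(cat_names) == sorted(names(part.files["full_data"][0]))
        assert len(cat_names) == part.total

    def test_reverse_complement_mode_reproduces_forward_partition(
        self, truth, emission, tmp_path
    ):
        import pysam

        from atacprep._utils import FastqWriter

        rc_index = tmp_path / "index_rc.fastq"
        with pysam.FastxFile(emission.index_fastq) as fh, FastqWriter(rc_index) as w:
            for rec in fh:
                w.write(rec.name, revcomp(rec.sequence), rec.quality[::-1])
        wl = Whitelist(truth.whitelist)
        fwd = demultiplex(
            emission.r1, emission.r2, tmp_path / "fwd",
            index_fastq=emission.index_fastq, whitelist=wl,
            record_assignments=True,
        )
        rev = demultiplex(
            emission.r1, emission.r2, tmp_path / "rev", index_fastq=rc_index,
            whitelist=wl, reverse_complement=True, record_assignments=True,
        )
        assert fwd.counts == rev.counts
        assert fwd.assignments == rev.assignments

    def test_embedded_mode_matches_index_mode(self, truth, tmp_path):
        emi = emit_reads(truth, tmp_path / "i", mode="index-fastq",
                         barcode_error_rate=0.15, seed=77)
        eme = emit_reads(truth, tmp_path / "e", mode="embedded",
                         barcode_error_rate=0.15, seed=77)
        wl = Whitelist(truth.whitelist)
        pi = demultiplex(emi.r1, emi.r2, tmp_path / "di",
                         index_fastq=emi.index_fastq, whitelist=wl)
        spec = BarcodeSpec.from_csv(eme.barcode_csv)
        pe = demultiplex(eme.r1, eme.r2, tmp_path / "de", barcode_spec=spec,
                         whitelist=wl)
        assert {k: pi.counts[k] for k in ("complete_match", "partial_match", "no_match")} \
            == {k: pe.counts[k] for k in ("complete_match", "partial_match", "no_match")}

    def test_embedded_mode_strips_barcode_from_reads(self, truth, tmp_path):
        import pysam

        eme = emit_reads(truth, tmp_path / "e", mode="embedded", seed=7)
        spec = BarcodeSpec.from_csv(eme.barcode_csv)
        part = demultiplex(eme.r1, eme.r2, tmp_path / "d", barcode_spec=spec,
                           whitelist=Whitelist(truth.whitelist))
        with pysam.FastxFile(part.files["complete_match"][0]) as fh:
            rec = next(iter(fh))
        assert len(rec.sequence) == 50  # barcode removed

    def test_no_whitelist_passthrough(self, truth, emission, tmp_path):
        part = demultiplex(
            emission.r1, emission.r2, tmp_path, index_fastq=emission.index_fastq,
            whitelist=None,
        )
        assert part.counts["complete_match"] == truth.n_read_pairs
        assert sum(part.barcode_counts.values()) == truth.n_read_pairs

    def test_record_count_mismatch_names_files(self, truth, emission, tmp_path):
        import itertools

        short_r2 = tmp_path / "short_R2.fastq"
        with open(emission.r2) as fh, open(short_r2, "w") as out:
            out.writelines(itertools.islice(fh, 8))  # keep only 2 records
        with pytest.raises(ValueError, match="mismatch"):
            demultiplex(emission.r1, short_r2, tmp_path / "d",
                        index_fastq=emission.index_fastq,
                        whitelist=Whitelist(truth.whitelist))

    def test_parameters_are_logged(self, truth, emission, tmp_path):
        import json

        demultiplex(emission.r1, emission.r2, tmp_path,
                    index_fastq=emission.index_fastq,
                    whitelist=Whitelist(truth.whitelist), separator="#")
        log = json.loads((tmp_path / "demux_log.json").read_text())
        assert log["separator"] == "#"
        assert log["whitelist_size"] == len(truth.whitelist)


class TestBarcodeSpec:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            BarcodeSpec("sideways", 16)

    def test_embedded_requires_rows(self):
        with pytest.raises(ValueError, match="csv_rows"):
            BarcodeSpec("embedded-csv", 16)
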