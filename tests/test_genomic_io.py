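"""Binning, track aggregation, feature parsing and state-track round trips."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromband.genomic_io import (
    FeatureSet,
    GeneModels,
    MalformedRecordError,
    build_bins,
    read_chrom_sizes,
    read_features,
    read_signal_track,
    read_state_track,
    write_state_track,
)


class TestBuildBins:
    def test_exact_tiling(self):
        bins = build_bins({"chrX": 1000}, 200)
        assert bins.n_bins == 5
        assert not bins.partial_mask().any()

    def test_global_order_follows_input(self):
        bins = build_bins({"chrX": 1000, "chr2L": 400}, 200)
        assert bins.n_bins == 7
        assert bins.chrom_range("chrX") == (0, 5)
        assert bins.chrom_range("chr2L") == (5, 7)

    def test_partial_terminal_bin_kept_and_flagged(self):
        bins = build_bins({"chrX": 1100}, 200)
        assert bins.n_bins == 6
        assert bins.interval(5) == ("chrX", 1000, 1100)
        assert bins.partial_mask().tolist() == [False] * 5 + [True]

    @pytest.mark.parametrize("sizes,width", [({"chrX": 0}, 200), ({"chrX": 100}, 0),
                                             ({"chrX": -5}, 200), ({"chrX": 100}, -1)])
    def test_invalid_inputs_rejected(self, sizes, width):
        with pytest.raises(ValueError):
            build_bins(sizes, width)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.dictionaries(st.sampled_from(["chr1", "chr2", "chr3"]),
                           st.integers(1, 5000), min_size=1),
           st.integers(1, 700))
    def test_bin_widths_partition_each_chromosome(self, sizes, width):
        bins = build_bins(sizes, width)
        widths = bins.bin_widths()
        for c in sizes:
            lo, hi = bins.chrom_range(c)
            assert widths[lo:hi].sum() == sizes[c]


class TestSignalTrack:
    def test_single_full_bin_line(self, small_bins, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chrX\t0\t200\t1.5\n")
        values, mask = read_signal_track(p, small_bins)
        assert values[0] == 1.5 and not mask[0]
        assert mask[1:].all()

    def test_coverage_weighted_mean(self, small_bins, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chrX\t0\t100\t2.0\nchrX\t100\t200\t4.0\n")
        values, _ = read_signal_track(p, small_bins)
        assert values[0] == pytest.approx(3.0)

    def test_uncovered_bin_masked(self, small_bins, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chrX\t0\t400\t1.0\nchrX\t600\t1000\t2.0\n")
        values, mask = read_signal_track(p, small_bins)
        assert mask[2] and np.isnan(values[2])
        assert not mask[[0, 1, 3, 4]].any()

    def test_unknown_chromosome_warns_and_skips(self, small_bins, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chrUn\t0\t200\t9.0\nchrX\t0\t200\t1.0\n")
        with pytest.warns(UserWarning, match="chrUn"):
            values, _ = read_signal_track(p, small_bins)
        assert values[0] == 1.0

    def test_malformed_line_reports_line_number(self, small_bins, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chrX\t0\t200\t1.0\nchrX\tnot_an_int\t400\t2.0\n")
        with pytest.raises(MalformedRecordError, match=":2"):
            read_signal_track(p, small_bins)

    def test_fixedstep_wig_matches_bedgraph(self, small_bins, tmp_path):
        bg = tmp_path / "t.bedGraph"
        bg.write_text("".join(f"chrX\t{i*200}\t{(i+1)*200}\t{float(i)}\n" for i in range(5)))
        wig = tmp_path / "t.wig"
        wig.write_text("fixedStep chrom=chrX start=1 step=200 span=200\n"
                       + "".join(f"{float(i)}\n" for i in range(5)))
        vb, mb = read_signal_track(bg, small_bins)
        vw, mw = read_signal_track(wig, small_bins)
        np.testing.assert_array_equal(vb, vw)
        np.testing.assert_array_equal(mb, mw)

    def test_variablestep_wig(self, small_bins, tmp_path):
        wig = tmp_path / "t.wig"
        wig.write_text("variableStep chrom=chrX span=200\n1\t2.5\n201\t3.5\n")
        values, mask = read_signal_track(wig, small_bins)
        assert values[0] == 2.5 and values[1] == 3.5
        assert mask[2:].all()

    def test_reader_determinism(self, small_bins, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chrX\t0\t150\t1.0\nchrX\t150\t500\t2.0\n")
        a = read_signal_track(p, small_bins)
        b = read_signal_track(p, small_bins)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestFeatures:
    def test_bed6_point(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chrX\t100\t101\tins1\t0\t+\n")
        fs = read_features(p, format="bed")
        rec = fs.df.iloc[0]
        assert (rec["start"], rec["end"], rec["strand"], rec["name"]) == (100, 101, "+", "ins1")

    def test_one_based_inclusive_point_converts(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chrX\t101\t101\n")
        fs = read_features(p, format="tsv", one_based=True,
                           columns={"chrom": 0, "start": 1, "end": 2})
        assert (fs.df.loc[0, "start"], fs.df.loc[0, "end"]) == (100, 101)

    def test_bed3_defaults_to_no_strand(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chrX\t0\t500\n")
        fs = read_features(p, format="bed")
        assert fs.df.loc[0, "strand"] == "."

    def test_empty_interval_rejected_with_warning(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chrX\t100\t100\nchrX\t0\t10\n")
        with pytest.warns(UserWarning, match="rejected"):
            fs = read_features(p, format="bed")
        assert len(fs) == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 10**6), st.integers(0, 1000))
    def test_one_based_round_trip_identity(self, start, length):
        # 1-based inclusive (s, e) -> half-open [s-1, e) -> back
        end = start + length
        half_open = (start - 1, end)
        back = (half_open[0] + 1, half_open[1])
        assert back == (start, end)


class TestStateTrack:
    def test_bed9_line_format(self, tmp_path):
        df = pd.DataFrame([{"chrom": "chrX", "start": 0, "end": 400, "state": "cyan"}])
        p = tmp_path / "s.bed"
        write_state_track(df, p)
        assert p.read_text() == "chrX\t0\t400\tcyan\t0\t.\t0\t400\t0,255,255\n"

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame([
            {"chrom": "chrX", "start": 0, "end": 400, "state": "cyan"},
            {"chrom": "chrX", "start": 400, "end": 1000, "state": "blue"},
            {"chrom": "chr2L", "start": 0, "end": 200, "state": "magenta"},
        ])
        p = tmp_path / "s.bed"
        write_state_track(df, p)
        back = read_state_track(p)
        pd.testing.assert_frame_equal(back, df)

    def test_empty_fragment_list(self, tmp_path):
        p = tmp_path / "s.bed"
        write_state_track(pd.DataFrame(columns=["chrom", "start", "end", "state"]), p)
        assert p.read_text() == ""

    def test_overlapping_fragments_rejected(self, tmp_path):
        df = pd.DataFrame([
            {"chrom": "chrX", "start": 0, "end": 400, "state": "cyan"},
            {"chrom": "chrX", "start": 200, "end": 600, "state": "blue"},
        ])
        with pytest.raises(ValueError, match="unsorted or overlapping"):
            write_state_track(df, tmp_path / "s.bed")


class TestGeneModels:
    def test_tss_respects_strand(self):
        gm = GeneModels(pd.DataFrame([
            {"gene_id": "a", "chrom": "chrX", "start": 100, "end": 500, "strand": "+"},
            {"gene_id": "b", "chrom": "chrX", "start": 700, "end": 900, "strand": "-"},
        ]))
        tss = gm.tss()
        assert tss["a"] == 100 and tss["b"] == 899

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([
            {"gene_id": "a", "chrom": "chrX", "start": 0, "end": 10, "strand": "+"},
            {"gene_id": "a", "chrom": "chrX", "start": 20, "end": 30, "strand": "+"},
        ])
        with pytest.raises(ValueError, match="unique"):
            GeneModels(df)


def test_read_chrom_sizes(tmp_path):
    p = tmp_path / "c.sizes"
    p.write_text("chrX\t1000\nchr2L\t400\n")
    assert read_chrom_sizes(p) == {"chrX": 1000, "chr2L": 400}
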