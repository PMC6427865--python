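import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadfuse.genome_io import (
    BinScheme,
    ContactMatrix,
    Deletion,
    filter_deletions,
    map_deletion_to_bins,
    read_contact_matrix,
    read_deletions_bed,
    read_loop_anchors,
    write_contact_matrix,
)


class TestBinScheme:
    def test_bin_covers_half_open_interval(self):
        s = BinScheme("chr1", 5000, 10)
        assert s.bin_of_bp(0) == 1
        assert s.bin_of_bp(4999) == 1
        assert s.bin_of_bp(5000) == 2
        assert s.bin_span_bp(3) == (10000, 15000)

    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            BinScheme("chr1", 0, 10)
        with pytest.raises(ValueError):
            BinScheme("chr1", 5000, 0)
        with pytest.raises(ValueError):
            BinScheme("chr1", 5000, 3).bin_of_bp(15000)


class TestReadContactMatrix:
    def test_triplets_populate_symmetrically(self):
        s = BinScheme("chr1", 5000, 3)
        H = read_contact_matrix(io.StringIO("1 2 10\n2 3 4\n"), s)
        assert H.get(1, 2) == H.get(2, 1) == 10
        assert H.get(2, 3) == H.get(3, 2) == 4
        assert H.get(1, 3) == 0

    def test_empty_stream_gives_zero_matrix(self):
        s = BinScheme("chr1", 5000, 5)
        H = read_contact_matrix(io.StringIO(""), s)
        assert len(H) == 0
        assert (H.to_dense() == 0).all()

    def test_out_of_range_index_is_error(self):
        s = BinScheme("chr1", 5000, 3)
        with pytest.raises(ValueError, match="outside"):
            read_contact_matrix(io.StringIO("1 9 3\n"), s)

    def test_negative_count_is_error(self):
        s = BinScheme("chr1", 5000, 3)
        with pytest.raises(ValueError, match="negative"):
            read_contact_matrix(io.StringIO("1 2 -1\n"), s)

    def test_duplicate_unordered_pair_is_error(self):
        s = BinScheme("chr1", 5000, 3)
        with pytest.raises(ValueError, match="duplicate"):
            read_contact_matrix(io.StringIO("1 2 3\n2 1 3\n"), s)

    def test_bin0_and_bp_dialects(self):
        s = BinScheme("chr1", 5000, 3)
        H0 = read_contact_matrix(io.StringIO("0 1 7\n"), s, coords="bin0")
        assert H0.get(1, 2) == 7
        Hbp = read_contact_matrix(io.StringIO("2500 7500 7\n"), s, coords="bp")
        assert Hbp.get(1, 2) == 7

    def test_round_trip_exact(self):
        s = BinScheme("chr1", 5000, 8)
        rng = np.random.default_rng(0)
        H = ContactMatrix(s)
        for i in range(1, 9):
            for j in range(i + 1, 9):
                H.set(i, j, float(rng.lognormal()))
        buf = io.StringIO()
        write_contact_matrix(H, buf)
        buf.seek(0)
        assert read_contact_matrix(buf, s) == H


class TestMapDeletionToBins:
    @pytest.mark.parametrize(
        "start,end,expect",
        [
            (12000, 31000, (4, 6)),   # bins [15k,20k),[20k,25k),[25k,30k)
            (0, 5000, (1, 1)),        # exactly one bin
            (2000, 9000, None),       # covers no whole bin
            (15000, 20000, (4, 4)),
        ],
    )
    def test_fully_contained_bins(self, start, end, expect):
        s = BinScheme("chr1", 5000, 20)
        d = map_deletion_to_bins(Deletion("chr1", start, end), s)
        if expect is None:
            assert d is None
        else:
            assert (d.x, d.y) == expect

    def test_outside_extent_is_error(self):
        s = BinScheme("chr1", 5000, 3)
        with pytest.raises(ValueError, match="extent"):
            map_deletion_to_bins(Deletion("chr1", 10000, 20000), s)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        start=st.integers(0, 80000),
        length=st.integers(1, 20000),
        grow_left=st.integers(0, 5000),
        grow_right=st.integers(0, 5000),
    )
    def test_enlarging_interval_never_shrinks_bin_range(
        self, start, length, grow_left, grow_right
    ):
        s = BinScheme("chr1", 5000, 30)
        end = min(start + length, s.chrom_length)
        d1 = map_deletion_to_bins(Deletion("chr1", start, end), s)
        big_start = max(0, start - grow_left)
        big_end = min(s.chrom_length, end + grow_right)
        d2 = map_deletion_to_bins(Deletion("chr1", big_start, big_end), s)
        if d1 is not None:
            assert d2 is not None
            assert d2.x <= d1.x and d2.y >= d1.y


class TestFilterDeletions:
    def test_containment_rule_decides_survival(self):
        s = BinScheme("chr1", 5000, 100)
        ds = [
            Deletion("chr1", 1000, 9000),     # 8 kb, covers no whole bin
            Deletion("chr1", 10000, 20000),   # 10 kb aligned: bins 3-4
            Deletion("chr1", 52000, 77000),   # 25 kb: at least 3 whole bins
            Deletion("chr1", 4000, 12000),    # 8 kb covering bin 2 fully
        ]
        kept = filter_deletions(ds, s)
        assert [(d.start_bp, d.x, d.y) for d in kept] == [
            (10000, 3, 4),
            (52000, 12, 15),
            (4000, 2, 2),
        ]

    def test_exclusion_overlap_removes(self):
        s = BinScheme("chr1", 5000, 100)
        d = Deletion("chr1", 10000, 30000)
        assert filter_deletions([d], s, exclusion=[Deletion("chr1", 10000, 30000)]) == []
        assert filter_deletions([d], s, exclusion=[Deletion("chr1", 29999, 40000)]) == []
        kept = filter_deletions([d], s, exclusion=[Deletion("chr1", 30000, 40000)])
        assert len(kept) == 1

    def test_empty_input(self):
        s = BinScheme("chr1", 5000, 100)
        assert filter_deletions([], s) == []

    def test_survivors_have_at_least_one_bin(self):
        s = BinScheme("chr1", 5000, 100)
        rng = np.random.default_rng(1)
        ds = []
        for _ in range(50):
            a = int(rng.integers(0, 400000))
            b = a + int(rng.integers(1, 60000))
            ds.append(Deletion("chr1", a, min(b, s.chrom_length)))
        for d in filter_deletions(ds, s):
            assert d.y - d.x + 1 >= 1
            assert d.start_bp <= (d.x - 1) * 5000 and d.y * 5000 <= d.end_bp


class TestReadLoopAnchors:
    def test_midpoint_binning(self, scheme6):
        s = BinScheme("chr1", 5000, 20)
        line = "chr1\t5000\t10000\tchr1\t40000\t45000\n"
        loops = read_loop_anchors(io.StringIO(line), s)
        assert loops.pairs == [(2, 9)]  # midpoints 7500 and 42500

    def test_same_bin_anchors_dropped(self):
        s = BinScheme("chr1", 5000, 20)
        line = "chr1\t1000\t2000\tchr1\t3000\t4000\n"
        assert len(read_loop_anchors(io.StringIO(line), s)) == 0

    def test_interchromosomal_skipped_with_warning(self):
        s = BinScheme("chr1", 5000, 20)
        text = "chr1\t0\t5000\tchr2\t40000\t45000\nchr1\t0\t5000\tchr1\t40000\t45000\n"
        with pytest.warns(UserWarning, match="inter-chromosomal"):
            loops = read_loop_anchors(io.StringIO(text), s)
        assert loops.pairs == [(1, 9)]

    def test_empty_file(self):
        s = BinScheme("chr1", 5000, 20)
        assert len(read_loop_anchors(io.StringIO(""), s)) == 0


def test_read_deletions_bed_filters_chromosome():
    text = "chr1\t0\t20000\nchr2\t0\t30000\n# comment\n"
    ds = read_deletions_bed(io.StringIO(text), chrom="chr1")
    assert len(ds) == 1 and ds[0].end_bp == 20000
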