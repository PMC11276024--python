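"""Signal tracks: bedGraph/BAM loading and window primitives."""

import numpy as np
import pysam
import pytest

from termindex import (
    SampleSheet,
    SignalTrack,
    cds_mean_density,
    load_track,
    track_from_alignments,
    window_count,
    write_bedgraph,
)
from helpers import brute_force_window_count, make_gene, random_sparse_track


class TestBedGraph:
    def test_half_open_interval_expands_to_one_based_positions(self, tmp_path):
        """bedGraph 'chrI 9 12 3' covers 1-based positions 10, 11, 12."""
        plus = tmp_path / "p.bg"
        minus = tmp_path / "m.bg"
        plus.write_text("chrI\t9\t12\t3\n")
        minus.write_text("")
        t = load_track(plus, minus)
        assert list(t.counts("chrI", "+", 9, 13)) == [0, 3, 3, 3, 0]

    def test_empty_pair_gives_zero_track(self, tmp_path):
        (tmp_path / "p.bg").write_text("")
        (tmp_path / "m.bg").write_text("")
        t = load_track(tmp_path / "p.bg", tmp_path / "m.bg")
        assert t.total() == 0

    def test_negative_minus_strand_values_stored_as_magnitudes(self, tmp_path):
        (tmp_path / "p.bg").write_text("")
        (tmp_path / "m.bg").write_text("chrI\t100\t105\t-2\n")
        t = load_track(tmp_path / "p.bg", tmp_path / "m.bg")
        assert list(t.counts("chrI", "-", 101, 105)) == [2] * 5

    def test_conflicting_overlap_raises(self, tmp_path):
        (tmp_path / "p.bg").write_text("chrI\t0\t10\t3\nchrI\t5\t15\t4\n")
        (tmp_path / "m.bg").write_text("")
        with pytest.raises(ValueError, match="conflicting"):
            load_track(tmp_path / "p.bg", tmp_path / "m.bg")

    def test_non_integer_values_rounded_with_warning(self, tmp_path, caplog):
        (tmp_path / "p.bg").write_text("chrI\t0\t4\t2.6\n")
        (tmp_path / "m.bg").write_text("")
        with caplog.at_level("WARNING"):
            t = load_track(tmp_path / "p.bg", tmp_path / "m.bg")
        assert list(t.counts("chrI", "+", 1, 4)) == [3] * 4
        assert any("rounded" in r.message for r in caplog.records)

    def test_write_read_round_trip(self, tmp_path, rng):
        t = random_sparse_track(rng)
        for p, c in [(50, 2), (51, 2), (52, 7)]:
            t.add("chrII", "-", p, c)
        write_bedgraph(t, tmp_path / "p.bg", tmp_path / "m.bg")
        back = load_track(tmp_path / "p.bg", tmp_path / "m.bg")
        for chrom, strand in t.chrom_strand_keys():
            hi = 5000
            assert np.array_equal(t.counts(chrom, strand, 1, hi),
                                  back.counts(chrom, strand, 1, hi))


class TestBAM:
    @staticmethod
    def _write_bam(path, reads):
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "chrI", "LN": 100000}, {"SN": "chrII", "LN": 100000}]}
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for name, ref_id, start0, length, reverse, flags in reads:
                a = pysam.AlignedSegment()
                a.query_name = name
                a.reference_id = ref_id
                a.reference_start = start0
                a.cigarstring = f"{length}M"
                a.query_sequence = "A" * length
                a.mapping_quality = 60
                a.flag = (16 if reverse else 0) | flags
                bam.write(a)
        pysam.sort("-o", str(path), str(path))
        pysam.index(str(path))

    def test_three_prime_end_counting_matches_definition(self, tmp_path):
        """A + read 101-150 counts at 150 on +; a - read there counts at 101 on -."""
        bam = tmp_path / "two.bam"
        self._write_bam(bam, [("f", 0, 100, 50, False, 0), ("r", 0, 100, 50, True, 0)])
        t = track_from_alignments(bam)
        assert t.counts("chrI", "+", 150, 150)[0] == 1
        assert t.counts("chrI", "-", 101, 101)[0] == 1
        assert t.total() == 2

    def test_mini_bam_matches_brute_force_scan(self, tmp_path, rng):
        reads = []
        expected = {}
        for i in range(10):
            start0 = int(rng.integers(0, 5000))
            length = int(rng.integers(20, 80))
            reverse = bool(rng.random() < 0.5)
            ref = int(rng.integers(0, 2))
            reads.append((f"r{i}", ref, start0, length, reverse, 0))
            chrom = ["chrI", "chrII"][ref]
            pos = start0 + length if not reverse else start0 + 1
            strand = "-" if reverse else "+"
            expected[(chrom, strand, pos)] = expected.get((chrom, strand, pos), 0) + 1
        bam = tmp_path / "mini.bam"
        self._write_bam(bam, reads)
        t = track_from_alignments(bam)
        assert t.total() == 10
        for (chrom, strand, pos), n in expected.items():
            assert t.counts(chrom, strand, pos, pos)[0] == n

    def test_secondary_and_duplicate_reads_skipped(self, tmp_path):
        bam = tmp_path / "skip.bam"
        self._write_bam(bam, [
            ("keep", 0, 100, 50, False, 0),
            ("dup", 0, 100, 50, False, 0x400),
            ("sec", 0, 100, 50, False, 0x100),
        ])
        assert track_from_alignments(bam).total() == 1
        assert track_from_alignments(bam, exclude_duplicates=False).total() == 2

    def test_coverage_mode_counts_every_aligned_base(self, tmp_path):
        bam = tmp_path / "cov.bam"
        self._write_bam(bam, [("f", 0, 100, 50, False, 0)])
        t = track_from_alignments(bam, mode="coverage")
        assert list(t.counts("chrI", "+", 100, 151)) == [0] + [1] * 50 + [0]

    def test_unindexed_bam_rejected(self, tmp_path):
        bam = tmp_path / "noidx.bam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrI", "LN": 1000}]}
        with pysam.AlignmentFile(bam, "wb", header=header):
            pass
        with pytest.raises(ValueError, match="index"):
            track_from_alignments(bam)


class TestWindows:
    def test_zero_track_any_window(self):
        g = make_gene()
        assert window_count(SignalTrack("s"), g, -500, -51) == 0

    def test_uniform_track_window_arithmetic(self):
        """450-position window over a 2 reads/nt track sums to 900."""
        g = make_gene(polya=2000)
        t = SignalTrack("u")
        t.set_interval("chrI", "+", 1, 2600, 2)
        assert window_count(t, g, -500, -51) == 900
        assert window_count(t, g, 51, 500) == 900

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_sparse_window_matches_brute_force(self, rng, strand):
        g = make_gene(strand=strand, polya=2000)
        for _ in range(10):
            t = random_sparse_track(rng, strand=strand)
            assert window_count(t, g, 51, 500) == brute_force_window_count(t, g, 51, 500)
            assert window_count(t, g, -500, -51) == brute_force_window_count(t, g, -500, -51)

    def test_additive_over_disjoint_windows(self, rng):
        g = make_gene(polya=2000)
        t = random_sparse_track(rng)
        for a, b, c in [(-500, -300, -51), (51, 200, 500), (-100, 0, 100)]:
            assert (window_count(t, g, a, b) + window_count(t, g, b + 1, c)
                    == window_count(t, g, a, c))

    def test_strand_mirror_preserves_window_counts(self, rng):
        """Reflecting a + strand signal about the poly(A) site onto the -
        strand leaves every strand-aware window count unchanged."""
        plus_gene = make_gene("p", strand="+", polya=3000)
        minus_gene = make_gene("m", strand="-", polya=3000)
        t_plus = SignalTrack("a")
        t_minus = SignalTrack("b")
        offsets = rng.integers(-800, 800, size=100)
        counts = rng.integers(1, 6, size=100)
        for off, c in zip(offsets, counts):
            t_plus.add("chrI", "+", 3000 + int(off), int(c))
            t_minus.add("chrI", "-", 3000 - int(off), int(c))
        for win in [(-500, -51), (51, 500), (-200, 200)]:
            assert (window_count(t_plus, plus_gene, *win)
                    == window_count(t_minus, minus_gene, *win))

    def test_window_truncated_at_chromosome_start(self):
        g = make_gene("edge", strand="-", polya=100, body=1500)
        t = SignalTrack("s")
        t.set_interval("chrI", "-", 1, 99, 1)  # downstream of a - gene at 100
        # offsets +1..+500 map to genomic 99..-400; only 99..1 exist
        assert window_count(t, g, 1, 500) == 99

    def test_cds_mean_density(self, rng):
        g = make_gene(polya=2000, body=1000)
        t = SignalTrack("s")
        t.set_interval("chrI", "+", g.cds_start, g.cds_end, 1)
        assert cds_mean_density(t, g) == 1.0
        assert cds_mean_density(SignalTrack("z"), g) == 0.0
        sparse = random_sparse_track(rng)
        expected = sum(
            int(sparse.counts("chrI", "+", p, p)[0])
            for p in range(g.cds_start, g.cds_end + 1)
        ) / g.cds_length
        assert cds_mean_density(sparse, g) == expected


class TestSampleSheet:
    def test_duplicate_strain_replicate_rejected(self):
        import pandas as pd
        df = pd.DataFrame({
            "sample_id": ["a", "b"], "strain": ["WT", "WT"], "replicate": [1, 1],
            "plus_file": ["a_p", "b_p"], "minus_file": ["a_m", "b_m"],
        })
        with pytest.raises(ValueError, match="duplicate"):
            SampleSheet(df)
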