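import numpy as np
import pytest

from promdir.coverage import (
    CoverageError,
    StrandedCoverage,
    count_anchored_intervals,
    count_promoter_windows,
    count_window,
    fragments_to_end_coverage,
    read_bedgraph,
    read_bedgraph_pair,
    write_bedgraph,
)

from .conftest import brute_force_end_tally, make_gene, random_fragments


class TestEndCoverage:
    def test_plus_fragment_three_prime_end_is_rightmost_base(self):
        cov = fragments_to_end_coverage(
            [("chrI", 100, 150, "+")], {"chrI": 1000},
            library_strandness="forward")
        assert cov.vector("chrI", "+")[149] == 1
        assert cov.total_signal() == 1

    def test_minus_fragment_three_prime_end_is_leftmost_base(self):
        cov = fragments_to_end_coverage(
            [("chrI", 100, 150, "-")], {"chrI": 1000},
            library_strandness="forward")
        assert cov.vector("chrI", "-")[100] == 1

    def test_reverse_strandness_flips_transcript_strand(self):
        cov = fragments_to_end_coverage(
            [("chrI", 100, 150, "+")], {"chrI": 1000},
            library_strandness="reverse")
        # read on +, reverse library: transcript strand is -, 3' end leftmost
        assert cov.vector("chrI", "-")[100] == 1
        assert cov.vector("chrI", "+").sum() == 0

    def test_five_prime_convention(self):
        cov = fragments_to_end_coverage(
            [("chrI", 100, 150, "+"), ("chrI", 200, 260, "-")],
            {"chrI": 1000}, end_convention="5prime",
            library_strandness="forward")
        assert cov.vector("chrI", "+")[100] == 1
        assert cov.vector("chrI", "-")[259] == 1

    @pytest.mark.parametrize("strandness", ["forward", "reverse"])
    @pytest.mark.parametrize("end_convention", ["3prime", "5prime"])
    def test_matches_brute_force_tally(self, rng, small_chrom_sizes,
                                       end_convention, strandness):
        frags = random_fragments(rng, small_chrom_sizes, n=1000)
        cov = fragments_to_end_coverage(
            frags, small_chrom_sizes, end_convention=end_convention,
            library_strandness=strandness)
        oracle = brute_force_end_tally(
            frags, small_chrom_sizes, end_convention, strandness)
        for chrom in small_chrom_sizes:
            for strand in "+-":
                np.testing.assert_array_equal(
                    cov.vector(chrom, strand), oracle[chrom][strand])
        assert cov.total_signal() == len(frags)

    def test_out_of_bounds_fragment_names_record(self):
        with pytest.raises(CoverageError, match="9999"):
            fragments_to_end_coverage(
                [("chrI", 9999, 10050, "+")], {"chrI": 10_000})


class TestBedgraphRoundTrip:
    def test_run_length_encoding(self, tmp_path):
        cov = StrandedCoverage.zeros({"chr1": 5})
        cov.data["chr1"]["+"][:] = [0, 0, 3, 3, 0]
        path = tmp_path / "t.bedGraph"
        write_bedgraph(cov, "+", path)
        assert path.read_text() == "chr1\t2\t4\t3\n"

    def test_empty_vector_writes_empty_file(self, tmp_path):
        cov = StrandedCoverage.zeros({"chr1": 100})
        path = tmp_path / "z.bedGraph"
        write_bedgraph(cov, "+", path)
        assert path.read_text() == ""

    def test_round_trip_identity_on_random_vectors(self, tmp_path, rng):
        sizes = {"chrI": 400, "chrII": 150}
        for trial in range(20):
            cov = StrandedCoverage.zeros(sizes)
            for chrom, n in sizes.items():
                vec = rng.poisson(0.5, n).astype(float)
                vec[rng.random(n) < 0.5] = 0  # plenty of zero runs
                cov.data[chrom]["+"][:] = vec
            path = tmp_path / f"rt{trial}.bedGraph"
            write_bedgraph(cov, "+", path)
            back = read_bedgraph(path, sizes, "+")
            for chrom in sizes:
                np.testing.assert_array_equal(
                    back.vector(chrom, "+"), cov.vector(chrom, "+"))

    def test_overlapping_intervals_rejected(self, tmp_path):
        path = tmp_path / "bad.bedGraph"
        path.write_text("chrI\t0\t10\t1\nchrI\t5\t15\t2\n")
        with pytest.raises(CoverageError, match="overlap"):
            read_bedgraph(path, {"chrI": 100}, "+")

    def test_unknown_chromosome_rejected(self, tmp_path):
        path = tmp_path / "bad.bedGraph"
        path.write_text("chrX\t0\t10\t1\n")
        with pytest.raises(CoverageError, match="chrX"):
            read_bedgraph(path, {"chrI": 100}, "+")


class TestCountWindow:
    def test_unit_inside_window_counts_once(self, empty_coverage):
        empty_coverage.data["chrI"]["+"][100] = 1
        assert count_window(empty_coverage, "chrI", "+", 50, 550) == 1

    def test_opposite_strand_not_counted(self, empty_coverage):
        empty_coverage.data["chrI"]["+"][100] = 1
        assert count_window(empty_coverage, "chrI", "-", 50, 550) == 0

    def test_matches_naive_sum(self, rng, small_chrom_sizes):
        cov = StrandedCoverage.zeros(small_chrom_sizes)
        vec = rng.poisson(1.0, small_chrom_sizes["chrI"]).astype(float)
        cov.data["chrI"]["+"][:] = vec
        for _ in range(50):
            a = int(rng.integers(0, 9000))
            b = a + int(rng.integers(1, 1000))
            assert count_window(cov, "chrI", "+", a, b) == sum(vec[a:b])

    def test_window_outside_chromosome_raises(self, empty_coverage):
        with pytest.raises(CoverageError):
            count_window(empty_coverage, "chrI", "+", 9990, 10_010)


class TestPromoterWindows:
    def test_plus_gene_window_arithmetic(self, empty_coverage, plus_gene):
        empty_coverage.data["chrI"]["+"][1250] = 1   # sense [1000,1500)
        empty_coverage.data["chrI"]["-"][800] = 1    # antisense [500,1000)
        (wc,) = count_promoter_windows([plus_gene], empty_coverage)
        assert (wc.sense_count, wc.antisense_count) == (1, 1)
        assert not wc.clipped

    def test_minus_gene_mirror_gives_identical_counts(self, small_chrom_sizes):
        # mirror of the plus case around the chromosome midpoint
        cov = StrandedCoverage.zeros(small_chrom_sizes)
        span = small_chrom_sizes["chrI"]
        g = make_gene("gm", start=span - 2000, end=span - 1000, strand="-")
        assert g.tss == span - 1001
        cov.data["chrI"]["-"][span - 1 - 1250] = 1
        cov.data["chrI"]["+"][span - 1 - 800] = 1
        (wc,) = count_promoter_windows([g], cov)
        assert (wc.sense_count, wc.antisense_count) == (1, 1)

    def test_zero_coverage_gives_zero_counts(self, empty_coverage, plus_gene):
        (wc,) = count_promoter_windows([plus_gene], empty_coverage)
        assert (wc.sense_count, wc.antisense_count) == (0, 0)

    def test_strand_mirror_invariance_on_random_coverage(self, rng):
        sizes = {"chrI": 4000}
        cov = StrandedCoverage.zeros(sizes)
        for s in "+-":
            cov.data["chrI"][s][:] = rng.poisson(0.3, 4000)
        gplus = make_gene("gp", start=1500, end=2500, strand="+")
        mirror = StrandedCoverage.zeros(sizes)
        mirror.data["chrI"]["+"][:] = cov.data["chrI"]["-"][::-1]
        mirror.data["chrI"]["-"][:] = cov.data["chrI"]["+"][::-1]
        gminus = make_gene("gm", start=4000 - 2500, end=4000 - 1500,
                           strand="-")
        (a,) = count_promoter_windows([gplus], cov)
        (b,) = count_promoter_windows([gminus], mirror)
        assert (a.sense_count, a.antisense_count) == \
            (b.sense_count, b.antisense_count)

    def test_window_clipped_at_chromosome_edge_is_flagged(self):
        sizes = {"chrI": 2000}
        cov = StrandedCoverage.zeros(sizes)
        cov.data["chrI"]["-"][100] = 1
        g = make_gene("edge", start=300, end=1200, strand="+")
        (wc,) = count_promoter_windows([g], cov)  # antisense window clipped
        assert wc.clipped and wc.antisense_count == 1

    def test_conservation_bound(self, rng, small_chrom_sizes):
        frags = random_fragments(rng, small_chrom_sizes, n=500)
        cov = fragments_to_end_coverage(frags, small_chrom_sizes,
                                        library_strandness="forward")
        genes = [make_gene(f"g{i}", start=s, end=s + 800)
                 for i, s in enumerate(range(600, 8000, 1400))]
        wcs = count_promoter_windows(genes, cov)
        total = sum(w.sense_count + w.antisense_count for w in wcs)
        assert total <= cov.total_signal()


class TestAnchoredIntervals:
    def test_two_rows_per_anchor(self, empty_coverage):
        anchors = [("chrI", 500 + 50 * i) for i in range(141)]
        rows = count_anchored_intervals(anchors, empty_coverage, flank=100)
        assert len(rows) == 282

    def test_single_anchor_counts(self, empty_coverage):
        empty_coverage.data["chrI"]["+"][450] = 1
        rows = count_anchored_intervals([("chrI", 500)], empty_coverage,
                                        flank=100)
        by_strand = {r["count_strand"]: r["count"] for r in rows}
        assert by_strand == {"+": 1, "-": 0}

    def test_flank_larger_than_chromosome_raises(self, empty_coverage):
        with pytest.raises(CoverageError):
            count_anchored_intervals([("chrI", 500)], empty_coverage,
                                     flank=20_000)


def test_bedgraph_pair_round_trip_through_files(tmp_path, rng,
                                                small_chrom_sizes):
    frags = random_fragments(rng, small_chrom_sizes, n=800)
    cov = fragments_to_end_coverage(frags, small_chrom_sizes,
                                    library_strandness="forward")
    plus, minus = tmp_path / "p.bedGraph", tmp_path / "m.bedGraph"
    write_bedgraph(cov, "+", plus)
    write_bedgraph(cov, "-", minus)
    back = read_bedgraph_pair(plus, minus, small_chrom_sizes)
    for chrom in small_chrom_sizes:
        for strand in "+-":
            np.testing.assert_array_equal(back.vector(chrom, strand),
                                          cov.vector(chrom, strand))
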