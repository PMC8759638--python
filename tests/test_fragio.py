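"""Fragment I/O, size partitioning, downsampling and coverage binning."""

import numpy as np
import pytest

from minidomain import (
    AnalysisConfig,
    Fragment,
    GenomeTable,
    coverage,
    downsample,
    partition_by_size,
    write_bedgraph,
)
from minidomain.fragio import (
    FragmentParseError,
    nucleosomal_only,
    read_bedgraph,
    read_fragments,
    read_genome_table,
    write_fragments,
)


def frag(start, end, chrom="chr2L"):
    return Fragment(chrom, start, end)


class TestReadFragments:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_fragments(p, "BED") == []

    def test_bed_line_maps_directly(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chr2L\t100\t180\n")
        (f,) = read_fragments(p, "BED")
        assert (f.chrom, f.start, f.end, f.length) == ("chr2L", 100, 180, 80)

    def test_bedpe_collapses_to_outermost_coordinates(self, tmp_path):
        # hand parse: mate 1 spans 100-150, mate 2 spans 160-180, so the
        # sequenced fragment spans min(starts)=100 to max(ends)=180
        p = tmp_path / "pair.bedpe"
        p.write_text("chr2L\t100\t150\tchr2L\t160\t180\n")
        (f,) = read_fragments(p, "BEDPE")
        assert (f.start, f.end) == (100, 180)

    def test_sam_lite_uses_template_length(self, tmp_path):
        p = tmp_path / "frags.sam"
        p.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr2L\tLN:100000\n"
            "r1\t99\tchr2L\t101\t60\t50M\t=\t131\t80\t*\t*\n"
            "r1\t147\tchr2L\t131\t60\t50M\t=\t101\t-80\t*\t*\n"
        )
        (f,) = read_fragments(p, "SAM-lite")
        assert (f.chrom, f.start, f.end) == ("chr2L", 100, 180)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr2L\t100\t180\nchr2L\toops\t200\n")
        with pytest.raises(FragmentParseError, match="2"):
            read_fragments(p, "BED")

    def test_unknown_chromosome_named_in_error(self, tmp_path, small_genome):
        p = tmp_path / "bad.bed"
        p.write_text("chrUnknown\t0\t50\n")
        with pytest.raises(FragmentParseError, match="chrUnknown"):
            read_fragments(p, "BED", genome=small_genome)

    def test_order_preserved_and_roundtrip(self, tmp_path):
        frags = [frag(500, 600), frag(0, 80), frag(100, 250)]
        p = tmp_path / "rt.bed"
        write_fragments(frags, p)
        assert read_fragments(p, "BED") == frags

    def test_genome_table_roundtrip(self, tmp_path):
        p = tmp_path / "chrom.sizes"
        p.write_text("chr2L\t100000\nchrX\t50000\n")
        gt = read_genome_table(p)
        assert gt["chrX"] == 50_000 and list(gt) == ["chr2L", "chrX"]


class TestPartitionBySize:
    def test_strictly_shorter_than_threshold(self):
        frags = [frag(0, 80), frag(0, 119), frag(0, 120), frag(0, 150)]
        short, allf = partition_by_size(frags, 120)
        assert [f.length for f in short] == [80, 119]
        assert allf == frags  # the all-fragments view keeps short ones

    def test_empty_input(self):
        assert partition_by_size([], 120) == ([], [])

    def test_no_short_fragments(self):
        frags = [frag(0, 150), frag(0, 200)]
        short, allf = partition_by_size(frags, 120)
        assert short == [] and allf == frags

    def test_short_is_subset_and_counts_add_up(self):
        rng = np.random.default_rng(7)
        frags = [frag(0, int(l)) for l in rng.integers(40, 260, size=300)]
        short, allf = partition_by_size(frags, 120)
        long = nucleosomal_only(frags, 120)
        assert len(short) + len(long) == len(allf)
        assert all(f in allf for f in short)


class TestDownsample:
    def test_full_target_returns_same_set(self):
        frags = [frag(i * 10, i * 10 + 80) for i in range(5)]
        out = downsample({"a": frags}, target=5, seed=1)
        assert out["a"] == frags

    def test_min_target_equalizes_sizes(self):
        sets = {
            "a": [frag(i, i + 80) for i in range(1000)],
            "b": [frag(i, i + 80) for i in range(600)],
        }
        out = downsample(sets, target="min", seed=3)
        assert len(out["a"]) == len(out["b"]) == 600

    def test_deterministic_under_fixed_seed(self):
        frags = [frag(i, i + 80) for i in range(1000)]
        out1 = downsample({"a": frags}, target=100, seed=42)
        out2 = downsample({"a": frags}, target=100, seed=42)
        assert out1 == out2

    def test_output_is_subset_preserving_order(self):
        frags = [frag(i, i + 80) for i in range(200)]
        (sub,) = downsample({"a": frags}, target=50, seed=5).values()
        positions = [frags.index(f) for f in sub]
        assert positions == sorted(positions) and len(set(positions)) == 50

    def test_target_exceeding_size_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            downsample({"a": [frag(0, 80)]}, target=2, seed=0)


class TestCoverage:
    def test_uniform_fragment_fills_bins(self, small_genome):
        track = coverage([frag(0, 50)], small_genome, bin_size=25)
        assert track.values["chr2L"][0] == 1.0 and track.values["chr2L"][1] == 1.0

    def test_partial_bin_overlap(self, small_genome):
        # fragment covers 10 of the first 25 bases: 10/25 = 0.4
        track = coverage([frag(10, 20)], small_genome, bin_size=25)
        assert track.values["chr2L"][0] == pytest.approx(0.4)
        assert track.values["chr2L"][1] == 0.0

    def test_linearity_in_duplicate_fragments(self, small_genome):
        one = coverage([frag(100, 260)], small_genome, 25)
        two = coverage([frag(100, 260)] * 2, small_genome, 25)
        np.testing.assert_array_equal(
            two.values["chr2L"], 2 * one.values["chr2L"]
        )

    def test_base_conservation_exact(self, small_genome):
        rng = np.random.default_rng(11)
        frags = [
            frag(int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, 99_000, size=500), rng.integers(50, 250, size=500)
            )
        ]
        track = coverage(frags, small_genome, 25)
        total_bases = sum(f.length for f in frags)
        assert track.values["chr2L"].sum() * 25 == pytest.approx(total_bases)

    def test_fragment_beyond_chromosome_end_errors(self):
        genome = GenomeTable({"chr2L": 100})
        with pytest.raises(ValueError, match="beyond"):
            coverage([frag(50, 150)], genome, 25)

    def test_per_million_normalization(self, small_genome):
        frags = [frag(0, 100)] * 4
        raw = coverage(frags, small_genome, 25)
        norm = coverage(frags, small_genome, 25, norm="per-million-fragments")
        assert norm.norm_factor == pytest.approx(1e6 / 4)
        np.testing.assert_allclose(
            norm.values["chr2L"], raw.values["chr2L"] * 1e6 / 4
        )


class TestBedgraph:
    def test_zero_track_writes_no_data(self, tmp_path, small_genome):
        track = coverage([], small_genome, 25)
        p = tmp_path / "zero.bedgraph"
        write_bedgraph(track, p)
        assert p.read_text() == ""

    def test_equal_runs_merge(self, tmp_path):
        genome = GenomeTable({"chr2L": 75})
        track = coverage([frag(0, 50)], genome, 25)
        p = tmp_path / "run.bedgraph"
        write_bedgraph(track, p)
        assert p.read_text() == "chr2L\t0\t50\t1\n"

    def test_roundtrip_reproduces_bin_values(self, tmp_path, small_genome):
        rng = np.random.default_rng(2)
        frags = [
            frag(int(s), int(s) + 160)
            for s in rng.integers(0, 99_000, size=200)
        ]
        track = coverage(frags, small_genome, 25)
        p = tmp_path / "rt.bedgraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p, small_genome, 25)
        np.testing.assert_allclose(back.values["chr2L"], track.values["chr2L"])


class TestAnalysisConfig:
    @pytest.mark.parametrize("field", ["short_threshold_bp", "all_bin_bp",
                                       "domain_min_bp"])
    def test_nonpositive_size_rejected_naming_field(self, field):
        with pytest.raises(ValueError, match=field):
            AnalysisConfig(**{field: 0})

    def test_pvalue_bounds(self):
        with pytest.raises(ValueError, match="peak_pvalue"):
            AnalysisConfig(peak_pvalue=1.5)
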