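"""Interval model, annotation input, read extension, coverage, counting, RPKM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scc2xpress.genomic_core import (
    AlignedRead,
    AnnotationParseError,
    GenomicInterval,
    coverage_from_reads,
    count_reads_per_feature,
    extend_read,
    load_annotation,
    read_chrom_sizes,
    reads_from_bed,
    rpkm,
    rpm_normalize,
    write_reads_bed,
)

from conftest import make_read


class TestIntervalModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 5)

    def test_blocks_must_nest_and_sort(self):
        iv = GenomicInterval("chr1", 0, 100, "+")
        with pytest.raises(ValueError):
            AlignedRead(iv, blocks=(GenomicInterval("chr1", 50, 120, "+"),))
        with pytest.raises(ValueError):
            AlignedRead(
                iv,
                blocks=(
                    GenomicInterval("chr1", 40, 80, "+"),
                    GenomicInterval("chr1", 0, 30, "+"),
                ),
            )

    def test_split_read_flag(self):
        read = make_read("chr1", 0, 100, blocks=[(0, 30), (70, 100)])
        assert read.is_split
        assert read.aligned_length == 60
        assert not make_read("chr1", 0, 36).is_split


class TestLoadAnnotation:
    def test_bed_coordinates_are_native(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tgeneA\t0\t+\n")
        tx = load_annotation(bed)["geneA"]
        assert (tx.span.start, tx.span.end, tx.strand) == (100, 200, "+")
        assert tx.tss == 100

    def test_gff_one_based_converted(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t101\t200\t.\t-\t.\tID=txB\n"
            "chr1\tsrc\texon\t101\t200\t.\t-\t.\tID=txB.e1;Parent=txB\n"
        )
        tx = load_annotation(gff)["txB"]
        assert (tx.span.start, tx.span.end) == (100, 200)
        # minus-strand TSS is the 3'-most genomic coordinate, index end-1
        assert tx.tss == 199

    def test_gtf_dialect(self, tmp_path):
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t11\t40\t.\t+\t.\tgene_id "g"; transcript_id "txC";\n'
            'chr1\tsrc\texon\t61\t90\t.\t+\t.\tgene_id "g"; transcript_id "txC";\n'
        )
        tx = load_annotation(gtf)["txC"]
        assert [(e.start, e.end) for e in tx.exons] == [(10, 40), (60, 90)]

    def test_empty_file_warns(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        with pytest.warns(UserWarning):
            assert load_annotation(bed) == {}

    def test_malformed_line_names_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t100\t200\tok\t0\t+\nchr1\tnot_an_int\t300\n")
        with pytest.raises(AnnotationParseError, match="line 2"):
            load_annotation(bed)

    def test_exon_outside_parent_span_rejected(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=tx\n"
            "chr1\tsrc\texon\t101\t250\t.\t+\t.\tParent=tx\n"
        )
        with pytest.raises(AnnotationParseError, match="outside"):
            load_annotation(gff)

    def test_bed12_blocks_roundtrip(self, tmp_path):
        reads = [make_read("chr1", 10, 100, blocks=[(10, 40), (80, 100)], sample="s")]
        path = tmp_path / "reads.bed"
        write_reads_bed(reads, path)
        back = reads_from_bed(path, sample_id="s")
        assert back[0].blocks == reads[0].blocks

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("chr1\t230218\nchr2\t813184\n")
        assert read_chrom_sizes(p) == {"chr1": 230218, "chr2": 813184}


class TestExtendRead:
    @pytest.mark.parametrize(
        "start,end,strand,want",
        [
            (100, 136, "+", (100, 250)),  # 5'-anchored, grows 3'
            (500, 536, "-", (386, 536)),  # minus strand grows leftward
            (100, 250, "+", (100, 250)),  # already at target: unchanged
            (100, 300, "+", (100, 300)),  # longer than target: never trimmed
        ],
    )
    def test_extension_geometry(self, start, end, strand, want):
        out = extend_read(make_read("chr1", start, end, strand), 150)
        assert (out.interval.start, out.interval.end) == want
        assert out.interval.strand == strand

    def test_clipped_at_chromosome_end(self):
        out = extend_read(make_read("chr1", 980, 1000, "+"), 150, {"chr1": 1000})
        assert (out.interval.start, out.interval.end) == (980, 1000)

    def test_multiblock_rejected(self):
        read = make_read("chr1", 0, 100, blocks=[(0, 30), (70, 100)])
        with pytest.raises(ValueError):
            extend_read(read, 150)

    @given(
        start=st.integers(0, 500),
        length=st.integers(1, 149),
        strand=st.sampled_from(["+", "-"]),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_five_prime_coordinate_preserved(self, start, length, strand):
        read = make_read("chr1", start, start + length, strand)
        out = extend_read(read, 150)
        if strand == "+":
            assert out.interval.start == start
        else:
            assert out.interval.end == start + length
        assert len(out.interval) <= 150


class TestCoverage:
    def test_additivity_at_shared_base(self, toy_sizes):
        sizes = {"chr1": 2000}
        reads = [make_read("chr1", 900, 1050), make_read("chr1", 1000, 1150)]
        track = coverage_from_reads(reads, sizes)
        assert track["chr1"][1000] == 2
        assert track["chr1"][899] == 0

    def test_no_reads_all_zero(self, toy_sizes):
        track = coverage_from_reads([], toy_sizes)
        assert track.total() == 0

    def test_matches_per_base_brute_force(self, toy_sizes, rng):
        reads = []
        for _ in range(30):
            s = int(rng.integers(0, 15))
            e = int(rng.integers(s + 1, 21))
            reads.append(make_read("chr1", s, min(e, 20)))
        track = coverage_from_reads(reads, {"chr1": 20})
        brute = [
            sum(1 for r in reads for b in r.blocks if b.start <= pos < b.end)
            for pos in range(20)
        ]
        assert track["chr1"].tolist() == brute

    def test_out_of_bounds_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            track = coverage_from_reads([make_read("chr1", 15, 25)], {"chr1": 20})
        assert track.total() == 5

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(1, 10)), min_size=0, max_size=25))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_coverage_conservation(self, spans):
        reads = [make_read("chr2", s, s + ln) for s, ln in spans]
        track = coverage_from_reads(reads, {"chr2": 50})
        assert track.total() == sum(ln for _, ln in spans)


class TestRpm:
    def test_scaling(self):
        track = coverage_from_reads([make_read("chr1", 0, 4)] * 4, {"chr1": 10})
        out = rpm_normalize(track, 2_000_000)
        assert out["chr1"][0] == pytest.approx(2.0)
        assert out.units == "rpm"

    def test_library_of_one_million_is_identity(self):
        track = coverage_from_reads([make_read("chr1", 0, 5)], {"chr1": 10})
        out = rpm_normalize(track, 1_000_000)
        assert np.array_equal(out["chr1"], track["chr1"])

    def test_zero_library_rejected(self):
        track = coverage_from_reads([], {"chr1": 10})
        with pytest.raises(ValueError):
            rpm_normalize(track, 0)

    def test_invariant_under_read_duplication(self, rng):
        reads = [make_read("chr1", int(s), int(s) + 5) for s in rng.integers(0, 95, 40)]
        a = rpm_normalize(coverage_from_reads(reads, {"chr1": 100}), len(reads))
        b = rpm_normalize(coverage_from_reads(reads * 2, {"chr1": 100}), 2 * len(reads))
        assert np.allclose(a["chr1"], b["chr1"])


class TestFeatureCounting:
    FEATS = {
        "geneA": GenomicInterval("chr1", 10, 30, "+"),
        "geneB": GenomicInterval("chr1", 30, 60, "+"),
        "geneC": GenomicInterval("chr1", 80, 90, "-"),
    }

    def test_single_containment(self):
        table = count_reads_per_feature([make_read("chr1", 12, 20)], self.FEATS)
        assert table.counts.loc["geneA", "s1"] == 1
        assert table.counts.loc["geneB", "s1"] == 0

    def test_boundary_straddler_increments_both(self):
        table = count_reads_per_feature([make_read("chr1", 25, 35)], self.FEATS)
        assert table.counts.loc["geneA", "s1"] == 1
        assert table.counts.loc["geneB", "s1"] == 1

    def test_duplicate_feature_ids_rejected(self):
        feats = [("geneA", self.FEATS["geneA"]), ("geneA", self.FEATS["geneB"])]
        with pytest.raises(ValueError, match="duplicate"):
            count_reads_per_feature([], feats)

    def test_matches_brute_force_enumeration(self, rng):
        reads = []
        for _ in range(60):
            s = int(rng.integers(0, 95))
            reads.append(make_read("chr1", s, s + int(rng.integers(1, 12))))
        table = count_reads_per_feature(reads, self.FEATS)
        for fid, iv in self.FEATS.items():
            brute = sum(
                1
                for r in reads
                if any(b.start < iv.end and iv.start < b.end for b in r.blocks)
            )
            assert table.counts.loc[fid, "s1"] == brute

    def test_rpkm_table(self):
        reads = [make_read("chr1", 12, 20) for _ in range(10)]
        table = count_reads_per_feature(reads, {"geneA": GenomicInterval("chr1", 10, 30)})
        # 10 reads over a 20 bp feature in a 10-read library
        assert table.rpkm().loc["geneA", "s1"] == pytest.approx(10 * 1e9 / (20 * 10))


class TestRpkmScalar:
    def test_arithmetic(self):
        assert rpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert rpkm(0, 1000, 10**6) == 0.0

    def test_doubling_library_halves_rpkm(self):
        assert rpkm(7, 500, 2 * 10**6) == pytest.approx(rpkm(7, 500, 10**6) / 2)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            rpkm(-1, 1000, 10**6)
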