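"""I/O boundary: coordinate conversion, normalization, round-trips."""

from __future__ import annotations

import random

import pytest

from radsig import catalogue_io as cio
from radsig.genome import InMemoryGenome
from radsig.records import (
    CallableRegions,
    IndelRecord,
    ParseError,
    RearrangementCall,
    ValidationError,
)

VCF_HEADER = "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=200>\n" \
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


@pytest.fixture
def vcf_reference() -> InMemoryGenome:
    # anchors laid out so no indel below is left-shiftable
    seq = list("G" * 200)
    seq[99] = "A"           # pos 100
    seq[100:103] = "TTT"    # pos 101-103
    seq[103] = "C"          # pos 104
    seq[109] = "A"          # pos 110
    seq[110] = "T"          # pos 111
    return InMemoryGenome({"chr1": "".join(seq)})


def _write(tmp_path, body: str):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestIndelVcf:
    def test_deletion_semantics(self, tmp_path, vcf_reference):
        path = _write(tmp_path, "chr1\t100\t.\tATTT\tA\t.\tPASS\t.\n")
        (rec,) = cio.read_indel_vcf(path, vcf_reference)
        assert rec.indel_class == "deletion"
        assert rec.length == 3
        assert rec.deleted_seq == "TTT"
        assert (rec.del_start, rec.del_end) == (101, 103)

    def test_insertion_semantics(self, tmp_path, vcf_reference):
        path = _write(tmp_path, "chr1\t100\t.\tA\tATT\t.\tPASS\t.\n")
        (rec,) = cio.read_indel_vcf(path, vcf_reference)
        assert rec.indel_class == "insertion"
        assert rec.length == 2

    def test_complex_semantics(self, tmp_path, vcf_reference):
        path = _write(tmp_path, "chr1\t110\t.\tAT\tGC\t.\tPASS\t.\n")
        (rec,) = cio.read_indel_vcf(path, vcf_reference)
        assert rec.indel_class == "complex"
        assert rec.length == 2

    def test_ref_mismatch_names_site(self, tmp_path, vcf_reference):
        path = _write(tmp_path, "chr1\t100\t.\tCTTT\tC\t.\tPASS\t.\n")
        with pytest.raises(ValidationError, match="chr1:100"):
            cio.read_indel_vcf(path, vcf_reference)

    def test_deletions_left_aligned(self, tmp_path):
        # TATATA with one TA unit deleted: any anchor describes the same event
        ref = InMemoryGenome({"chr1": "GGTATATACC"})
        header = VCF_HEADER.replace("length=200", "length=10")
        a = tmp_path / "a.vcf"
        a.write_text(header + "chr1\t3\t.\tTAT\tT\t.\tPASS\t.\n")
        b = tmp_path / "b.vcf"
        b.write_text(header + "chr1\t5\t.\tTAT\tT\t.\tPASS\t.\n")
        (rec_a,) = cio.read_indel_vcf(str(a), ref)
        (rec_b,) = cio.read_indel_vcf(str(b), ref)
        assert rec_a.pos == rec_b.pos == 2
        assert rec_a.deleted_seq == rec_b.deleted_seq

    def test_write_read_round_trip(self, tmp_path, vcf_reference):
        records = [
            IndelRecord("chr1", 100, "ATTT", "A", "deletion", 3,
                        deleted_seq="TTT", vaf=0.31, mh_len=2, clonality="clonal",
                        sample_id="s1"),
            IndelRecord("chr1", 110, "A", "AGG", "insertion", 2, vaf=0.12,
                        sample_id="s1"),
        ]
        path = str(tmp_path / "rt.vcf")
        cio.write_indel_vcf(records, path, {"chr1": 200})
        back = cio.read_indel_vcf(path)
        assert [
            (r.chrom, r.pos, r.ref_allele, r.alt_allele, r.indel_class, r.length,
             r.vaf, r.mh_len, r.clonality, r.sample_id)
            for r in back
        ] == [
            (r.chrom, r.pos, r.ref_allele, r.alt_allele, r.indel_class, r.length,
             r.vaf, r.mh_len, r.clonality, r.sample_id)
            for r in records
        ]


class TestBedpe:
    def test_coordinate_conversion(self, tmp_path):
        path = tmp_path / "r.bedpe"
        path.write_text("chr1\t99\t110\tchr1\t4999\t5010\tJ1\t12\t+\t+\n")
        (call,) = cio.read_rearrangement_bedpe(str(path))
        assert call.low_ival == (100, 110)
        assert call.high_ival == (5000, 5010)
        assert call.orient == "head_head"
        assert call.read_support == 12

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bedpe"
        path.write_text("")
        assert cio.read_rearrangement_bedpe(str(path)) == []

    @pytest.mark.parametrize(
        "strands,orient",
        [(("+", "+"), "head_head"), (("-", "-"), "tail_tail"),
         (("+", "-"), "other"), (("-", "+"), "other")],
    )
    def test_strand_orientation_mapping(self, tmp_path, strands, orient):
        path = tmp_path / "r.bedpe"
        path.write_text(
            f"chr1\t99\t110\tchr1\t4999\t5010\tJ1\t12\t{strands[0]}\t{strands[1]}\n"
        )
        (call,) = cio.read_rearrangement_bedpe(str(path))
        assert call.orient == orient

    def test_too_few_columns(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t99\t110\tchr1\t4999\t5010\tJ1\t12\t+\n")
        with pytest.raises(ParseError, match="10 columns"):
            cio.read_rearrangement_bedpe(str(path))

    def test_negative_coordinate(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t-5\t110\tchr1\t4999\t5010\tJ1\t12\t+\t+\n")
        with pytest.raises(ValidationError, match="negative"):
            cio.read_rearrangement_bedpe(str(path))

    def test_round_trip_inverse(self, tmp_path):
        calls = [
            RearrangementCall("J1", "chr1", "chr1", (100, 110), (5000, 5010),
                              "head_head", 12, "s1"),
            RearrangementCall("J2", "chr2", "chr3", (7, 7), (900, 950),
                              "other", 3, "s1"),
        ]
        path = str(tmp_path / "rt.bedpe")
        cio.write_rearrangement_bedpe(calls, path)
        back = cio.read_rearrangement_bedpe(path)
        assert [
            (c.call_id, c.chrom_low, c.chrom_high, c.low_ival, c.high_ival,
             c.orient, c.read_support, c.sample_id)
            for c in back
        ] == [
            (c.call_id, c.chrom_low, c.chrom_high, c.low_ival, c.high_ival,
             c.orient, c.read_support, c.sample_id)
            for c in calls
        ]


class TestRegionsAndTracks:
    def test_bed_line_to_interval(self, tmp_path):
        path = tmp_path / "c.bed"
        path.write_text("chr1\t0\t100\n")
        regions = cio.read_callable_bed(str(path))
        assert regions.intervals("chr1") == [(1, 100)]
        assert regions.total_bases == 100

    def test_adjacent_intervals_merge(self):
        regions = CallableRegions({"chr1": [(1, 50), (51, 100)]})
        assert regions.intervals("chr1") == [(1, 100)]

    def test_total_bases_invariant_under_reordering(self):
        rng = random.Random(7)
        ivals = [(s, s + rng.randrange(1, 50)) for s in range(1, 5000, 100)]
        shuffled = ivals[:]
        rng.shuffle(shuffled)
        assert (
            CallableRegions({"chr1": ivals}).total_bases
            == CallableRegions({"chr1": shuffled}).total_bases
        )

    def test_bedgraph_query(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t10\t0.7\n")
        track = cio.read_bedgraph_track(str(path), "timing")
        assert track.value_at("chr1", 5) == pytest.approx(0.7)

    def test_conflicting_categorical_overlap(self):
        from radsig.records import FeatureTrack

        with pytest.raises(ValidationError, match="conflicting"):
            FeatureTrack(
                "chromatin", "categorical",
                {"chr1": [(1, 100, "A"), (50, 150, "B")]},
                "A", labels=("A", "B"),
            )

    def test_tracks_yaml_sidecar(self, tmp_path):
        (tmp_path / "callable.bed").write_text("chr1\t0\t1000\n")
        (tmp_path / "timing.bedgraph").write_text("chr1\t0\t1000\t0.5\n")
        (tmp_path / "chromatin.bed").write_text("chr1\t0\t1000\tA\n")
        (tmp_path / "tracks.yaml").write_text(
            "callable: callable.bed\n"
            "tracks:\n"
            "  - {name: timing, kind: quantitative, path: timing.bedgraph}\n"
            "  - {name: chromatin, kind: categorical, path: chromatin.bed,\n"
            "     labels: [A, B], default: A}\n"
        )
        regions, tracks = cio.read_tracks_and_regions(str(tmp_path / "tracks.yaml"))
        assert regions.total_bases == 1000
        assert {t.name: t.kind for t in tracks} == {
            "timing": "quantitative", "chromatin": "categorical"
        }


class TestManifest:
    def test_missing_file_names_sample(self, tmp_path):
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text(
            "sample_id\tgroup\tpurity\tindel_vcf\nPD001\tradiation\t0.7\tmissing.vcf\n"
        )
        df = cio.read_manifest(str(manifest))
        with pytest.raises(FileNotFoundError, match="PD001"):
            cio.load_catalogue(df.iloc[0], base_dir=str(tmp_path))

    def test_manifest_requires_group_column(self, tmp_path):
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text("sample_id\nPD001\n")
        with pytest.raises(ParseError, match="group"):
            cio.read_manifest(str(manifest))
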