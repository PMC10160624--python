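"""Domain types, query parsing, report round-trips, alignment I/O."""

import json

import pytest

from lrconfirm.core import (
    ConfirmationResult,
    GenomicInterval,
    Kind,
    Status,
    Thresholds,
    chrom_lengths,
    read_alignments,
    read_queries,
    read_report,
    write_alignments,
    write_report,
)
from lrconfirm.simulate import SimConfig, simulate_alignments, spike_variants
from lrconfirm.simulate import make_genome

from conftest import make_read

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">
##contig=<ID=chr3,length=200000000>
##contig=<ID=chrM,length=16569>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_coordinate_round_trip(self):
        # 1-based in -> 0-based half-open -> 1-based out is the identity
        for start_1, end_1 in [(1, 1), (8344, 8344), (100, 250)]:
            iv = GenomicInterval.from_1based("chrM", start_1, end_1)
            assert iv.to_1based() == f"chrM:{start_1}-{end_1}"


class TestAlignmentRecord:
    def test_cigar_sequence_consistency_enforced(self):
        rec = make_read("r", "chr1", 10, "ACGTACGT")
        assert len(rec.interval) == 8
        rec.sequence = "ACGT"
        with pytest.raises(ValueError):
            rec.validate()

    def test_clip_accessors(self):
        rec = make_read("r", "chr1", 10, "A" * 30,
                        cigar=[("S", 5), ("M", 20), ("S", 5)])
        assert rec.left_clip == 5 and rec.right_clip == 5


class TestThresholds:
    def test_defaults_match_protocol_floors(self):
        t = Thresholds()
        assert t.min_genomic_depth == 12
        assert t.min_mito_depth == 1000
        assert t.min_depth_for(Kind.MITO_SSC) == 1000
        assert t.min_depth_for(Kind.SSC) == 12

    def test_validation(self):
        with pytest.raises(ValueError):
            Thresholds(min_support_fraction=1.5)


class TestReadQueries:
    def test_vcf_and_sidecar_rows(self, tmp_path):
        vcf = tmp_path / "q.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chrM\t8344\tmt1\tA\tG\t.\t.\t.\n"
            + "chr3\t155116689\ts1\tCT\tC\t.\t.\t.\n"
            + "chr3\t1000\tsv1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=2000;SVLEN=-1000\n"
        )
        side = tmp_path / "q.tsv"
        side.write_text(
            "\t".join(["query_id", "kind", "chrom", "start_1based",
                       "end_1based", "motif", "pathogenic_threshold",
                       "expected_copy", "expected_length", "parental_vcf"])
            + "\nstr1\tSTR\tchr19\t45770205\t45770266\tCAG\t36\t\t\t\n"
        )
        parsed = read_queries(str(vcf), str(side))
        assert not parsed.rejected
        by_id = {q.query_id: q for q in parsed.queries}
        # 1-based VCF position 8344 becomes 0-based 8343
        assert by_id["mt1"].kind == Kind.MITO_SSC
        assert by_id["mt1"].locus.start == 8343
        assert by_id["s1"].kind == Kind.SSC
        assert by_id["sv1"].kind == Kind.SV_DEL
        assert by_id["sv1"].locus == GenomicInterval("chr3", 999, 2000)
        assert by_id["str1"].motif == "CAG"
        assert by_id["str1"].pathogenic_threshold == 36

    def test_parsing_is_total(self, tmp_path):
        side = tmp_path / "bad.tsv"
        side.write_text(
            "query_id\tkind\tchrom\tstart_1based\tend_1based\tmotif\t"
            "pathogenic_threshold\texpected_copy\texpected_length\tparental_vcf\n"
            "a\tSTR\tchr1\t100\t200\t\t\t\t\t\n"  # STR without motif
            "b\tBOGUS\tchr1\t100\t200\t\t\t\t\t\n"  # unknown kind
            "c\tCNV\tchr1\t100\t200000\t\t\t1\t\t\n"  # fine
        )
        parsed = read_queries(None, str(side))
        assert len(parsed.queries) == 1
        assert len(parsed.rejected) == 2
        assert all(r.reason for r in parsed.rejected)

    def test_empty_inputs(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(VCF_HEADER)
        parsed = read_queries(str(vcf))
        assert parsed.queries == [] and parsed.rejected == []


class TestReport:
    @pytest.fixture
    def batch(self):
        return [
            ConfirmationResult("q1", Status.CONFIRMED, 18,
                               {"alt_count": 7, "depth": 18}, ""),
            ConfirmationResult("q2", Status.INSUFFICIENT_COVERAGE, 11,
                               {}, "depth 11 below 12x floor"),
            ConfirmationResult("q3", Status.NOT_CONFIRMED, 30,
                               {"alt_count": 0}, ""),
        ]

    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_round_trip_preserves_every_field(self, tmp_path, batch, fmt):
        path = tmp_path / f"report.{fmt}"
        write_report(batch, str(path), fmt)
        back = read_report(str(path), fmt)
        assert back == batch
        # the insufficient row keeps its depth and empty evidence
        assert back[1].depth == 11 and back[1].evidence == {}

    def test_schema_version_stamped(self, tmp_path, batch):
        path = tmp_path / "report.json"
        write_report(batch, str(path), "json")
        assert json.loads(path.read_text())["schema_version"] == "1"

    def test_cardinality(self, tmp_path, batch):
        path = tmp_path / "r.tsv"
        write_report(batch, str(path), "tsv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + len(batch)


class TestAlignmentIO:
    def test_bam_round_trip_and_region_query(self, tmp_path):
        genome, _ = make_genome(1, 100_000, seed=11, read_length_mean=5000)
        haps, manifest = spike_variants(genome, [])
        records = simulate_alignments(
            haps, SimConfig(seed=11, read_length_mean=5000,
                            read_length_sd=2000), manifest)
        path = str(tmp_path / "sim.bam")
        write_alignments(records, chrom_lengths(genome), path)
        whole = list(read_alignments(
            path, GenomicInterval("chr1", 0, 100_000)))
        # every simulated record overlaps the whole contig
        assert len(whole) == len(records)
        # count agrees with the truth manifest plus split segments
        assert len({r.read_id for r in whole}) == len(manifest.reads)
        outside = list(read_alignments(path))
        assert len(outside) == len(records)

    def test_region_outside_reads_is_empty(self, tmp_path):
        rec = make_read("r1", "chr1", 100, "ACGT" * 10)
        path = str(tmp_path / "one.bam")
        write_alignments([rec], {"chr1": 10_000}, path)
        assert list(read_alignments(
            path, GenomicInterval("chr1", 5_000, 6_000))) == []
        got = list(read_alignments(path, GenomicInterval("chr1", 90, 200)))
        assert [r.read_id for r in got] == ["r1"]
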