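"""Depth, pileup classification, clipped reads, insertion observations."""

import numpy as np
import pytest

from lrconfirm.core import GenomicInterval, Kind, Role, Thresholds, VariantQuery
from lrconfirm.evidence import (
    allele_pileup,
    aligned_slice,
    clipped_reads,
    local_depth,
    spanning_insertions,
)
from lrconfirm.scenarios import small_deletion
from lrconfirm.simulate import revcomp

from conftest import make_read, matched_reads


def _ssc_query(ref, chrom, pos, alt=None):
    base = ref[chrom][pos]
    alt = alt or {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
    return VariantQuery("q", Kind.MITO_SSC if chrom == "chrM" else Kind.SSC,
                        GenomicInterval(chrom, pos, pos + 1),
                        ref_allele=base, alt_allele=alt)


class TestLocalDepth:
    def test_no_reads_is_zero(self):
        assert local_depth([], GenomicInterval("chr1", 0, 100)) == 0

    def test_exact_on_constructed_reads(self, random_ref):
        reads = matched_reads(random_ref["chr1"], "chr1", 7, 100, 200)
        assert local_depth(reads, GenomicInterval("chr1", 150, 250)) == 7

    def test_mapq0_and_supplementary_excluded(self, random_ref):
        seq = random_ref["chr1"][100:300]
        reads = [
            make_read("a", "chr1", 100, seq),
            make_read("b", "chr1", 100, seq, mapq=0),
            make_read("c", "chr1", 100, seq, role=Role.SUPPLEMENTARY),
        ]
        assert local_depth(reads, GenomicInterval("chr1", 150, 250)) == 1

    def test_additive_over_disjoint_read_sets(self, random_ref):
        a = matched_reads(random_ref["chr1"], "chr1", 4, 100, 200, prefix="a")
        b = matched_reads(random_ref["chr1"], "chr1", 3, 100, 200, prefix="b")
        iv = GenomicInterval("chr1", 120, 280)
        assert local_depth(a + b, iv) == local_depth(a, iv) + local_depth(b, iv)

    def test_permutation_invariant(self, random_ref):
        reads = matched_reads(random_ref["chr1"], "chr1", 9, 50, 300)
        iv = GenomicInterval("chr1", 100, 200)
        assert local_depth(reads[::-1], iv) == local_depth(reads, iv)


class TestAllelePileup:
    def test_mito_fixture_counts_match_exactly(self, random_ref):
        """658 alt reads over 1699 total reproduce alt/X bookkeeping."""
        chrom, pos = "chrM", 300
        q = _ssc_query(random_ref, chrom, pos)
        ref_seq = random_ref[chrom]
        alt_read = (ref_seq[250:pos] + q.alt_allele + ref_seq[pos + 1:350])
        reads = matched_reads(ref_seq, chrom, 1041, 250, 100, prefix="ref")
        reads += [make_read(f"alt{i}", chrom, 250, alt_read)
                  for i in range(658)]
        counts = allele_pileup(reads, q, random_ref)
        assert counts.depth == 1699
        assert counts.alt_count == 658
        assert counts.ref_count == 1041
        assert counts.other_count == 0

    def test_all_reference_reads_give_zero_alt(self, random_ref):
        q = _ssc_query(random_ref, "chr1", 200)
        reads = matched_reads(random_ref["chr1"], "chr1", 20, 100, 300)
        counts = allele_pileup(reads, q, random_ref)
        assert counts.alt_count == 0 and counts.ref_count == 20

    def test_order_permutation_invariant(self, random_ref):
        q = _ssc_query(random_ref, "chr1", 200)
        reads = matched_reads(random_ref["chr1"], "chr1", 12, 100, 300)
        a = allele_pileup(reads, q, random_ref)
        b = allele_pileup(reads[::-1], q, random_ref)
        assert (a.depth, a.ref_count, a.alt_count) == (b.depth, b.ref_count, b.alt_count)

    def test_non_acgt_allele_rejected(self, random_ref):
        q = _ssc_query(random_ref, "chr1", 200)
        q.alt_allele = "N"
        with pytest.raises(ValueError):
            allele_pileup([], q, random_ref)

    def test_agrees_with_string_comparison_oracle_error_free(self):
        """On error-free simulated reads the pileup equals a brute-force
        oracle comparing each read's aligned slice to both alleles."""
        sc = small_deletion(5, err_sub=0.0, err_ins=0.0, err_del=0.0)
        q = sc["query"]
        wstart, wend = q.locus.start - 10, q.locus.end + 10
        ref = sc["reference"]["chr1"]
        ref_w = ref[wstart:wend]
        alt_w = ref[wstart:q.locus.start] + q.alt_allele + ref[q.locus.end:wend]
        oracle = {"ref": 0, "alt": 0}
        for rec in sc["records"]:
            obs = aligned_slice(rec, wstart, wend)
            if obs is None:
                continue
            if obs == ref_w:
                oracle["ref"] += 1
            elif obs == alt_w:
                oracle["alt"] += 1
        counts = allele_pileup(sc["records"], q, sc["reference"])
        assert counts.ref_count == oracle["ref"]
        assert counts.alt_count == oracle["alt"]
        assert counts.other_count == 0

    def test_het_deletion_fraction_near_half(self):
        sc = small_deletion(1)
        counts = allele_pileup(sc["records"], sc["query"], sc["reference"])
        frac = counts.alt_count / counts.depth
        assert 0.2 <= frac <= 0.8


class TestClippedReads:
    def test_fully_matched_reads_give_nothing(self, random_ref):
        reads = matched_reads(random_ref["chr1"], "chr1", 5, 100, 200)
        assert clipped_reads(reads, GenomicInterval("chr1", 0, 600), 50) == []

    def test_threshold_boundary(self, random_ref):
        seq = random_ref["chr1"][100:250]
        rec = make_read("r", "chr1", 100, "A" * 150 + seq,
                        cigar=[("S", 150), ("M", 150)])
        iv = GenomicInterval("chr1", 50, 150)
        assert clipped_reads([rec], iv, 200) == []
        got = clipped_reads([rec], iv, 150)
        assert len(got) == 1
        assert got[0].clip_side == "left" and got[0].clip_pos == 100

    def test_right_clip_position(self, random_ref):
        seq = random_ref["chr1"][100:250]
        rec = make_read("r", "chr1", 100, seq + "A" * 300,
                        cigar=[("M", 150), ("S", 300)])
        got = clipped_reads([rec], GenomicInterval("chr1", 240, 260), 200)
        assert len(got) == 1
        assert got[0].clip_side == "right" and got[0].clip_pos == 250


class TestSpanningInsertions:
    def test_no_insertion_ops(self, random_ref):
        reads = matched_reads(random_ref["chr1"], "chr1", 5, 100, 200)
        assert spanning_insertions(reads, GenomicInterval("chr1", 0, 600), 1) == []

    def test_two_reads_two_observations(self, random_ref):
        ref = random_ref["chr1"]
        ins = "TTTTTTTTTT"
        reads = [
            make_read(f"r{i}", "chr1", 100,
                      ref[100:200] + ins + ref[200:300],
                      cigar=[("M", 100), ("I", 10), ("M", 100)])
            for i in range(2)
        ]
        got = spanning_insertions(reads, GenomicInterval("chr1", 150, 250), 5)
        assert len(got) == 2
        assert {o.read_id for o in got} == {"r0", "r1"}
        assert all(o.position == 200 and o.length == 10 and
                   o.inserted_sequence == ins for o in got)

    def test_min_len_filters(self, random_ref):
        ref = random_ref["chr1"]
        rec = make_read("r", "chr1", 100, ref[100:200] + "TTT" + ref[200:300],
                        cigar=[("M", 100), ("I", 3), ("M", 100)])
        assert spanning_insertions([rec], GenomicInterval("chr1", 0, 600), 5) == []
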