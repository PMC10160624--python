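"""Split-read and insertion evidence for structural variants."""

import pytest

from lrconfirm.core import GenomicInterval, Status, Thresholds
from lrconfirm.scenarios import (
    large_deletion,
    large_inversion,
    mei_insertion,
    small_sv_deletion,
)
from lrconfirm.sv import (
    breakpoint_support,
    confirm_del_dup_splitread,
    confirm_insertion,
    confirm_inversion,
)

from conftest import matched_reads


@pytest.fixture(scope="module")
def inversion_error_free():
    return large_inversion(1, error_free=True)


@pytest.fixture(scope="module")
def deletion_error_free():
    return large_deletion(1, error_free=True)


def _split_read_pairs(records, bp1, bp2, window=500):
    """(strand_a, strand_b) for every read with segments at both
    breakpoints."""
    by_read = {}
    for r in records:
        by_read.setdefault(r.read_id, []).append(r)
    pairs = []
    for segs in by_read.values():
        if len(segs) < 2:
            continue
        at1 = [s for s in segs
               if abs(s.interval.start - bp1) <= window
               or abs(s.interval.end - bp1) <= window]
        at2 = [s for s in segs
               if abs(s.interval.start - bp2) <= window
               or abs(s.interval.end - bp2) <= window]
        if at1 and at2 and at1[0] is not at2[0]:
            pairs.append((at1[0].strand, at2[0].strand))
    return pairs


class TestOrientationContract:
    def test_inversion_junction_reads_all_opposite_strand(
            self, inversion_error_free):
        """Error-free inversion: 100% of junction-spanning reads map with
        opposite-strand segments."""
        pairs = _split_read_pairs(inversion_error_free["records"],
                                  700_000, 1_300_000)
        assert pairs
        assert all(a != b for a, b in pairs)

    def test_deletion_junction_reads_all_same_strand(
            self, deletion_error_free):
        """Error-free deletion: 0% of junction reads show opposite
        strands."""
        pairs = _split_read_pairs(deletion_error_free["records"],
                                  200_000, 305_130)
        assert pairs
        assert all(a == b for a, b in pairs)


class TestBreakpointSupport:
    def test_monotone_in_window_and_clip_len(self, deletion_error_free):
        recs = deletion_error_free["records"]
        bp = GenomicInterval("chr16", 200_000, 200_001)
        s_narrow = breakpoint_support(recs, bp, 0, 200).split_reads
        s_wide = breakpoint_support(recs, bp, 500, 200).split_reads
        assert s_narrow <= s_wide
        s_strict = breakpoint_support(recs, bp, 500, 5000).split_reads
        assert s_strict <= s_wide

    def test_partner_recorded_at_other_breakpoint(self, deletion_error_free):
        recs = deletion_error_free["records"]
        sup = breakpoint_support(
            recs, GenomicInterval("chr16", 200_000, 200_001), 500, 200,
            partner=GenomicInterval("chr16", 305_130, 305_131))
        with_partner = [o for o in sup.orientations
                        if o["partner_breakpoint_present"]]
        assert with_partner
        assert all(o["partner_strand"] == o["strand_here"]
                   for o in with_partner)

    def test_no_clipped_reads_no_support(self, random_ref):
        reads = matched_reads(random_ref["chr1"], "chr1", 10, 100, 300)
        sup = breakpoint_support(reads, GenomicInterval("chr1", 200, 201),
                                 50, 50)
        assert sup.split_reads == 0


class TestInsertion:
    def test_simulated_300bp_insertion_confirms(self):
        sc = mei_insertion(1, depth=18.0)
        res = confirm_insertion(sc["query"], sc["records"])
        assert res.status == Status.CONFIRMED
        assert abs(len(res.evidence["consensus_insertion"]) - 300) <= 30
        ctrl = confirm_insertion(sc["control"], sc["records"])
        assert ctrl.status != Status.CONFIRMED

    def test_wrong_length_not_confirmed(self):
        sc = mei_insertion(1, depth=18.0)
        q = sc["query"]
        q.expected_length = 1200  # observed ~300 bp falls outside +/-30%
        res = confirm_insertion(q, sc["records"])
        assert res.status == Status.NOT_CONFIRMED

    def test_low_depth_is_insufficient(self):
        sc = mei_insertion(1)
        thin = [r for i, r in enumerate(sc["records"]) if i % 3 == 0]
        res = confirm_insertion(sc["query"], thin,
                                Thresholds(min_genomic_depth=12))
        assert res.status == Status.INSUFFICIENT_COVERAGE


class TestInversion:
    def test_simulated_large_inversion_confirms(self):
        sc = large_inversion(1)
        res = confirm_inversion(sc["query"], sc["records"])
        assert res.status == Status.CONFIRMED
        assert res.evidence["opposite_strand_split_reads"] >= 3

    def test_deletion_signature_rejected(self, deletion_error_free):
        """Same-strand split reads at both ends never confirm an
        inversion."""
        res = confirm_inversion(deletion_error_free["inversion_control"],
                                deletion_error_free["records"],
                                Thresholds(min_genomic_depth=1))
        assert res.status == Status.NOT_CONFIRMED
        assert res.evidence["opposite_strand_split_reads"] == 0
        assert res.evidence["same_strand_split_reads"] >= 1

    def test_interchromosomal_breakpoints_rejected(self):
        sc = large_inversion(1)
        q = sc["query"]
        q.breakpoints = (GenomicInterval("chr2", 100, 101),
                         GenomicInterval("chr3", 100, 101))
        with pytest.raises(ValueError):
            confirm_inversion(q, sc["records"])


class TestDelDup:
    def test_small_deletion_via_cigar_operations(self):
        sc = small_sv_deletion(1)
        res = confirm_del_dup_splitread(sc["query"], sc["records"])
        assert res.status == Status.CONFIRMED
        assert res.evidence["spanning_reads_with_event"] >= 3

    def test_large_deletion_via_split_reads(self):
        sc = large_deletion(3)
        res = confirm_del_dup_splitread(sc["query"], sc["records"])
        assert res.status == Status.CONFIRMED
        assert res.evidence["consistent_split_reads"] >= 3

    def test_homozygous_doubles_junction_reads(self):
        """Homozygous deletion yields about twice the junction reads of
        the heterozygous simulation at equal depth."""
        het = large_deletion(2, error_free=True)
        hom = large_deletion(2, homozygous=True, error_free=True)
        low = Thresholds(min_genomic_depth=1)
        n_het = confirm_del_dup_splitread(
            het["query"], het["records"], low
        ).evidence["consistent_split_reads"]
        n_hom = confirm_del_dup_splitread(
            hom["query"], hom["records"], low
        ).evidence["consistent_split_reads"]
        assert n_het >= 2
        assert 1.2 <= n_hom / n_het <= 3.5

    def test_unsupported_breakpoints_not_confirmed(self, random_ref):
        reads = matched_reads(random_ref["chr1"], "chr1", 20, 0, 600)
        sc = small_sv_deletion(1)
        q = sc["query"]
        res = confirm_del_dup_splitread(q, sc["records"][:0] or [],
                                        Thresholds(min_genomic_depth=0))
        assert res.status == Status.NOT_CONFIRMED
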