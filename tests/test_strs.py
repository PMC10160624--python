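"""Repeat counting, interruption detection, STR locus decisions."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from lrconfirm.core import Status
from lrconfirm.scenarios import str_expansion
from lrconfirm.simulate import revcomp
from lrconfirm.strs import (
    count_repeats_in_read,
    decide_str,
    load_str_catalog,
    profile_str_locus,
)

LEFT = "TGACCTGAAGGCTTAGCTAGGACTTCAGAT"
RIGHT = "CCATGGATCCGTTAGAACGGTTCACTGGAA"


class TestCountRepeats:
    def test_pure_tract_spanning(self):
        read = LEFT + "CAG" * 51 + RIGHT
        count, inter, spanning = count_repeats_in_read(read, "CAG", LEFT, RIGHT)
        assert (count, inter, spanning) == (51, [], True)

    def test_interruptions_count_toward_total(self):
        # 74 motif units + 3 interrupting units -> tract of 77 units
        units = ["CTG"] * 74
        for off in (10, 40, 60):
            units.insert(off, "TAA")
        read = LEFT + "".join(units) + RIGHT
        count, inter, spanning = count_repeats_in_read(read, "CTG", LEFT, RIGHT)
        assert count == 77
        assert len(inter) == 3
        assert spanning
        assert sorted(i.offset_in_tract for i in inter) == [10, 40, 60]

    def test_truncated_read_is_lower_bound(self):
        read = LEFT + "CAG" * 120  # right flank never reached
        count, inter, spanning = count_repeats_in_read(read, "CAG", LEFT, RIGHT)
        assert count == 120
        assert not spanning

    def test_right_flank_only(self):
        read = "CAG" * 80 + RIGHT
        count, _, spanning = count_repeats_in_read(read, "CAG", LEFT, RIGHT)
        assert count == 80
        assert not spanning

    def test_neither_flank_is_no_call(self):
        assert count_repeats_in_read("CAG" * 50, "CAG", LEFT, RIGHT) is None

    def test_non_acgt_motif_rejected(self):
        with pytest.raises(ValueError):
            count_repeats_in_read("ACGT", "CNG", LEFT, RIGHT)

    def test_single_unit_mismatch_tolerated(self):
        units = ["CAG"] * 30
        units[10] = "CAT"  # one mismatch: still a motif unit, not an interruption
        read = LEFT + "".join(units) + RIGHT
        count, inter, _ = count_repeats_in_read(read, "CAG", LEFT, RIGHT)
        assert count == 30 and inter == []


@st.composite
def _tract_example(draw):
    motif = draw(st.text(alphabet="ACGT", min_size=2, max_size=6))
    n_units = draw(st.integers(3, 60))
    n_inter = draw(st.integers(0, 3))
    units = [motif] * n_units
    for _ in range(n_inter):
        # an interruption differs from the motif in >= 2 positions
        unit = draw(st.text(alphabet="ACGT", min_size=len(motif),
                            max_size=len(motif)))
        if sum(a != b for a, b in zip(unit, motif)) < 2:
            unit = "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[c]
                           for c in motif)
        units.insert(draw(st.integers(0, len(units))), unit)
    left = draw(st.text(alphabet="ACGT", min_size=30, max_size=30))
    right = draw(st.text(alphabet="ACGT", min_size=30, max_size=30))
    return motif, units, left, right


class TestCounterOracle:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(_tract_example())
    def test_matches_unit_oracle_on_error_free_reads(self, example):
        """Greedy counting equals the direct unit-enumeration / regex
        oracle for all motifs of length 2-6 on error-free reads."""
        motif, units, left, right = example
        tract = "".join(units)
        read = left + tract + right
        # exact flanks must occur exactly once for the example to be valid
        if read.count(left) != 1 or read.count(right) != 1:
            return
        got = count_repeats_in_read(read, motif, left, right,
                                    max_mismatch_frac=0.0)
        assert got is not None
        count, inter, spanning = got
        assert spanning
        assert count == len(units)
        # regex oracle on the unit grid: units matching the motif exactly
        # vs. units within one mismatch (what the counter calls motif units)
        grid = [tract[i:i + len(motif)]
                for i in range(0, len(tract) - len(motif) + 1, len(motif))]
        exact_units = sum(bool(re.fullmatch(re.escape(motif), u)) for u in grid)
        hamming_le1 = sum(
            sum(a != b for a, b in zip(u, motif)) <= 1 for u in grid)
        assert count - len(inter) == hamming_le1
        assert exact_units <= hamming_le1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(_tract_example())
    def test_strand_consistency(self, example):
        """Reverse-complementing read, motif and (swapped) flanks leaves
        the unit count unchanged."""
        motif, units, left, right = example
        read = left + "".join(units) + right
        if read.count(left) != 1 or read.count(right) != 1:
            return
        fwd = count_repeats_in_read(read, motif, left, right, 0.0)
        rev = count_repeats_in_read(revcomp(read), revcomp(motif),
                                    revcomp(right), revcomp(left), 0.0)
        rc = revcomp(read)
        if rc.count(revcomp(right)) != 1 or rc.count(revcomp(left)) != 1:
            return
        assert fwd is not None and rev is not None
        assert fwd[0] == rev[0]
        assert len(fwd[1]) == len(rev[1])


@pytest.fixture(scope="module")
def het_16_68():
    sc = str_expansion(1)  # reference 16 CAG, expansion to 68, thr 36
    profile = profile_str_locus(sc["records"], sc["query"], sc["reference"])
    return sc, profile


class TestProfileAndDecision:

    def test_two_modes_recovered(self, het_16_68):
        _, profile = het_16_68
        modes = sorted(m for m, _ in profile.allele_summary)
        assert len(modes) == 2
        assert abs(modes[0] - 16) <= 2
        assert abs(modes[1] - 68) <= 3

    def test_max_observed_is_max_of_per_read(self, het_16_68):
        _, profile = het_16_68
        assert profile.max_observed == max(r.repeat_count
                                           for r in profile.per_read)

    def test_pathogenic_expansion_confirms(self, het_16_68):
        sc, profile = het_16_68
        res, decision = decide_str(profile, sc["query"])
        assert res.status == Status.CONFIRMED
        assert decision.expanded_reads >= 1
        assert decision.mosaic_range[0] >= 36

    def test_normal_genotype_not_confirmed(self):
        # FMR1-like 30/23 against threshold 45
        sc = str_expansion(1, normal=30, expanded=23, motif="CGG", threshold=45)
        profile = profile_str_locus(sc["records"], sc["query"], sc["reference"])
        res, decision = decide_str(profile, sc["query"])
        assert res.status == Status.NOT_CONFIRMED
        assert decision.expanded_reads == 0

    def test_threshold_boundary_is_geq(self, het_16_68):
        sc, profile = het_16_68
        below = max(r.repeat_count for r in profile.per_read) + 1
        q = sc["query"]
        q.pathogenic_threshold = below
        res, _ = decide_str(profile, q)
        assert res.status == Status.NOT_CONFIRMED
        q.pathogenic_threshold = profile.max_observed
        res, _ = decide_str(profile, q)
        assert res.status == Status.CONFIRMED

    def test_huge_expansion_confirmed_from_clipped_lower_bounds(self):
        # DMPK-like 2000-repeat expansion: tract (6 kb) exceeds many reads
        sc = str_expansion(2, normal=21, expanded=2000, motif="CTG",
                           threshold=36)
        profile = profile_str_locus(sc["records"], sc["query"], sc["reference"])
        res, _ = decide_str(profile, sc["query"])
        assert res.status == Status.CONFIRMED
        assert profile.max_observed >= 36
        assert any(not r.spanning for r in profile.per_read)
        # clipped lower bounds never define allele modes
        assert all(m <= 2005 for m, _ in profile.allele_summary)

    def test_mosaic_mix_widens_range(self):
        sc = str_expansion(2, normal=21, motif="CTG", threshold=36,
                           mosaic_counts=[330, 335, 340, 345, 350])
        profile = profile_str_locus(sc["records"], sc["query"], sc["reference"])
        res, decision = decide_str(profile, sc["query"])
        assert res.status == Status.CONFIRMED
        lo, hi = decision.mosaic_range
        assert hi > lo  # somatic variability visible as a length range
        assert hi >= 330


def test_bundled_catalog_lists_validated_loci():
    catalog = load_str_catalog()
    genes = {row["gene"] for row in catalog}
    assert {"HTT", "DMPK", "FMR1", "FXN", "C9ORF72"} <= genes
    for row in catalog:
        assert int(row["pathogenic_threshold"]) > 0
        assert set(row["motif"]) <= set("ACGT")
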