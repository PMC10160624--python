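"""Confirmation of small sequence changes (<=50 bp), mitochondrial
heteroplasmy estimation, and read-backed phasing of variant pairs.

Decision semantics: a variant queried at a locus with local depth below the
floor (12x genomic, 1000x mitochondrial) is ``insufficient_coverage``;
observed at or above the floor without adequate read support it is
``not_confirmed`` (the pipeline's false-negative rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .core import (
    AlignmentRecord,
    ConfirmationResult,
    Kind,
    Status,
    Thresholds,
    VariantQuery,
    is_mito,
)
from .evidence import (
    allele_pileup,
    allele_windows,
    classify_read_allele,
    depth_eligible,
)


@dataclass
class HeteroplasmyEstimate:
    """Fraction of mitochondrial genome copies carrying the variant,
    estimated as alt reads over total classified depth."""

    alt_count: int
    depth: int
    fraction: float
    percent_rounded: int

    @staticmethod
    def from_counts(alt_count: int, depth: int) -> "HeteroplasmyEstimate":
        if depth <= 0:
            raise ValueError("depth must be positive")
        frac = alt_count / depth
        # half away from zero, i.e. 0.385 -> 39
        pct = int(math.floor(frac * 100 + 0.5))
        return HeteroplasmyEstimate(alt_count, depth, frac, pct)


@dataclass
class PhaseCall:
    """Joint classification of reads spanning two SSC loci."""

    pair: tuple[str, str]
    relationship: str  # cis | trans | unphased
    reads_both: int
    reads_v1_only: int
    reads_v2_only: int
    reads_neither: int

    @property
    def spanning(self) -> int:
        return (self.reads_both + self.reads_v1_only
                + self.reads_v2_only + self.reads_neither)


def confirm_ssc(
    query: VariantQuery,
    alignments: Iterable[AlignmentRecord],
    reference,
    thresholds: Optional[Thresholds] = None,
) -> ConfirmationResult:
    """Confirm a nuclear small sequence change from its allele pileup."""
    if query.kind != Kind.SSC:
        raise ValueError(f"confirm_ssc got kind {query.kind}")
    thresholds = thresholds or Thresholds()
    counts = allele_pileup(alignments, query, reference, thresholds)
    if counts.depth < thresholds.min_genomic_depth:
        return ConfirmationResult(
            query.query_id, Status.INSUFFICIENT_COVERAGE, counts.depth,
            notes=f"local depth {counts.depth} below "
                  f"{thresholds.min_genomic_depth}x floor",
        )
    supported = (
        counts.alt_count >= thresholds.min_support_reads
        and counts.alt_count / counts.depth >= thresholds.min_support_fraction
    )
    status = Status.CONFIRMED if supported else Status.NOT_CONFIRMED
    return ConfirmationResult(
        query.query_id, status, counts.depth, evidence=counts.to_dict()
    )


def heteroplasmy(
    query: VariantQuery,
    alignments: Iterable[AlignmentRecord],
    reference,
    thresholds: Optional[Thresholds] = None,
) -> tuple[ConfirmationResult, Optional[HeteroplasmyEstimate]]:
    """Confirm a mitochondrial variant and estimate its heteroplasmy level."""
    if query.kind != Kind.MITO_SSC:
        raise ValueError(f"heteroplasmy got kind {query.kind}")
    thresholds = thresholds or Thresholds()
    notes = ""
    if not is_mito(query.locus.chrom):
        notes = f"non-mitochondrial contig {query.locus.chrom}; proceeding"
    counts = allele_pileup(alignments, query, reference, thresholds)
    if counts.depth < thresholds.min_mito_depth:
        res = ConfirmationResult(
            query.query_id, Status.INSUFFICIENT_COVERAGE, counts.depth,
            notes=(notes + "; " if notes else "")
            + f"depth {counts.depth} below {thresholds.min_mito_depth}x floor",
        )
        return res, None
    est = HeteroplasmyEstimate.from_counts(counts.alt_count, counts.depth)
    status = (Status.CONFIRMED if counts.alt_count >= thresholds.min_support_reads
              else Status.NOT_CONFIRMED)
    evidence = counts.to_dict()
    evidence["heteroplasmy_fraction"] = est.fraction
    evidence["heteroplasmy_percent"] = est.percent_rounded
    return (
        ConfirmationResult(query.query_id, status, counts.depth,
                           evidence=evidence, notes=notes),
        est,
    )


def phase_pair(
    q1: VariantQuery,
    q2: VariantQuery,
    alignments: Iterable[AlignmentRecord],
    reference,
    thresholds: Optional[Thresholds] = None,
) -> PhaseCall:
    """Phase two small variants from reads spanning both loci.

    ``trans`` requires each single-variant class to reach the support floor
    with (almost) no double-alt reads; ``cis`` is the symmetric condition.
    A fraction of contradicting reads up to ``phase_noise_fraction`` of the
    double-spanning reads is tolerated.
    """
    if q1.locus.chrom != q2.locus.chrom:
        raise ValueError("phase_pair requires variants on the same chromosome")
    thresholds = thresholds or Thresholds()
    w1 = allele_windows(q1, reference)
    w2 = allele_windows(q2, reference)
    both = v1 = v2 = neither = 0
    for rec in alignments:
        if not depth_eligible(rec, thresholds):
            continue
        c1 = classify_read_allele(rec, q1, w1[0], w1[1], w1[2], w1[3])
        c2 = classify_read_allele(rec, q2, w2[0], w2[1], w2[2], w2[3])
        if c1 is None or c2 is None or c1 == "other" or c2 == "other":
            continue
        if c1 == "alt" and c2 == "alt":
            both += 1
        elif c1 == "alt":
            v1 += 1
        elif c2 == "alt":
            v2 += 1
        else:
            neither += 1
    spanning = both + v1 + v2 + neither
    tol = thresholds.phase_noise_fraction * spanning
    m = thresholds.min_support_reads
    relationship = "unphased"
    if spanning >= 1:
        if v1 >= m and v2 >= m and both <= tol:
            relationship = "trans"
        elif both >= m and v1 <= tol and v2 <= tol:
            relationship = "cis"
    return PhaseCall(
        pair=(q1.query_id, q2.query_id),
        relationship=relationship,
        reads_both=both,
        reads_v1_only=v1,
        reads_v2_only=v2,
        reads_neither=neither,
    )
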