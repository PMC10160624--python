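"""Structural-variant confirmation from read-level evidence.

Three evidence channels, chosen by event type and size:

* events short enough to sit inside one read (small deletions, insertions
  including mobile elements) are confirmed from CIGAR operations of
  spanning reads;
* longer deletions/duplications are confirmed from clipped/split reads at
  both breakpoints with size- and orientation-consistent partners;
* inversions require split reads whose two segments map near the two
  breakpoints on opposite strands — same-strand split reads (the deletion
  signature) never count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Optional

from .core import (
    AlignmentRecord,
    ConfirmationResult,
    GenomicInterval,
    Kind,
    Role,
    Status,
    Thresholds,
    VariantQuery,
)
from .evidence import clipped_reads, local_depth, spanning_insertions


@dataclass
class SegmentInfo:
    read_id: str
    interval: GenomicInterval
    strand: str
    role: Role


@dataclass
class BreakpointSupport:
    breakpoint: GenomicInterval
    split_reads: int
    orientations: list[dict] = field(default_factory=list)


def _segments_by_read(
    alignments: Iterable[AlignmentRecord],
) -> dict[str, list[SegmentInfo]]:
    by_read: dict[str, list[SegmentInfo]] = {}
    for rec in alignments:
        if rec.role == Role.SECONDARY:
            continue
        by_read.setdefault(rec.read_id, []).append(
            SegmentInfo(rec.read_id, rec.interval, rec.strand, rec.role)
        )
    return by_read


def _near(pos: int, breakpoint: GenomicInterval, window: int) -> bool:
    return breakpoint.start - window <= pos <= breakpoint.end + window


def _segment_at(seg: SegmentInfo, breakpoint: GenomicInterval, window: int) -> bool:
    """A segment supports a breakpoint when one of its ends lies within
    breakpoint +/- window on the same contig."""
    if seg.interval.chrom != breakpoint.chrom:
        return False
    return (_near(seg.interval.start, breakpoint, window)
            or _near(seg.interval.end, breakpoint, window))


def breakpoint_support(
    alignments: Iterable[AlignmentRecord],
    breakpoint: GenomicInterval,
    window: int,
    min_clip_len: int,
    partner: Optional[GenomicInterval] = None,
) -> BreakpointSupport:
    """Reads with a clip boundary or split-alignment junction at a
    breakpoint; when ``partner`` is given, records whether each read also
    maps there and on which strand."""
    if window < 0:
        raise ValueError("window must be >= 0")
    recs = list(alignments)
    search = GenomicInterval(
        breakpoint.chrom,
        max(breakpoint.start - window, 0),
        breakpoint.end + window,
    )
    clip_ids = {c.read_id for c in clipped_reads(recs, search, min_clip_len)}
    by_read = _segments_by_read(recs)
    orientations: list[dict] = []
    supporting: set[str] = set()
    for read_id, segs in by_read.items():
        here = [s for s in segs if _segment_at(s, breakpoint, window)]
        if not here:
            continue
        is_split = len(segs) >= 2
        if read_id not in clip_ids and not is_split:
            continue
        supporting.add(read_id)
        partner_seg = None
        if partner is not None:
            for s in segs:
                if s is not here[0] and _segment_at(s, partner, window):
                    partner_seg = s
                    break
        orientations.append({
            "read_id": read_id,
            "strand_here": here[0].strand,
            "partner_breakpoint_present": partner_seg is not None,
            "partner_strand": partner_seg.strand if partner_seg else None,
        })
    return BreakpointSupport(breakpoint, len(supporting), orientations)


def _breakpoint_depth(
    recs: list[AlignmentRecord],
    breakpoints: tuple[GenomicInterval, GenomicInterval],
    thresholds: Thresholds,
) -> int:
    """Median depth over the outward flanks of the event.

    The left flank window ends at the first breakpoint and the right one
    starts at the second, so a heterozygous event's interior (uncovered on
    the variant haplotype) does not drag the estimate down.  A split read
    counts through the union of its primary and supplementary segments
    (each read once per base)."""
    import numpy as np

    w = 2 * thresholds.breakpoint_window
    bp1, bp2 = breakpoints
    flanks = [
        GenomicInterval(bp1.chrom, max(bp1.start - w, 0), max(bp1.start, 1)),
        GenomicInterval(bp2.chrom, bp2.end, bp2.end + w),
    ]
    depths = []
    for iv in flanks:
        n = len(iv)
        cover = np.zeros(n + 1, dtype=np.int64)
        by_read: dict[str, list[tuple[int, int]]] = {}
        for rec in recs:
            if rec.role == Role.SECONDARY or rec.mapq < thresholds.min_mapq:
                continue
            if not rec.interval.overlaps(iv):
                continue
            a = max(rec.interval.start, iv.start) - iv.start
            b = min(rec.interval.end, iv.end) - iv.start
            by_read.setdefault(rec.read_id, []).append((a, b))
        for spans in by_read.values():
            spans.sort()
            merged = [list(spans[0])]
            for a, b in spans[1:]:
                if a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            for a, b in merged:
                cover[a] += 1
                cover[b] -= 1
        depths.append(int(np.median(np.cumsum(cover[:-1]))))
    return int(median(depths))


def confirm_insertion(
    query: VariantQuery,
    alignments: Iterable[AlignmentRecord],
    thresholds: Optional[Thresholds] = None,
) -> ConfirmationResult:
    """Confirm an insertion (e.g. a mobile element) from spanning reads
    carrying an insertion operation of compatible length.

    Length matching is approximate (default +/-30%), reflecting that an
    Alu-sized event is recognised by its ~300 bp scale rather than an
    exact base count.  Clip-only evidence is reported but never suffices.
    The consensus inserted sequence (from the read with the median-length
    event) is emitted for external classification.
    """
    if query.kind != Kind.SV_INS:
        raise ValueError(f"confirm_insertion got kind {query.kind}")
    if query.expected_length <= 0:
        raise ValueError(f"{query.query_id}: expected_length must be set")
    thresholds = thresholds or Thresholds()
    recs = list(alignments)
    w = thresholds.breakpoint_window
    loc = query.locus
    search = GenomicInterval(loc.chrom, max(loc.start - w, 0), loc.end + w)
    depth = local_depth(recs, search, thresholds)
    if depth < thresholds.min_genomic_depth:
        return ConfirmationResult(
            query.query_id, Status.INSUFFICIENT_COVERAGE, depth,
            notes=f"depth {depth} below {thresholds.min_genomic_depth}x floor",
        )
    tol = thresholds.indel_len_tolerance
    lo = int(query.expected_length * (1 - tol))
    hi = int(query.expected_length * (1 + tol))
    min_len = max(1, lo)
    obs = spanning_insertions(recs, search, min_len)
    matching = [o for o in obs if lo <= o.length <= hi]
    clips = clipped_reads(recs, search, thresholds.min_clip_len)
    support_ids = {o.read_id for o in matching}
    consensus = ""
    if matching:
        by_len = sorted(matching, key=lambda o: o.length)
        consensus = by_len[len(by_len) // 2].inserted_sequence
    status = (Status.CONFIRMED if len(support_ids) >= thresholds.min_support_reads
              else Status.NOT_CONFIRMED)
    return ConfirmationResult(
        query.query_id, status, depth,
        evidence={
            "expected_length": query.expected_length,
            "supporting_reads": len(support_ids),
            "observed_lengths": sorted(o.length for o in matching),
            "clip_only_reads": len({c.read_id for c in clips} - support_ids),
            "consensus_insertion": consensus,
        },
    )


def confirm_inversion(
    query: VariantQuery,
    alignments: Iterable[AlignmentRecord],
    thresholds: Optional[Thresholds] = None,
) -> ConfirmationResult:
    """Confirm an inversion from opposite-strand split reads at its two
    breakpoints."""
    if query.kind != Kind.SV_INV:
        raise ValueError(f"confirm_inversion got kind {query.kind}")
    if not query.breakpoints:
        raise ValueError(f"{query.query_id}: breakpoints must be set")
    bp1, bp2 = query.breakpoints
    if bp1.chrom != bp2.chrom:
        raise ValueError("inversions are intrachromosomal; breakpoints on "
                         f"{bp1.chrom} and {bp2.chrom}")
    thresholds = thresholds or Thresholds()
    recs = list(alignments)
    w = thresholds.breakpoint_window
    depth = _breakpoint_depth(recs, (bp1, bp2), thresholds)
    if depth < thresholds.min_genomic_depth:
        return ConfirmationResult(
            query.query_id, Status.INSUFFICIENT_COVERAGE, depth,
            notes=f"depth {depth} below {thresholds.min_genomic_depth}x floor",
        )
    by_read = _segments_by_read(recs)
    opposite = set()
    same = set()
    for read_id, segs in by_read.items():
        if len(segs) < 2:
            continue
        at1 = [s for s in segs if _segment_at(s, bp1, w)]
        at2 = [s for s in segs if _segment_at(s, bp2, w)]
        pair = None
        for a in at1:
            for b in at2:
                if a is not b:
                    pair = (a, b)
                    break
            if pair:
                break
        if not pair:
            continue
        (opposite if pair[0].strand != pair[1].strand else same).add(read_id)
    sup1 = breakpoint_support(recs, bp1, w, thresholds.min_clip_len, partner=bp2)
    sup2 = breakpoint_support(recs, bp2, w, thresholds.min_clip_len, partner=bp1)
    status = (Status.CONFIRMED if len(opposite) >= thresholds.min_support_reads
              else Status.NOT_CONFIRMED)
    return ConfirmationResult(
        query.query_id, status, depth,
        evidence={
            "opposite_strand_split_reads": len(opposite),
            "same_strand_split_reads": len(same),
            "breakpoint_1": {"pos": bp1.to_1based(), "split_reads": sup1.split_reads,
                             "segments": sup1.orientations},
            "breakpoint_2": {"pos": bp2.to_1based(), "split_reads": sup2.split_reads,
                             "segments": sup2.orientations},
        },
    )


def confirm_del_dup_splitread(
    query: VariantQuery,
    alignments: Iterable[AlignmentRecord],
    thresholds: Optional[Thresholds] = None,
) -> ConfirmationResult:
    """Confirm a deletion or tandem duplication from read evidence.

    Spanning-read route: reads whose CIGAR carries a deletion operation of
    compatible size inside the event (deletions fully inside reads).
    Split-read route: reads with same-strand segments at both breakpoints,
    partner positions consistent with the event type (DEL: jump forward
    over the event; DUP: jump backward to the event start, the tandem
    junction).  Depth-based corroboration for large events belongs to the
    copy-number track, not here.
    """
    if query.kind not in (Kind.SV_DEL, Kind.SV_DUP):
        raise ValueError(f"confirm_del_dup_splitread got kind {query.kind}")
    if not query.breakpoints:
        raise ValueError(f"{query.query_id}: breakpoints must be set")
    bp1, bp2 = query.breakpoints
    thresholds = thresholds or Thresholds()
    recs = list(alignments)
    w = thresholds.breakpoint_window
    depth = _breakpoint_depth(recs, (bp1, bp2), thresholds)
    if depth < thresholds.min_genomic_depth:
        return ConfirmationResult(
            query.query_id, Status.INSUFFICIENT_COVERAGE, depth,
            notes=f"depth {depth} below {thresholds.min_genomic_depth}x floor",
        )
    size = bp2.start - bp1.start
    tol = thresholds.indel_len_tolerance
    spanning_ids: set[str] = set()
    if query.kind == Kind.SV_DEL:
        lo, hi = size * (1 - tol), size * (1 + tol)
        region = GenomicInterval(bp1.chrom, max(bp1.start - w, 0), bp2.end + w)
        for rec in recs:
            if rec.role != Role.PRIMARY or not rec.interval.overlaps(region):
                continue
            rpos = rec.interval.start
            for op, n in rec.cigar:
                if op == "M":
                    rpos += n
                elif op == "D":
                    if lo <= n <= hi and _near(rpos, bp1, w + size):
                        spanning_ids.add(rec.read_id)
                    rpos += n
    # split-read route
    by_read = _segments_by_read(recs)
    split_ids: set[str] = set()
    for read_id, segs in by_read.items():
        if len(segs) < 2:
            continue
        for a in segs:
            for b in segs:
                if a is b or a.strand != b.strand:
                    continue
                if query.kind == Kind.SV_DEL:
                    # a ends at bp1, b starts at bp2: forward jump
                    if (_near(a.interval.end, bp1, w)
                            and _near(b.interval.start, bp2, w)):
                        split_ids.add(read_id)
                else:
                    # tandem duplication junction: a ends at bp2 (end of the
                    # duplicated copy), b restarts at bp1
                    if (_near(a.interval.end, bp2, w)
                            and _near(b.interval.start, bp1, w)):
                        split_ids.add(read_id)
    m = thresholds.min_support_reads
    confirmed = len(spanning_ids) >= m or len(split_ids) >= m
    status = Status.CONFIRMED if confirmed else Status.NOT_CONFIRMED
    return ConfirmationResult(
        query.query_id, status, depth,
        evidence={
            "event_size": size,
            "spanning_reads_with_event": len(spanning_ids),
            "consistent_split_reads": len(split_ids),
        },
    )
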