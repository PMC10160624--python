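"""Low-level evidence extraction from alignments.

Everything downstream (SSC, STR, SV, CNV, UPD confirmers) is built on the
four primitives here: local depth, per-read allele classification at a
locus, clipped-read collection, and per-read insertion events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .core import (
    AlignmentRecord,
    GenomicInterval,
    Kind,
    Role,
    Thresholds,
    VariantQuery,
    fetch_ref,
)

#: reference padding around an allele when comparing read slices to alleles
ALLELE_WINDOW_PAD = 10


@dataclass
class PileupCounts:
    """Read classification tallies at a small-variant locus.

    ``alt_count / depth`` is the allele (or heteroplasmy) fraction; reads
    matching neither allele land in ``other_count`` and never support
    confirmation.
    """

    depth: int = 0
    ref_count: int = 0
    alt_count: int = 0
    other_count: int = 0

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "ref_count": self.ref_count,
            "alt_count": self.alt_count,
            "other_count": self.other_count,
        }


@dataclass
class ClipEvidence:
    read_id: str
    clip_side: str  # left | right
    clip_len: int
    clip_pos: int  # 0-based reference position of the clip boundary
    strand: str
    role: Role


@dataclass
class InsertionObservation:
    read_id: str
    position: int  # 0-based reference position the insertion is anchored at
    length: int
    inserted_sequence: str


def depth_eligible(rec: AlignmentRecord, thresholds: Thresholds) -> bool:
    """Primary alignments above the mapq floor; supplementary/secondary
    segments never count toward depth."""
    return rec.role == Role.PRIMARY and rec.mapq >= thresholds.min_mapq


def local_depth(
    alignments: Iterable[AlignmentRecord],
    interval: GenomicInterval,
    thresholds: Optional[Thresholds] = None,
) -> int:
    """Median per-base count of depth-eligible reads over ``interval``."""
    thresholds = thresholds or Thresholds()
    if len(interval) == 0:
        raise ValueError("interval must be nonempty")
    cover = np.zeros(len(interval) + 1, dtype=np.int64)
    for rec in alignments:
        if not depth_eligible(rec, thresholds):
            continue
        if not rec.interval.overlaps(interval):
            continue
        a = max(rec.interval.start, interval.start) - interval.start
        b = min(rec.interval.end, interval.end) - interval.start
        cover[a] += 1
        cover[b] -= 1
    per_base = np.cumsum(cover[:-1])
    return int(np.median(per_base))


def aligned_slice(
    rec: AlignmentRecord, start: int, end: int
) -> Optional[str]:
    """Read bases aligned to reference window [start, end), including
    insertions anchored strictly inside it.

    Returns ``None`` when the record does not fully span the window (the
    read cannot be classified at the locus).
    """
    if rec.interval.start > start or rec.interval.end < end:
        return None
    qpos = 0
    rpos = rec.interval.start
    parts: list[str] = []
    for op, n in rec.cigar:
        if op == "S":
            qpos += n
        elif op == "H":
            pass
        elif op == "M":
            a = max(rpos, start)
            b = min(rpos + n, end)
            if a < b:
                parts.append(rec.sequence[qpos + (a - rpos): qpos + (b - rpos)])
            qpos += n
            rpos += n
        elif op == "I":
            if start < rpos < end:
                parts.append(rec.sequence[qpos: qpos + n])
            qpos += n
        elif op == "D":
            rpos += n
    return "".join(parts)


def _edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def classify_read_allele(
    rec: AlignmentRecord,
    query: VariantQuery,
    ref_window: str,
    alt_window: str,
    wstart: int,
    wend: int,
) -> Optional[str]:
    """Classify one read at an SSC locus as ``ref`` / ``alt`` / ``other``.

    The read's aligned slice over a padded window is compared by edit
    distance against the reference window and the window rewritten with the
    alternate allele; the closer one wins, ties are ``other``.  Returns
    ``None`` when the read does not span the window.
    """
    if rec.interval.chrom != query.locus.chrom:
        return None
    obs = aligned_slice(rec, wstart, wend)
    if obs is None:
        return None
    d_ref = _edit_distance(obs, ref_window)
    d_alt = _edit_distance(obs, alt_window)
    if d_alt < d_ref:
        return "alt"
    if d_ref < d_alt:
        return "ref"
    return "other"


def allele_windows(
    query: VariantQuery, reference, pad: int = ALLELE_WINDOW_PAD
) -> tuple[str, str, int, int]:
    """Reference and alternate sequence windows around an SSC locus."""
    if not set(query.ref_allele) <= set("ACGT") or not set(query.alt_allele) <= set("ACGT"):
        raise ValueError(f"{query.query_id}: alleles must be ACGT only")
    loc = query.locus
    wstart = max(loc.start - pad, 0)
    wend = loc.end + pad
    left = fetch_ref(reference, loc.chrom, wstart, loc.start)
    right = fetch_ref(reference, loc.chrom, loc.end, wend)
    mid_ref = fetch_ref(reference, loc.chrom, loc.start, loc.end)
    if mid_ref != query.ref_allele:
        raise ValueError(
            f"{query.query_id}: ref allele {query.ref_allele} does not match "
            f"reference {mid_ref} at {loc.to_1based()}"
        )
    return left + mid_ref + right, left + query.alt_allele + right, wstart, wend


def allele_pileup(
    alignments: Iterable[AlignmentRecord],
    query: VariantQuery,
    reference,
    thresholds: Optional[Thresholds] = None,
) -> PileupCounts:
    """Classify every depth-eligible spanning read at an SSC locus."""
    if query.kind not in (Kind.SSC, Kind.MITO_SSC):
        raise ValueError(f"allele_pileup needs an SSC-kind query, got {query.kind}")
    thresholds = thresholds or Thresholds()
    ref_w, alt_w, wstart, wend = allele_windows(query, reference)
    counts = PileupCounts()
    for rec in alignments:
        if not depth_eligible(rec, thresholds):
            continue
        cls = classify_read_allele(rec, query, ref_w, alt_w, wstart, wend)
        if cls is None:
            continue
        counts.depth += 1
        if cls == "ref":
            counts.ref_count += 1
        elif cls == "alt":
            counts.alt_count += 1
        else:
            counts.other_count += 1
    return counts


def clipped_reads(
    alignments: Iterable[AlignmentRecord],
    interval: GenomicInterval,
    min_clip_len: int,
) -> list[ClipEvidence]:
    """Soft/hard-clipped read ends whose clip boundary falls in ``interval``."""
    if min_clip_len < 1:
        raise ValueError("min_clip_len must be >= 1")
    out: list[ClipEvidence] = []
    for rec in alignments:
        if rec.role == Role.SECONDARY or rec.interval.chrom != interval.chrom:
            continue
        if rec.cigar and rec.cigar[0][0] in "SH":
            n = rec.cigar[0][1]
            pos = rec.interval.start
            if n >= min_clip_len and interval.start <= pos < interval.end:
                out.append(ClipEvidence(rec.read_id, "left", n, pos,
                                        rec.strand, rec.role))
        if rec.cigar and rec.cigar[-1][0] in "SH":
            n = rec.cigar[-1][1]
            pos = rec.interval.end
            if n >= min_clip_len and interval.start <= pos < interval.end:
                out.append(ClipEvidence(rec.read_id, "right", n, pos,
                                        rec.strand, rec.role))
    return out


def spanning_insertions(
    alignments: Iterable[AlignmentRecord],
    interval: GenomicInterval,
    min_len: int,
) -> list[InsertionObservation]:
    """Per-read insertion CIGAR events of length >= min_len anchored in
    ``interval``; one observation per read per event."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out: list[InsertionObservation] = []
    for rec in alignments:
        if rec.role == Role.SECONDARY or rec.interval.chrom != interval.chrom:
            continue
        if not rec.interval.overlaps(interval):
            continue
        qpos = 0
        rpos = rec.interval.start
        for op, n in rec.cigar:
            if op == "S":
                qpos += n
            elif op == "M":
                qpos += n
                rpos += n
            elif op == "I":
                if n >= min_len and interval.start <= rpos < interval.end:
                    seq = rec.sequence[qpos: qpos + n] if rec.sequence else ""
                    out.append(InsertionObservation(rec.read_id, rpos, n, seq))
                qpos += n
            elif op == "D":
                rpos += n
    return out
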