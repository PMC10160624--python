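"""Short-tandem-repeat expansion confirmation.

Per-read repeat counting works on the raw read sequence: the reference
flanks of the locus are located in the read (approximately, tolerating
ONT-level errors), the tract between them is extracted, and consecutive
motif units are counted greedily with at most one mismatch per unit.
Units matching neither criterion are recorded as interruptions and count
toward the total tract length, mirroring how expanded alleles are read off
sequence displays (e.g. "313 CAG + 21 interrupting repeats" is a tract of
334 units).  Reads that end inside the tract (one flank only) give
lower-bound counts; a lower bound beyond the pathogenic threshold still
confirms, but never defines an allele mode.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib

from .core import (
    AlignmentRecord,
    ConfirmationResult,
    GenomicInterval,
    Kind,
    Status,
    Thresholds,
    VariantQuery,
    fetch_ref,
)
from .evidence import depth_eligible

DEFAULT_FLANK_LEN = 30
DEFAULT_MAX_MISMATCH_FRAC = 0.25


@dataclass
class Interruption:
    offset_in_tract: int  # unit index within the tract, 0-based
    interrupting_unit: str


@dataclass
class ReadRepeatCount:
    read_id: str
    repeat_count: int  # total tract units (motif + interrupting)
    spanning: bool  # False -> lower bound only
    interruptions: list[Interruption] = field(default_factory=list)


@dataclass
class RepeatProfile:
    locus: GenomicInterval
    motif: str
    per_read: list[ReadRepeatCount]
    max_observed: int
    allele_summary: list[tuple[int, int]]  # (modal repeat count, supporting reads)
    depth: int  # reads overlapping the locus (depth-eligible primaries)


@dataclass
class StrDecision:
    status: Status
    pathogenic_threshold: int
    expanded_reads: int
    mosaic_range: Optional[tuple[int, int]]


def _find_flank(seq: str, flank: str, max_ed: int, leftmost: bool):
    """Best approximate occurrence of ``flank`` in ``seq``.

    Returns (start, end_exclusive) of the match or None.  ``leftmost``
    picks the first of equally good locations, else the last — left flanks
    should match as early as possible, right flanks as late as possible.
    """
    res = edlib.align(flank, seq, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_ed:
        return None
    locs = res["locations"]
    start, end = locs[0] if leftmost else locs[-1]
    return start, end + 1


def _scan_units(tract: str, motif: str) -> tuple[int, list[Interruption]]:
    """Greedy unit-by-unit scan: a unit is the motif with <=1 mismatch,
    anything else of motif length is an interruption."""
    m = len(motif)
    count = 0
    interruptions: list[Interruption] = []
    i = 0
    unit_idx = 0
    while i + m <= len(tract):
        unit = tract[i:i + m]
        mismatches = sum(a != b for a, b in zip(unit, motif))
        if mismatches > 1:
            interruptions.append(Interruption(unit_idx, unit))
        count += 1
        unit_idx += 1
        i += m
    return count, interruptions


def count_repeats_in_read(
    read_sequence: str,
    motif: str,
    left_flank: str,
    right_flank: str,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> Optional[tuple[int, list[Interruption], bool]]:
    """Count tandem repeat units between two flanks in one read.

    Returns ``(repeat_count, interruptions, spanning)`` where
    ``repeat_count`` is the total number of units in the tract (motif
    matches plus interruptions), or ``None`` when neither flank is found
    (no-call for this read).
    """
    if not set(motif) <= set("ACGT") or len(motif) < 2:
        raise ValueError(f"motif must be ACGT of length >= 2, got {motif!r}")
    seq = read_sequence.upper()
    ed_l = int(len(left_flank) * max_mismatch_frac)
    ed_r = int(len(right_flank) * max_mismatch_frac)
    left = _find_flank(seq, left_flank, ed_l, leftmost=True)
    right = _find_flank(seq, right_flank, ed_r, leftmost=False)
    if left is not None and right is not None and right[0] <= left[1]:
        # flanks found out of order (no tract between them): treat the
        # later-scoring one as absent
        right = None
    if left is None and right is None:
        return None
    if left is not None and right is not None:
        tract = seq[left[1]: right[0]]
        count, inter = _scan_units(tract, motif)
        return count, inter, True
    if left is not None:
        tract = seq[left[1]:]
        count, inter = _scan_units(tract, motif)
        return count, inter, False
    # right flank only: scan backwards from the flank start
    tract = seq[: right[0]]
    m = len(motif)
    # align the unit grid to the right flank boundary
    offset = len(tract) % m
    count, inter = _scan_units(tract[offset:], motif)
    return count, inter, False


def _cluster_modes(counts: list[int], gap: int = 6) -> list[tuple[int, int]]:
    """Split sorted counts at the largest gap (> ``gap``) into <= 2 clusters;
    return (median count, support) per cluster, largest support first."""
    if not counts:
        return []
    s = sorted(counts)
    best_gap, split = 0, None
    for i in range(1, len(s)):
        if s[i] - s[i - 1] > best_gap:
            best_gap, split = s[i] - s[i - 1], i
    clusters = [s] if best_gap <= gap or split is None else [s[:split], s[split:]]
    out = []
    for c in clusters:
        out.append((int(c[len(c) // 2]), len(c)))
    return out


def profile_str_locus(
    alignments: Iterable[AlignmentRecord],
    query: VariantQuery,
    reference,
    thresholds: Optional[Thresholds] = None,
    flank_len: int = DEFAULT_FLANK_LEN,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> RepeatProfile:
    """Per-read repeat counts for every read overlapping an STR locus."""
    if query.kind != Kind.STR:
        raise ValueError(f"profile_str_locus got kind {query.kind}")
    thresholds = thresholds or Thresholds()
    loc = query.locus
    left_flank = fetch_ref(reference, loc.chrom, loc.start - flank_len, loc.start)
    right_flank = fetch_ref(reference, loc.chrom, loc.end, loc.end + flank_len)
    if len(left_flank) < 15 or len(right_flank) < 15:
        raise ValueError(f"{query.query_id}: flanks around {loc.to_1based()} "
                         "are too short (need >= 15 bp)")
    # pad the overlap test so reads clipped exactly at the tract boundary
    # (alignments resuming at locus end) still contribute lower bounds
    padded = GenomicInterval(loc.chrom, max(loc.start - flank_len, 0),
                             loc.end + flank_len)
    per_read: list[ReadRepeatCount] = []
    depth = 0
    for rec in alignments:
        if not depth_eligible(rec, thresholds):
            continue
        if not rec.interval.overlaps(padded):
            continue
        depth += 1
        if not rec.sequence:
            continue
        got = count_repeats_in_read(
            rec.sequence, query.motif, left_flank, right_flank,
            max_mismatch_frac,
        )
        if got is None:
            continue
        count, inter, spanning = got
        per_read.append(ReadRepeatCount(rec.read_id, count, spanning, inter))
    max_observed = max((r.repeat_count for r in per_read), default=0)
    spanning_counts = [r.repeat_count for r in per_read if r.spanning]
    return RepeatProfile(
        locus=loc,
        motif=query.motif,
        per_read=per_read,
        max_observed=max_observed,
        allele_summary=_cluster_modes(spanning_counts),
        depth=depth,
    )


def decide_str(
    profile: RepeatProfile,
    query: VariantQuery,
    thresholds: Optional[Thresholds] = None,
) -> tuple[ConfirmationResult, StrDecision]:
    """Pathogenic-threshold decision: confirmed when any per-read count
    (spanning or clipped lower bound) reaches the reportable threshold."""
    thresholds = thresholds or Thresholds()
    thr = query.pathogenic_threshold
    if profile.depth < thresholds.min_genomic_depth:
        res = ConfirmationResult(
            query.query_id, Status.INSUFFICIENT_COVERAGE, profile.depth,
            notes=f"depth {profile.depth} below "
                  f"{thresholds.min_genomic_depth}x floor",
        )
        return res, StrDecision(Status.INSUFFICIENT_COVERAGE, thr, 0, None)
    expanded = [r for r in profile.per_read if r.repeat_count >= thr]
    status = Status.CONFIRMED if expanded else Status.NOT_CONFIRMED
    mosaic = None
    if expanded:
        counts = [r.repeat_count for r in expanded]
        mosaic = (min(counts), max(counts))
    evidence = {
        "motif": profile.motif,
        "pathogenic_threshold": thr,
        "max_observed": profile.max_observed,
        "allele_summary": profile.allele_summary,
        "expanded_reads": len(expanded),
        "mosaic_range": list(mosaic) if mosaic else None,
        "n_counted_reads": len(profile.per_read),
    }
    res = ConfirmationResult(query.query_id, status, profile.depth,
                             evidence=evidence)
    return res, StrDecision(status, thr, len(expanded), mosaic)


def load_str_catalog() -> list[dict]:
    """Bundled catalog of clinically validated STR loci (gene, motif,
    normal reference repeat count, reportable threshold)."""
    text = (
        importlib.resources.files("lrconfirm")
        .joinpath("data/str_catalog.tsv")
        .read_text()
    )
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    return [dict(zip(header, l.split("\t"))) for l in lines[1:]]
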