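"""Top-level dispatch: run every query through its confirmer."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

from .cnv import (
    DEFAULT_WINDOW_SIZE,
    chromosome_ploidy,
    confirm_aneuploidy,
    confirm_cnv,
    copy_track,
)
from .core import (
    AlignmentRecord,
    ConfirmationResult,
    GenomicInterval,
    Kind,
    Status,
    Thresholds,
    VariantQuery,
    read_alignments,
)
from .small import confirm_ssc, heteroplasmy
from .strs import decide_str, profile_str_locus
from .sv import confirm_del_dup_splitread, confirm_insertion, confirm_inversion
from .upd import InformativeLocus, confirm_upd

#: margin added around a query locus when fetching from an indexed file
FETCH_MARGIN = 50_000


def _fetch(
    alignments: Union[str, Sequence[AlignmentRecord]],
    region: Optional[GenomicInterval],
) -> list[AlignmentRecord]:
    if isinstance(alignments, str):
        if region is not None:
            region = GenomicInterval(
                region.chrom, max(region.start - FETCH_MARGIN, 0),
                region.end + FETCH_MARGIN,
            )
        return list(read_alignments(alignments, region))
    if region is None:
        return list(alignments)
    return [r for r in alignments if r.interval.chrom == region.chrom]


def confirm_all(
    alignments: Union[str, Sequence[AlignmentRecord]],
    reference,
    queries: Iterable[VariantQuery],
    thresholds: Optional[Thresholds] = None,
    upd_loci: Optional[Mapping[str, Sequence[InformativeLocus]]] = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[ConfirmationResult]:
    """Confirm every query, computing the genome-wide copy track and
    ploidy table once if any query needs them.

    UPD queries need informative loci (from parental genotypes) supplied
    via ``upd_loci`` keyed by query_id; without them the query is reported
    as not evaluable.
    """
    thresholds = thresholds or Thresholds()
    queries = list(queries)
    upd_loci = upd_loci or {}
    track = None
    ploidy_tab = None
    if any(q.kind in (Kind.CNV, Kind.UPD) for q in queries):
        track = copy_track(_fetch(alignments, None), reference,
                           window_size, thresholds)
    if any(q.kind == Kind.ANEUPLOIDY for q in queries):
        ploidy_tab = chromosome_ploidy(_fetch(alignments, None),
                                       reference, thresholds)
    results = []
    for q in queries:
        if q.kind == Kind.SSC:
            recs = _fetch(alignments, q.locus)
            results.append(confirm_ssc(q, recs, reference, thresholds))
        elif q.kind == Kind.MITO_SSC:
            recs = _fetch(alignments, q.locus)
            results.append(heteroplasmy(q, recs, reference, thresholds)[0])
        elif q.kind == Kind.STR:
            recs = _fetch(alignments, q.locus)
            profile = profile_str_locus(recs, q, reference, thresholds)
            results.append(decide_str(profile, q, thresholds)[0])
        elif q.kind == Kind.SV_INS:
            recs = _fetch(alignments, q.locus)
            results.append(confirm_insertion(q, recs, thresholds))
        elif q.kind == Kind.SV_INV:
            recs = _fetch(alignments, q.locus)
            results.append(confirm_inversion(q, recs, thresholds))
        elif q.kind in (Kind.SV_DEL, Kind.SV_DUP):
            recs = _fetch(alignments, q.locus)
            results.append(confirm_del_dup_splitread(q, recs, thresholds))
        elif q.kind == Kind.CNV:
            results.append(confirm_cnv(q, track, thresholds))
        elif q.kind == Kind.ANEUPLOIDY:
            results.append(confirm_aneuploidy(q, ploidy_tab, thresholds))
        elif q.kind == Kind.UPD:
            loci = upd_loci.get(q.query_id)
            if not loci:
                results.append(ConfirmationResult(
                    q.query_id, Status.INSUFFICIENT_COVERAGE, 0,
                    notes="no informative parental loci supplied; UPD needs "
                          "trio genotypes",
                ))
            else:
                recs = _fetch(alignments, q.locus)
                results.append(confirm_upd(q, recs, loci, thresholds,
                                           track, reference))
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unhandled kind {q.kind}")
    return results
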