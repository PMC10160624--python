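"""Uniparental disomy confirmation via informative parental loci.

An informative locus for a suspected UPD region is one where the
non-transmitting parent is homozygous alternate and the UPD-source parent
is homozygous reference.  Under biparental inheritance the proband is
heterozygous at every such locus; under UPD of the source parent (either
isodisomy or heterodisomy) the proband reads reference-only.  At least 20
loci, spread across the region, are tested; depth over the region must
also be compatible with two copies, ruling out a deletion masquerading as
reference-only observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .core import (
    AlignmentRecord,
    ConfirmationResult,
    GenomicInterval,
    Kind,
    Status,
    Thresholds,
    VariantQuery,
)
from .cnv import CopyTrack
from .evidence import allele_pileup

MIN_INFORMATIVE_LOCI = 20
#: historical minimum used by traditional confirmatory assays
HISTORICAL_MINIMUM = 2

GT_REF_HOM = "ref_hom"
GT_HET = "het"
GT_ALT_HOM = "alt_hom"
GT_MISSING = "missing"


@dataclass
class TrioSite:
    """One biallelic site with parental genotypes."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    father: str  # ref_hom | het | alt_hom | missing
    mother: str


@dataclass
class InformativeLocus:
    position: GenomicInterval
    allele_from_absent_parent: str
    father_genotype: str
    mother_genotype: str
    proband_observation: str = "no_call"  # ref_only | alt_seen | no_call
    proband_depth: int = 0
    alt_reads: int = 0


class InsufficientLociError(ValueError):
    def __init__(self, available: int, needed: int):
        super().__init__(
            f"only {available} informative loci available, need {needed} "
            f"(historical minimum was {HISTORICAL_MINIMUM})"
        )
        self.available = available
        self.needed = needed


def _classify_gt(allele_indices) -> str:
    if allele_indices is None or any(a is None for a in allele_indices):
        return GT_MISSING
    s = set(allele_indices)
    if s == {0}:
        return GT_REF_HOM
    if 0 in s:
        return GT_HET
    return GT_ALT_HOM


def read_trio_vcf(path: str, father_sample: str, mother_sample: str) -> list[TrioSite]:
    """Load biallelic SNV sites with parental genotypes from a VCF."""
    sites = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if not rec.alts or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            f = _classify_gt(rec.samples[father_sample].get("GT"))
            m = _classify_gt(rec.samples[mother_sample].get("GT"))
            sites.append(TrioSite(rec.chrom, rec.pos - 1, rec.ref.upper(),
                                  str(rec.alts[0]).upper(), f, m))
    return sites


def select_informative_loci(
    parental_genotypes: Sequence[TrioSite],
    region: GenomicInterval,
    source_parent: str,
    n_target: int = MIN_INFORMATIVE_LOCI,
    seed: int = 0,
) -> list[InformativeLocus]:
    """Pick ``n_target`` informative loci spread across the UPD region.

    ``source_parent`` ("mother" or "father") is the parent suspected of
    contributing both copies; informative loci are homozygous-alternate in
    the other parent and homozygous-reference in the source parent.  The
    region is split into ``n_target`` equal bins, one locus drawn per
    populated bin (seeded), then topped up from the remaining candidates.
    """
    if n_target < MIN_INFORMATIVE_LOCI:
        raise ValueError(f"n_target must be >= {MIN_INFORMATIVE_LOCI}")
    if source_parent not in ("mother", "father"):
        raise ValueError("source_parent must be 'mother' or 'father'")
    candidates = []
    for s in parental_genotypes:
        if s.chrom != region.chrom or not (region.start <= s.pos < region.end):
            continue
        if source_parent == "mother":
            informative = s.mother == GT_REF_HOM and s.father == GT_ALT_HOM
        else:
            informative = s.father == GT_REF_HOM and s.mother == GT_ALT_HOM
        if informative:
            candidates.append(s)
    if len(candidates) < n_target:
        raise InsufficientLociError(len(candidates), n_target)
    rng = np.random.default_rng(seed)
    bin_width = max(len(region) // n_target, 1)
    bins: dict[int, list[TrioSite]] = {}
    for s in candidates:
        bins.setdefault((s.pos - region.start) // bin_width, []).append(s)
    chosen: list[TrioSite] = []
    for b in sorted(bins):
        group = bins[b]
        chosen.append(group[rng.integers(len(group))])
    if len(chosen) > n_target:
        chosen = chosen[:n_target]
    elif len(chosen) < n_target:
        leftovers = [s for s in candidates if s not in chosen]
        idx = rng.permutation(len(leftovers))[: n_target - len(chosen)]
        chosen.extend(leftovers[i] for i in sorted(idx))
    chosen.sort(key=lambda s: s.pos)
    return [
        InformativeLocus(
            position=GenomicInterval(s.chrom, s.pos, s.pos + 1),
            allele_from_absent_parent=s.alt,
            father_genotype=s.father,
            mother_genotype=s.mother,
        )
        for s in chosen
    ]


def confirm_upd(
    query: VariantQuery,
    alignments: Iterable[AlignmentRecord],
    loci: Sequence[InformativeLocus],
    thresholds: Optional[Thresholds],
    copy_track: Optional[CopyTrack],
    reference,
) -> ConfirmationResult:
    """UPD decision over the informative loci plus a deletion rule-out.

    Confirmed when every evaluable locus reads reference-only AND the
    regional normalized copy is within tolerance of 1.0.  A locus counts
    as alt_seen only when alt reads reach both an absolute floor (2) and
    10% of its depth, so single ONT errors cannot overturn the call.
    """
    if query.kind != Kind.UPD:
        raise ValueError(f"confirm_upd got kind {query.kind}")
    if len(loci) < MIN_INFORMATIVE_LOCI:
        raise InsufficientLociError(len(loci), MIN_INFORMATIVE_LOCI)
    thresholds = thresholds or Thresholds()
    region = query.locus
    for loc in loci:
        if not region.overlaps(loc.position):
            raise ValueError(
                f"locus {loc.position.to_1based()} outside query region "
                f"{region.to_1based()}"
            )
    recs = list(alignments)
    alt_seen = ref_only = low_depth = 0
    per_locus = []
    for loc in loci:
        ref_base = str(reference[loc.position.chrom][loc.position.start]).upper()
        sub = VariantQuery(
            query_id=f"{query.query_id}@{loc.position.to_1based()}",
            kind=Kind.SSC,
            locus=loc.position,
            ref_allele=ref_base,
            alt_allele=loc.allele_from_absent_parent,
        )
        counts = allele_pileup(recs, sub, reference, thresholds)
        loc.proband_depth = counts.depth
        loc.alt_reads = counts.alt_count
        if counts.depth < thresholds.min_genomic_depth:
            loc.proband_observation = "no_call"
            low_depth += 1
        elif counts.alt_count >= 2 and counts.alt_count >= 0.10 * counts.depth:
            loc.proband_observation = "alt_seen"
            alt_seen += 1
        else:
            loc.proband_observation = "ref_only"
            ref_only += 1
        per_locus.append({
            "position": loc.position.to_1based(),
            "observation": loc.proband_observation,
            "depth": loc.proband_depth,
            "alt_reads": loc.alt_reads,
        })
    median_depth = int(np.median([l.proband_depth for l in loci]))
    if low_depth > 0.20 * len(loci):
        return ConfirmationResult(
            query.query_id, Status.INSUFFICIENT_COVERAGE, median_depth,
            notes=f"{low_depth}/{len(loci)} informative loci below "
                  f"{thresholds.min_genomic_depth}x",
        )
    copy_ok = None
    mean_copy = None
    if copy_track is not None:
        mean_copy = copy_track.region_mean(region)
        copy_ok = abs(mean_copy - 1.0) <= thresholds.cnv_copy_tolerance
    notes = ""
    if alt_seen > 0:
        status = Status.NOT_CONFIRMED
        notes = f"{alt_seen} loci show the absent parent's allele"
    elif copy_ok is False:
        status = Status.NOT_CONFIRMED
        notes = (f"regional copy {mean_copy:.2f} incompatible with two "
                 "copies; deletion not ruled out")
    else:
        status = Status.CONFIRMED
    return ConfirmationResult(
        query.query_id, status, median_depth,
        evidence={
            "n_loci": len(loci),
            "ref_only": ref_only,
            "alt_seen": alt_seen,
            "no_call": low_depth,
            "regional_normalized_copy": (round(mean_copy, 4)
                                         if mean_copy is not None else None),
            "loci": per_locus,
        },
        notes=notes,
    )
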