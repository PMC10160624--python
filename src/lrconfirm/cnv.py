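"""Depth-normalized copy-number track and whole-chromosome ploidy.

Raw windowed depth is divided by the median over autosomal windows, so a
normalized copy of 1.0 corresponds to the diploid state, ~0.5 to a
heterozygous deletion and ~1.5 to a heterozygous duplication.  Chromosome
ploidy is the per-chromosome per-base coverage over the autosomal median,
times two.  The median normalizer makes both outputs invariant under any
uniform rescaling of sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import (
    AlignmentRecord,
    ConfirmationResult,
    GenomicInterval,
    Kind,
    Status,
    Thresholds,
    VariantQuery,
    chrom_lengths,
    is_autosome,
    is_mito,
)
from .evidence import depth_eligible

DEFAULT_WINDOW_SIZE = 100_000
#: depth-only evidence is reliable for events at least this long
MIN_CONFIDENT_CNV_SIZE = 300_000


@dataclass
class CopyTrack:
    """Windowed normalized copy counts (diploid = 1.0)."""

    windows: pd.DataFrame  # chrom, start, end, raw_depth, normalized_copy
    window_size: int

    def region_mean(self, region: GenomicInterval) -> float:
        df = self.windows
        sel = df[(df.chrom == region.chrom)
                 & (df.start < region.end) & (df.end > region.start)]
        if sel.empty:
            raise ValueError(f"region {region.to_1based()} not covered by track")
        return float(sel.normalized_copy.mean())

    def region_windows(self, region: GenomicInterval) -> int:
        df = self.windows
        return int(((df.chrom == region.chrom)
                    & (df.start < region.end) & (df.end > region.start)).sum())

    def to_tsv(self, path: str) -> None:
        self.windows[["chrom", "start", "end", "normalized_copy"]].to_csv(
            path, sep="\t", index=False, float_format="%.4f"
        )


@dataclass
class PloidyTable:
    rows: pd.DataFrame  # chromosome, predicted_ploidy, normalized_ploidy, read_coverage

    def ploidy_of(self, chrom: str) -> float:
        sel = self.rows[self.rows.chromosome == chrom]
        if sel.empty:
            raise KeyError(f"chromosome {chrom!r} absent from ploidy table")
        return float(sel.normalized_ploidy.iloc[0])

    def to_tsv(self, path: str) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.2f")


def _windowed_raw_depth(
    alignments: Iterable[AlignmentRecord],
    lengths: dict[str, int],
    window_size: int,
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Mean per-base depth per fixed window, from aligned spans of
    depth-eligible reads (partial windows at contig ends are normalised by
    their true width)."""
    covered: dict[str, np.ndarray] = {
        c: np.zeros(int(np.ceil(L / window_size)), dtype=np.float64)
        for c, L in lengths.items()
    }
    for rec in alignments:
        if not depth_eligible(rec, thresholds):
            continue
        arr = covered.get(rec.interval.chrom)
        if arr is None:
            continue
        a, b = rec.interval.start, rec.interval.end
        w0, w1 = a // window_size, (b - 1) // window_size
        if w0 == w1:
            arr[w0] += b - a
        else:
            arr[w0] += (w0 + 1) * window_size - a
            arr[w1] += b - w1 * window_size
            if w1 > w0 + 1:
                arr[w0 + 1: w1] += window_size
    rows = []
    for chrom, L in lengths.items():
        arr = covered[chrom]
        for i, bases in enumerate(arr):
            start = i * window_size
            end = min(start + window_size, L)
            rows.append((chrom, start, end, bases / (end - start)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "raw_depth"])


def copy_track(
    alignments: Iterable[AlignmentRecord],
    reference,
    window_size: int = DEFAULT_WINDOW_SIZE,
    thresholds: Optional[Thresholds] = None,
) -> CopyTrack:
    """Normalized copy-count track: windowed depth over the autosomal
    median, scaled so the diploid state is 1.0."""
    if window_size < 1000:
        raise ValueError("window_size must be >= 1 kb")
    thresholds = thresholds or Thresholds()
    lengths = chrom_lengths(reference)
    df = _windowed_raw_depth(alignments, lengths, window_size, thresholds)
    auto = df[df.chrom.map(is_autosome) & (df.raw_depth > 0)]
    if auto.empty:
        raise ValueError("no autosomal coverage; cannot normalize")
    norm = float(auto.raw_depth.median())
    df = df.assign(normalized_copy=df.raw_depth / norm)
    return CopyTrack(df, window_size)


def confirm_cnv(
    query: VariantQuery,
    track: CopyTrack,
    thresholds: Optional[Thresholds] = None,
) -> ConfirmationResult:
    """Copy-number decision: the mean normalized copy over the queried
    region must sit within tolerance of expected_copy/2."""
    if query.kind != Kind.CNV:
        raise ValueError(f"confirm_cnv got kind {query.kind}")
    if query.expected_copy < 0:
        raise ValueError(f"{query.query_id}: expected_copy must be set")
    thresholds = thresholds or Thresholds()
    region = query.locus
    n_windows = track.region_windows(region)
    if n_windows < 3:
        raise ValueError(
            f"{query.query_id}: region covered by {n_windows} windows; "
            "need >= 3 (shrink the window size or widen the region)"
        )
    mean_copy = track.region_mean(region)
    expected = query.expected_copy / 2.0
    tol = thresholds.cnv_copy_tolerance
    notes = ""
    if len(region) < MIN_CONFIDENT_CNV_SIZE:
        notes = (f"event shorter than {MIN_CONFIDENT_CNV_SIZE} bp: depth-only "
                 "evidence is low-confidence")
    if abs(mean_copy - expected) <= tol:
        status = Status.CONFIRMED
    elif abs(mean_copy - 1.0) <= tol:
        status = Status.NOT_CONFIRMED
    else:
        status = Status.NOT_CONFIRMED
        notes = (notes + "; " if notes else "") + (
            f"observed copy {mean_copy:.2f} discordant with both expected "
            f"{expected:.2f} and diploid 1.0"
        )
    df = track.windows
    sel = df[(df.chrom == region.chrom)
             & (df.start < region.end) & (df.end > region.start)]
    raw_depth = int(round(float(sel.raw_depth.mean())))
    return ConfirmationResult(
        query.query_id, status, raw_depth,
        evidence={
            "mean_normalized_copy": round(mean_copy, 4),
            "expected_normalized_copy": expected,
            "n_windows": n_windows,
        },
        notes=notes,
    )


def chromosome_ploidy(
    alignments: Iterable[AlignmentRecord],
    reference,
    thresholds: Optional[Thresholds] = None,
) -> PloidyTable:
    """Per-chromosome normalized ploidy from read coverage distribution.

    Coverage is aligned bases per chromosome base; normalized ploidy is
    coverage over the autosomal median, times 2 (so a normal autosome
    reads ~2.0).  Mitochondrial contigs are excluded.
    """
    thresholds = thresholds or Thresholds()
    lengths = chrom_lengths(reference)
    for chrom, L in lengths.items():
        if L == 0:
            raise ValueError(f"chromosome {chrom!r} has zero length")
    bases: dict[str, int] = {c: 0 for c in lengths}
    for rec in alignments:
        if not depth_eligible(rec, thresholds):
            continue
        if rec.interval.chrom in bases:
            bases[rec.interval.chrom] += len(rec.interval)
    coverage = {c: bases[c] / lengths[c] for c in lengths if not is_mito(c)}
    auto_cov = [v for c, v in coverage.items() if is_autosome(c)]
    if not auto_cov or np.median(auto_cov) == 0:
        raise ValueError("no autosomal coverage; cannot normalize ploidy")
    norm = float(np.median(auto_cov))
    rows = []
    for chrom, cov in coverage.items():
        np_ = 2.0 * cov / norm
        rows.append((chrom, int(round(np_)), np_, cov))
    return PloidyTable(pd.DataFrame(
        rows, columns=["chromosome", "predicted_ploidy",
                       "normalized_ploidy", "read_coverage"]
    ))


def confirm_aneuploidy(
    query: VariantQuery,
    ploidy_table: PloidyTable,
    thresholds: Optional[Thresholds] = None,
) -> ConfirmationResult:
    """Whole-chromosome copy decision; the query may name several
    chromosomes (comma-separated) sharing one expected copy count, e.g.
    chrX,chrY at 2 for an XXYY karyotype."""
    if query.kind != Kind.ANEUPLOIDY:
        raise ValueError(f"confirm_aneuploidy got kind {query.kind}")
    if query.expected_copy < 0:
        raise ValueError(f"{query.query_id}: expected_copy must be set")
    thresholds = thresholds or Thresholds()
    chroms_text = query.ref_allele or query.locus.chrom
    chroms = [c.strip() for c in chroms_text.split(",") if c.strip()]
    tol = thresholds.aneuploidy_copy_tolerance
    observed = {}
    ok = True
    for chrom in chroms:
        np_ = ploidy_table.ploidy_of(chrom)  # raises KeyError if absent
        observed[chrom] = round(np_, 3)
        if abs(np_ - query.expected_copy) > tol:
            ok = False
    status = Status.CONFIRMED if ok else Status.NOT_CONFIRMED
    return ConfirmationResult(
        query.query_id, status, 0,
        evidence={
            "expected_copy": query.expected_copy,
            "normalized_ploidy": observed,
        },
    )
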