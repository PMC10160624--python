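"""Domain types and I/O backbone for long-read orthogonal variant confirmation.

Internally every coordinate is 0-based, half-open.  User-facing text (VCF,
sidecar TSV, reports) follows the VCF convention of 1-based inclusive
positions; conversion happens at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

logger = logging.getLogger("lrconfirm")

SCHEMA_VERSION = "1"

#: contig names treated as mitochondrial
MITO_NAMES = {"chrM", "MT", "chrMT", "M"}
#: contig names (chr-prefix stripped) excluded from the autosomal normalizer
NON_AUTOSOMES = {"X", "Y", "M", "MT"}


def is_mito(chrom: str) -> bool:
    return chrom in MITO_NAMES


def is_autosome(chrom: str) -> bool:
    name = chrom[3:] if chrom.startswith("chr") else chrom
    return name not in NON_AUTOSOMES


class Kind(str, Enum):
    """Variant classes the confirmation system understands."""

    SSC = "SSC"
    MITO_SSC = "MITO_SSC"
    STR = "STR"
    SV_DEL = "SV_DEL"
    SV_DUP = "SV_DUP"
    SV_INS = "SV_INS"
    SV_INV = "SV_INV"
    CNV = "CNV"
    ANEUPLOIDY = "ANEUPLOIDY"
    UPD = "UPD"


class Status(str, Enum):
    CONFIRMED = "confirmed"
    NOT_CONFIRMED = "not_confirmed"
    INSUFFICIENT_COVERAGE = "insufficient_coverage"


class Role(str, Enum):
    PRIMARY = "primary"
    SUPPLEMENTARY = "supplementary"
    SECONDARY = "secondary"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_1based(self) -> str:
        """Display form: 1-based inclusive, VCF style."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @staticmethod
    def from_1based(chrom: str, start_1: int, end_1: int) -> "GenomicInterval":
        return GenomicInterval(chrom, start_1 - 1, end_1)


# CIGAR operations are (op, length) with op in "MIDSH":
# M aligned (match or mismatch), I insertion, D deletion,
# S soft clip, H hard clip.
Cigar = Sequence[tuple[str, int]]

_QUERY_OPS = set("MIS")
_REF_OPS = set("MD")


@dataclass
class AlignmentRecord:
    """One aligned segment of one long read (SAM record equivalent)."""

    read_id: str
    interval: GenomicInterval
    strand: str
    cigar: list[tuple[str, int]]
    mapq: int
    role: Role = Role.PRIMARY
    sequence: str = ""
    mean_quality: float = 0.0

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    def validate(self) -> None:
        if self.sequence and self.query_length() != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: query-consuming CIGAR length "
                f"{self.query_length()} != sequence length {len(self.sequence)}"
            )
        if self.reference_length() != len(self.interval):
            raise ValueError(
                f"{self.read_id}: reference-consuming CIGAR length "
                f"{self.reference_length()} != span {len(self.interval)}"
            )

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] in "SH" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] in "SH" else 0


@dataclass
class VariantQuery:
    """A typed candidate variant to confirm against the alignments."""

    query_id: str
    kind: Kind
    locus: GenomicInterval
    ref_allele: str = ""
    alt_allele: str = ""
    motif: str = ""
    pathogenic_threshold: int = 0
    expected_length: int = 0
    breakpoints: Optional[tuple[GenomicInterval, GenomicInterval]] = None
    expected_copy: int = -1
    parental_vcf: str = ""

    def __post_init__(self) -> None:
        if self.kind == Kind.STR:
            if not self.motif or self.pathogenic_threshold <= 0:
                raise ValueError(
                    f"{self.query_id}: STR query needs motif and positive "
                    "pathogenic_threshold"
                )


@dataclass
class Thresholds:
    """Decision thresholds for all confirmers.

    Depth floors are 12x genomic / 1000x mitochondrial.  The remaining
    knobs operationalise evidence sufficiency (support reads, support
    fraction, breakpoint window, minimum informative clip length) and are
    deliberately configurable.
    """

    min_genomic_depth: int = 12
    min_mito_depth: int = 1000
    min_support_reads: int = 3
    min_support_fraction: float = 0.2
    breakpoint_window: int = 500
    min_clip_len: int = 200
    min_mapq: int = 1  # mapq 0 (multimappers) excluded from depth/evidence
    indel_len_tolerance: float = 0.30  # relative tolerance for SV/insertion sizes
    phase_noise_fraction: float = 0.10
    cnv_copy_tolerance: float = 0.2
    aneuploidy_copy_tolerance: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_support_fraction <= 1.0):
            raise ValueError("min_support_fraction must be in [0,1]")
        for name in ("min_genomic_depth", "min_mito_depth", "min_support_reads",
                     "breakpoint_window", "min_clip_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def min_depth_for(self, kind: Kind) -> int:
        return self.min_mito_depth if kind == Kind.MITO_SSC else self.min_genomic_depth


@dataclass
class ConfirmationResult:
    """Verdict for one query plus its quantitative evidence summary."""

    query_id: str
    status: Status
    depth: int
    evidence: dict = field(default_factory=dict)
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "status": self.status.value,
            "depth": self.depth,
            "evidence": self.evidence,
            "notes": self.notes,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "ConfirmationResult":
        return ConfirmationResult(
            query_id=d["query_id"],
            status=Status(d["status"]),
            depth=int(d["depth"]),
            evidence=dict(d.get("evidence") or {}),
            notes=d.get("notes", ""),
        )


# ---------------------------------------------------------------------------
# Reference access helpers (accept a pyfaidx.Fasta or a plain dict of strings)

def fetch_ref(reference, chrom: str, start: int, end: int) -> str:
    """Reference slice [start, end), uppercased; errors name the contig."""
    try:
        seq = reference[chrom]
    except KeyError:
        raise KeyError(f"contig {chrom!r} absent from reference") from None
    start = max(start, 0)
    return str(seq[start:end]).upper()


def chrom_lengths(reference) -> dict[str, int]:
    if hasattr(reference, "faidx"):  # pyfaidx.Fasta
        return {name: len(reference[name]) for name in reference.keys()}
    return {name: len(seq) for name, seq in reference.items()}


# ---------------------------------------------------------------------------
# Alignment I/O

_PYSAM_OPS = "MIDNSHP=XB"
_OP_MAP = {"M": "M", "=": "M", "X": "M", "I": "I", "D": "D", "N": "D",
           "S": "S", "H": "H"}


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = []
    for code, length in seg.cigartuples or []:
        op = _OP_MAP.get(_PYSAM_OPS[code])
        if op is None:
            raise ValueError(
                f"malformed record {seg.query_name}: unsupported CIGAR op "
                f"{_PYSAM_OPS[code]}"
            )
        cigar.append((op, length))
    if seg.is_secondary:
        role = Role.SECONDARY
    elif seg.is_supplementary:
        role = Role.SUPPLEMENTARY
    else:
        role = Role.PRIMARY
    quals = seg.query_qualities
    meanq = float(sum(quals)) / len(quals) if quals else 0.0
    return AlignmentRecord(
        read_id=seg.query_name,
        interval=GenomicInterval(
            seg.reference_name, seg.reference_start, seg.reference_end
        ),
        strand="-" if seg.is_reverse else "+",
        cigar=cigar,
        mapq=seg.mapping_quality,
        role=role,
        sequence=seg.query_sequence or "",
        mean_quality=meanq,
    )


def read_alignments(
    path: str, region: Optional[GenomicInterval] = None
) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a coordinate-sorted SAM/BAM file.

    With ``region`` set, yields every record overlapping it (requires an
    index for BAM; raises if random access is impossible).
    """
    with pysam.AlignmentFile(path, "r") as af:
        if region is None:
            it = af.fetch(until_eof=True)
        else:
            try:
                it = af.fetch(region.chrom, region.start, region.end)
            except ValueError as exc:
                raise ValueError(
                    f"region query on {path} requires an index: {exc}"
                ) from exc
        for seg in it:
            if seg.is_unmapped:
                continue
            yield _from_pysam(seg)


def write_alignments(
    records: Iterable[AlignmentRecord],
    lengths: Mapping[str, int],
    path: str,
    index: bool = True,
) -> None:
    """Write records as coordinate-sorted SAM/BAM (extension decides); BAM
    output is indexed so region queries work."""
    names = list(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(lengths[n])} for n in names],
    }
    order = {n: i for i, n in enumerate(names)}
    recs = sorted(records, key=lambda r: (order[r.interval.chrom], r.interval.start))
    mode = "wb" if path.endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in recs:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.reference_name = r.interval.chrom
            seg.reference_start = r.interval.start
            seg.mapping_quality = r.mapq
            flag = 0
            if r.strand == "-":
                flag |= 16
            if r.role == Role.SUPPLEMENTARY:
                flag |= 2048
            elif r.role == Role.SECONDARY:
                flag |= 256
            seg.flag = flag
            seg.cigartuples = [
                (_PYSAM_OPS.index(op), n) for op, n in r.cigar
            ]
            seg.query_sequence = r.sequence or None
            if r.sequence:
                q = min(93, max(0, round(r.mean_quality)))
                seg.query_qualities = pysam.qualitystring_to_array(
                    chr(q + 33) * len(r.sequence)
                )
            out.write(seg)
    if index and mode == "wb":
        pysam.index(path)


# ---------------------------------------------------------------------------
# Query parsing

@dataclass
class RejectedRow:
    row: str
    reason: str


@dataclass
class QuerySet:
    """Total parse result: every input row lands in one of the two lists."""

    queries: list[VariantQuery]
    rejected: list[RejectedRow]


_SVTYPE_TO_KIND = {
    "DEL": Kind.SV_DEL,
    "DUP": Kind.SV_DUP,
    "INS": Kind.SV_INS,
    "INV": Kind.SV_INV,
}

SIDECAR_COLUMNS = [
    "query_id", "kind", "chrom", "start_1based", "end_1based", "motif",
    "pathogenic_threshold", "expected_copy", "expected_length", "parental_vcf",
]


def _parse_vcf_record(rec, counter: int) -> VariantQuery:
    qid = rec.id or f"vcf_{counter}"
    chrom = rec.chrom
    pos0 = rec.pos - 1  # pysam .pos is 1-based
    alts = rec.alts or ()
    svtype = rec.info.get("SVTYPE") if "SVTYPE" in rec.info else None
    if svtype:
        if isinstance(svtype, tuple):
            svtype = svtype[0]
        kind = _SVTYPE_TO_KIND.get(str(svtype))
        if kind is None:
            raise ValueError(f"unknown SVTYPE {svtype!r}")
        end0 = int(rec.stop)  # pysam .stop is 0-based half-open end
        svlen = rec.info.get("SVLEN", 0)
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        q = VariantQuery(
            query_id=qid,
            kind=kind,
            locus=GenomicInterval(chrom, pos0, max(end0, pos0 + 1)),
            expected_length=abs(int(svlen)) if svlen else max(end0 - pos0, 0),
        )
        if kind in (Kind.SV_DEL, Kind.SV_DUP, Kind.SV_INV):
            q.breakpoints = (
                GenomicInterval(chrom, pos0, pos0 + 1),
                GenomicInterval(chrom, max(end0 - 1, pos0), max(end0, pos0 + 1)),
            )
        return q
    if not alts:
        raise ValueError("no ALT allele")
    ref = rec.ref.upper()
    alt = str(alts[0]).upper()
    if not set(ref) <= set("ACGT") or not set(alt) <= set("ACGT"):
        raise ValueError(f"non-ACGT allele {ref}>{alt}")
    kind = Kind.MITO_SSC if is_mito(chrom) else Kind.SSC
    return VariantQuery(
        query_id=qid,
        kind=kind,
        locus=GenomicInterval(chrom, pos0, pos0 + len(ref)),
        ref_allele=ref,
        alt_allele=alt,
    )


def _parse_sidecar_row(row: Mapping[str, str], counter: int) -> VariantQuery:
    kind_text = (row.get("kind") or "").strip().upper()
    try:
        kind = Kind(kind_text)
    except ValueError:
        raise ValueError(f"unknown kind {kind_text!r}") from None
    if kind not in (Kind.STR, Kind.CNV, Kind.ANEUPLOIDY, Kind.UPD):
        raise ValueError(f"kind {kind_text} belongs in the VCF, not the sidecar")
    chrom = (row.get("chrom") or "").strip()
    if not chrom:
        raise ValueError("missing chrom")
    start_1 = int(row.get("start_1based") or 0)
    end_1 = int(row.get("end_1based") or 0)
    if start_1 < 1 or end_1 < start_1:
        raise ValueError(f"bad coordinates {start_1}-{end_1}")
    qid = (row.get("query_id") or "").strip() or f"sidecar_{counter}"
    locus = GenomicInterval.from_1based(chrom.split(",")[0], start_1, end_1)
    if kind == Kind.STR:
        motif = (row.get("motif") or "").strip().upper()
        thr = int(row.get("pathogenic_threshold") or 0)
        if not motif or thr <= 0:
            raise ValueError("STR row missing motif or pathogenic_threshold")
        return VariantQuery(qid, kind, locus, motif=motif, pathogenic_threshold=thr)
    if kind in (Kind.CNV, Kind.ANEUPLOIDY):
        copy_text = (row.get("expected_copy") or "").strip()
        if copy_text == "":
            raise ValueError(f"{kind.value} row missing expected_copy")
        q = VariantQuery(qid, kind, locus, expected_copy=int(copy_text))
        q.motif = ""  # unused
        # ANEUPLOIDY may list several chromosomes, comma separated
        if kind == Kind.ANEUPLOIDY:
            q.parental_vcf = ""
            q.ref_allele = chrom  # keep full (possibly comma-joined) list
        return q
    # UPD
    return VariantQuery(
        qid, kind, locus, parental_vcf=(row.get("parental_vcf") or "").strip()
    )


def read_queries(vcf_path: Optional[str], sidecar_path: Optional[str] = None) -> QuerySet:
    """Parse candidate variants from a VCF plus optional sidecar TSV.

    Parsing is total: every row becomes either a :class:`VariantQuery` or a
    :class:`RejectedRow` with a reason.
    """
    queries: list[VariantQuery] = []
    rejected: list[RejectedRow] = []
    counter = 0
    if vcf_path:
        with pysam.VariantFile(vcf_path) as vf:
            for rec in vf:
                counter += 1
                try:
                    queries.append(_parse_vcf_record(rec, counter))
                except (ValueError, KeyError) as exc:
                    rejected.append(
                        RejectedRow(f"{rec.chrom}:{rec.pos}", str(exc))
                    )
    if sidecar_path:
        with open(sidecar_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                counter += 1
                try:
                    queries.append(_parse_sidecar_row(row, counter))
                except (ValueError, KeyError) as exc:
                    rejected.append(RejectedRow(json.dumps(row), str(exc)))
    return QuerySet(queries, rejected)


# ---------------------------------------------------------------------------
# Report emission

_REPORT_COLUMNS = ["schema_version", "query_id", "status", "depth", "evidence", "notes"]


def write_report(results: Sequence[ConfirmationResult], path: str,
                 format: str = "tsv") -> None:
    """Write confirmation results as TSV or JSON (schema-version stamped)."""
    if format == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "results": [r.to_dict() for r in results],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_REPORT_COLUMNS)
            for r in results:
                w.writerow([
                    SCHEMA_VERSION, r.query_id, r.status.value, r.depth,
                    json.dumps(r.evidence, sort_keys=True), r.notes,
                ])
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str, format: str = "tsv") -> list[ConfirmationResult]:
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return [ConfirmationResult.from_dict(d) for d in payload["results"]]
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(ConfirmationResult(
                query_id=row["query_id"],
                status=Status(row["status"]),
                depth=int(row["depth"]),
                evidence=json.loads(row["evidence"]),
                notes=row["notes"],
            ))
    return out
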