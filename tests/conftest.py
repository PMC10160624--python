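"""Shared fixtures and hand-built alignment helpers."""

from __future__ import annotations

import numpy as np
import pytest

from lrconfirm.core import AlignmentRecord, GenomicInterval, Role


def make_read(
    read_id: str,
    chrom: str,
    start: int,
    sequence: str,
    cigar=None,
    strand: str = "+",
    role: Role = Role.PRIMARY,
    mapq: int = 60,
    mean_quality: float = 20.0,
) -> AlignmentRecord:
    """Build a record from a sequence and (default fully matched) CIGAR."""
    cigar = list(cigar) if cigar else [("M", len(sequence))]
    ref_len = sum(n for op, n in cigar if op in "MD")
    rec = AlignmentRecord(
        read_id=read_id,
        interval=GenomicInterval(chrom, start, start + ref_len),
        strand=strand,
        cigar=cigar,
        mapq=mapq,
        role=role,
        sequence=sequence,
        mean_quality=mean_quality,
    )
    rec.validate()
    return rec


def matched_reads(refseq: str, chrom: str, n: int, start: int, length: int,
                  prefix: str = "r") -> list[AlignmentRecord]:
    """n identical reference-matching reads over [start, start+length)."""
    return [
        make_read(f"{prefix}{i}", chrom, start, refseq[start:start + length])
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def random_ref():
    """600 bp random reference on one nuclear and one mito contig."""
    rng = np.random.default_rng(20230421)
    bases = np.array(list("ACGT"))
    return {
        "chr1": "".join(bases[rng.integers(0, 4, 600)]),
        "chrM": "".join(bases[rng.integers(0, 4, 600)]),
    }
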