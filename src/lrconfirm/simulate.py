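"""Synthetic long-read generator for desk-scale testing.

Emulates low-pass ONT-style whole-genome sequencing: ~10 kb reads (long-
tailed log-normal length distribution truncated at 500 bp), ~12x genomic
and >=1000x mitochondrial depth, and indel-rich errors tuned so mean read
accuracy is about Q16, with indels enriched in homopolymers.

Every supported variant class can be spiked into haplotypes: SNVs and
small indels, STR expansions (with interrupting units and mosaic length
mixes), deletions, tandem duplications, insertions, inversions, whole-
chromosome copy changes, and trio genotype layouts for UPD scenarios.

Alignments are generated directly from the known haplotype-to-reference
projection (no external aligner): each haplotype base carries its
reference position (-1 for inserted bases) and strand, a read is a slice
of that projection, and CIGAR operations, clips, and primary/supplementary
split segments at SV junctions all fall out of one uniform derivation.
Reads crossing an inversion or distant-jump junction are emitted as a
primary plus supplementary segment exactly as an aligner would place them.
Output is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import AlignmentRecord, GenomicInterval, Role, is_mito

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for i, a in enumerate(b"ACGT"):
    _BASE_INDEX[a] = i


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return _to_str(_COMP[_to_bytes(seq)][::-1])


@dataclass
class SimConfig:
    """Sequencing-emulation parameters.

    Error rates default to (sub, ins, del) = (0.010, 0.006, 0.009), a total
    of 2.5% ~= Q16 mean read accuracy; indel rates are multiplied inside
    homopolymer runs (>= 4 identical bases)."""

    seed: int = 0
    read_length_mean: int = 10_000
    read_length_sd: int = 5_000
    depth: float = 12.0
    mito_depth: float = 1200.0
    err_sub: float = 0.010
    err_ins: float = 0.006
    err_del: float = 0.009
    homopolymer_indel_multiplier: float = 2.0
    min_read_length: int = 500
    junction_max_gap: int = 1000  # larger reference jumps become split reads

    def __post_init__(self):
        for r in (self.err_sub, self.err_ins, self.err_del):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class Haplotype:
    """One chromosome copy with its base-level reference projection."""

    name: str
    chrom: str
    seq: np.ndarray  # uint8 ASCII
    refpos: np.ndarray  # int64; -1 for bases absent from the reference
    strand: np.ndarray  # int8; +1 / -1
    weight: float = 1.0  # expected depth = weight * depth / 2

    @staticmethod
    def identity(name: str, chrom: str, sequence: str,
                 weight: float = 1.0) -> "Haplotype":
        seq = _to_bytes(sequence)
        return Haplotype(
            name, chrom, seq,
            np.arange(len(seq), dtype=np.int64),
            np.ones(len(seq), dtype=np.int8),
            weight,
        )


@dataclass
class VariantSpec:
    """One planted variant.

    kind: snv | ins | del | dup | inv | str
    For ``str``, ``count`` may be a sequence of repeat counts: the carrier
    haplotype is then split into equally weighted subclones, one per
    count, emulating somatic mosaicism.  ``interruptions`` is a list of
    (unit_offset, unit_sequence) inserted into the repeat tract.
    """

    kind: str
    chrom: str
    start: int
    end: int = -1
    alt: str = ""
    motif: str = ""
    count: Union[int, Sequence[int], None] = None
    interruptions: Sequence[tuple[int, str]] = ()
    haps: Sequence[int] = (0,)

    def __post_init__(self):
        if self.end < 0:
            self.end = self.start + 1 if self.kind == "snv" else self.start

    def footprint(self) -> tuple[int, int]:
        return self.start, max(self.end, self.start + 1)


@dataclass
class TruthManifest:
    """Ground truth: spiked variants per haplotype and per-read provenance."""

    variants: list[dict] = field(default_factory=list)
    reads: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"variants": self.variants, "reads": self.reads}


# ---------------------------------------------------------------------------
# Genome construction

def make_genome(
    n_chroms: int,
    chrom_length: int,
    seed: int,
    names: Optional[Sequence[str]] = None,
    gc: float = 0.42,
    str_loci: Optional[Sequence[dict]] = None,
    read_length_mean: int = 10_000,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Random reference genome with optional planted STR loci.

    ``str_loci`` entries are dicts with chrom, start, motif, count; the
    reference tract motif*count is written at the stated position.
    """
    if chrom_length < 10 * read_length_mean:
        raise ValueError(
            f"chrom_length {chrom_length} too small; need >= 10x the mean "
            f"read length ({10 * read_length_mean})"
        )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    names = list(names) if names else [f"chr{i+1}" for i in range(n_chroms)]
    genome = {}
    for name in names:
        arr = _BASES[rng.choice(4, size=chrom_length, p=p)]
        genome[name] = _to_str(arr)
    placements = []
    for locus in (str_loci or []):
        chrom = locus["chrom"]
        start = int(locus["start"])
        tract = locus["motif"].upper() * int(locus["count"])
        seq = genome[chrom]
        if start + len(tract) > len(seq):
            raise ValueError(f"STR locus at {chrom}:{start} exceeds contig")
        genome[chrom] = seq[:start] + tract + seq[start + len(tract):]
        placements.append(GenomicInterval(chrom, start, start + len(tract)))
    return genome, placements


# ---------------------------------------------------------------------------
# Variant spiking

def _apply_spec(hap: Haplotype, spec: VariantSpec,
                count_override: Optional[int] = None) -> None:
    """Apply one variant in place.  Must be called in descending start
    order so untouched lower coordinates keep identity indexing."""
    a, b = spec.start, spec.end
    seq, rp, st = hap.seq, hap.refpos, hap.strand
    if spec.kind == "snv":
        hap.seq = seq.copy()
        hap.seq[a] = _to_bytes(spec.alt)[0]
        return
    if spec.kind == "del":
        hap.seq = np.concatenate([seq[:a], seq[b:]])
        hap.refpos = np.concatenate([rp[:a], rp[b:]])
        hap.strand = np.concatenate([st[:a], st[b:]])
        return
    if spec.kind == "ins":
        ins = _to_bytes(spec.alt)
        hap.seq = np.concatenate([seq[:a], ins, seq[a:]])
        hap.refpos = np.concatenate(
            [rp[:a], np.full(len(ins), -1, dtype=np.int64), rp[a:]]
        )
        hap.strand = np.concatenate(
            [st[:a], np.ones(len(ins), dtype=np.int8), st[a:]]
        )
        return
    if spec.kind == "dup":
        hap.seq = np.concatenate([seq[:b], seq[a:b], seq[b:]])
        hap.refpos = np.concatenate([rp[:b], rp[a:b], rp[b:]])
        hap.strand = np.concatenate([st[:b], st[a:b], st[b:]])
        return
    if spec.kind == "inv":
        hap.seq = np.concatenate([seq[:a], _COMP[seq[a:b]][::-1], seq[b:]])
        hap.refpos = np.concatenate([rp[:a], rp[a:b][::-1], rp[b:]])
        hap.strand = np.concatenate([st[:a], -st[a:b][::-1], st[b:]])
        return
    if spec.kind == "str":
        count = count_override if count_override is not None else spec.count
        if not isinstance(count, (int, np.integer)):
            raise ValueError("mosaic STR counts must be expanded beforehand")
        units = [spec.motif.upper()] * int(count)
        for off, unit in sorted(spec.interruptions, key=lambda t: t[0]):
            units.insert(min(off, len(units)), unit.upper())
        tract = _to_bytes("".join(units))
        ref_span = b - a
        rp_tract = np.full(len(tract), -1, dtype=np.int64)
        n_map = min(ref_span, len(tract))
        rp_tract[:n_map] = np.arange(a, a + n_map, dtype=np.int64)
        hap.seq = np.concatenate([seq[:a], tract, seq[b:]])
        hap.refpos = np.concatenate([rp[:a], rp_tract, rp[b:]])
        hap.strand = np.concatenate(
            [st[:a], np.ones(len(tract), dtype=np.int8), st[b:]]
        )
        return
    raise ValueError(f"unknown variant kind {spec.kind!r}")


def spike_variants(
    reference: dict[str, str],
    specs: Sequence[VariantSpec],
    ploidy: Optional[dict[str, int]] = None,
    hap_weights: Optional[dict[str, Sequence[float]]] = None,
) -> tuple[list[Haplotype], TruthManifest]:
    """Build per-chromosome haplotype copies with variants applied.

    Each chromosome gets ``ploidy[chrom]`` copies (default 2), optionally
    with per-copy depth weights (e.g. heteroplasmy fractions for chrM).
    Overlapping specs on the same haplotype are an error.
    """
    ploidy = ploidy or {}
    hap_weights = hap_weights or {}
    manifest = TruthManifest()
    haplotypes: list[Haplotype] = []
    for chrom, sequence in reference.items():
        copies = ploidy.get(chrom, 2)
        weights = list(hap_weights.get(chrom, [1.0] * copies))
        if len(weights) != copies:
            raise ValueError(f"{chrom}: {copies} copies but "
                             f"{len(weights)} weights")
        for h in range(copies):
            on_hap = [s for s in specs if s.chrom == chrom and h in s.haps]
            on_hap.sort(key=lambda s: s.start)
            for prev, cur in zip(on_hap, on_hap[1:]):
                if prev.footprint()[1] > cur.footprint()[0]:
                    raise ValueError(
                        f"overlapping specs on {chrom} hap {h}: "
                        f"{prev.kind}@{prev.start} and {cur.kind}@{cur.start}"
                    )
            mosaic = [s for s in on_hap
                      if s.kind == "str" and not isinstance(s.count, (int, np.integer))]
            if len(mosaic) > 1:
                raise ValueError("at most one mosaic STR spec per haplotype")
            counts = list(mosaic[0].count) if mosaic else [None]
            sub_w = weights[h] / len(counts)
            for k, count in enumerate(counts):
                name = f"{chrom}_hap{h}" + (f"_m{k}" if len(counts) > 1 else "")
                hap = Haplotype.identity(name, chrom, sequence, sub_w)
                for s in reversed(on_hap):
                    if s.kind == "str" and s in mosaic:
                        _apply_spec(hap, s, count_override=count)
                    else:
                        _apply_spec(hap, s)
                haplotypes.append(hap)
            for s in on_hap:
                manifest.variants.append({
                    "kind": s.kind, "chrom": chrom, "hap": h,
                    "start": s.start, "end": s.end,
                    "alt": s.alt, "motif": s.motif,
                    "count": (list(s.count)
                              if isinstance(s.count, (list, tuple)) else s.count),
                    "interruptions": [list(t) for t in s.interruptions],
                })
    return haplotypes, manifest


# ---------------------------------------------------------------------------
# Read simulation

def _homopolymer_mask(seq: np.ndarray, min_run: int = 4) -> np.ndarray:
    if len(seq) == 0:
        return np.zeros(0, dtype=bool)
    change = np.ones(len(seq), dtype=bool)
    change[1:] = seq[1:] != seq[:-1]
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_run


def _inject_errors(seq, refpos, strand, hp, rng, cfg):
    """Vectorized ONT-style error injection on a read's projection arrays.

    Substitutions edit bases in place; deletion errors drop elements
    (creating 1-base reference gaps, i.e. D operations); insertion errors
    add refpos=-1 elements (I operations)."""
    n = len(seq)
    mult = np.where(hp, cfg.homopolymer_indel_multiplier, 1.0)
    del_mask = rng.random(n) < cfg.err_del * mult
    sub_mask = (~del_mask) & (rng.random(n) < cfg.err_sub)
    ins_mask = rng.random(n) < cfg.err_ins * mult
    n_errors = int(del_mask.sum() + sub_mask.sum() + ins_mask.sum())
    seq = seq.copy()
    idx = np.flatnonzero(sub_mask)
    if len(idx):
        orig = _BASE_INDEX[seq[idx]]
        repl = (orig + rng.integers(1, 4, size=len(idx))) % 4
        seq[idx] = _BASES[repl]
    keep = ~del_mask
    seq, refpos, strand, ins_mask = (
        seq[keep], refpos[keep], strand[keep], ins_mask[keep]
    )
    ipos = np.flatnonzero(ins_mask) + 1
    if len(ipos):
        seq = np.insert(seq, ipos, _BASES[rng.integers(0, 4, size=len(ipos))])
        refpos = np.insert(refpos, ipos, -1)
        src = np.clip(ipos - 1, 0, len(strand) - 1)
        strand = np.insert(strand, ipos, strand[src])
    return seq, refpos, strand, n_errors


def _segment_bounds(refpos: np.ndarray, strand: np.ndarray,
                    max_gap: int) -> list[tuple[int, int]]:
    """Split a read's projection at junctions: strand changes or reference
    jumps beyond ``max_gap`` between consecutive mapped bases."""
    m = np.flatnonzero(refpos >= 0)
    if len(m) == 0:
        return []
    rp, st = refpos[m], strand[m]
    d = np.diff(rp)
    same = st[1:] == st[:-1]
    fwd = (d >= 1) & (d <= max_gap)
    rev = (d <= -1) & (d >= -max_gap)
    ok = same & np.where(st[:-1] > 0, fwd, rev)
    breaks = np.flatnonzero(~ok)
    bounds = []
    start_j = 0
    for j in breaks:
        bounds.append((int(m[start_j]), int(m[j]) + 1))
        start_j = j + 1
    bounds.append((int(m[start_j]), int(m[-1]) + 1))
    return bounds


def _cigar_from_refpos(rp: np.ndarray) -> list[tuple[str, int]]:
    """CIGAR from an ascending-mapped projection slice (first and last
    elements mapped)."""
    mapped = rp >= 0
    m_idx = np.flatnonzero(mapped)
    gaps = np.zeros(len(rp), dtype=np.int64)
    gaps[m_idx[1:]] = np.diff(rp[m_idx]) - 1
    code = mapped.astype(np.int8)
    boundary = np.ones(len(rp), dtype=bool)
    boundary[1:] = (code[1:] != code[:-1]) | (gaps[1:] > 0)
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], len(rp))
    ops: list[tuple[str, int]] = []
    for s0, e0 in zip(starts, ends):
        if gaps[s0] > 0:
            ops.append(("D", int(gaps[s0])))
        ops.append(("M" if code[s0] else "I", int(e0 - s0)))
    return ops


def _emit_read(hap, s, e, read_id, rng, cfg, hp_full):
    """Generate the AlignmentRecord(s) for one read drawn from haplotype
    coordinates [s, e)."""
    seq = hap.seq[s:e]
    refpos = hap.refpos[s:e]
    strand = hap.strand[s:e]
    hp = hp_full[s:e]
    seq, refpos, strand, n_errors = _inject_errors(
        seq, refpos, strand, hp, rng, cfg
    )
    bounds = _segment_bounds(refpos, strand, cfg.junction_max_gap)
    if not bounds:
        return [], n_errors
    total = len(seq)
    err_frac = max(n_errors / max(total, 1), 1e-4)
    meanq = min(-10.0 * math.log10(err_frac), 40.0)
    fwd_seq = _to_str(seq)
    rev_seq = None
    # primary = segment with most query bases
    primary_idx = max(range(len(bounds)), key=lambda i: bounds[i][1] - bounds[i][0])
    records = []
    for i, (a, b) in enumerate(bounds):
        seg_rp = refpos[a:b]
        seg_strand = int(strand[a])
        left, right = a, total - b
        if seg_strand > 0:
            core = _cigar_from_refpos(seg_rp)
            record_seq = fwd_seq
            clips = (left, right)
        else:
            core = _cigar_from_refpos(seg_rp[::-1])
            if rev_seq is None:
                rev_seq = _to_str(_COMP[seq][::-1])
            record_seq = rev_seq
            clips = (right, left)
        cigar = []
        if clips[0]:
            cigar.append(("S", clips[0]))
        cigar.extend(core)
        if clips[1]:
            cigar.append(("S", clips[1]))
        mapped = seg_rp[seg_rp >= 0]
        records.append(AlignmentRecord(
            read_id=read_id,
            interval=GenomicInterval(hap.chrom, int(mapped.min()),
                                     int(mapped.max()) + 1),
            strand="+" if seg_strand > 0 else "-",
            cigar=cigar,
            mapq=60,
            role=Role.PRIMARY if i == primary_idx else Role.SUPPLEMENTARY,
            sequence=record_seq,
            mean_quality=meanq,
        ))
    return records, n_errors


def simulate_alignments(
    haplotypes: Sequence[Haplotype],
    config: SimConfig,
    manifest: Optional[TruthManifest] = None,
) -> list[AlignmentRecord]:
    """Draw reads to the target depth from every haplotype and emit aligned
    records (sorted by coordinate).  Deterministic per config.seed."""
    rng = np.random.default_rng(config.seed)
    manifest = manifest if manifest is not None else TruthManifest()
    mean, sd = float(config.read_length_mean), float(config.read_length_sd)
    mu = math.log(mean**2 / math.sqrt(mean**2 + sd**2))
    sigma = math.sqrt(math.log(1 + (sd / mean) ** 2))
    records: list[AlignmentRecord] = []
    serial = 0
    for hap in haplotypes:
        L = len(hap.seq)
        depth = config.mito_depth if is_mito(hap.chrom) else config.depth
        target = depth / 2.0 * hap.weight
        eff_len = mean * max(1.0 - mean / (2.0 * L), 0.25)
        n_reads = max(int(round(target * L / eff_len)), 1)
        hp_full = _homopolymer_mask(hap.seq)
        starts = rng.integers(0, L, size=n_reads)
        lengths = np.maximum(
            rng.lognormal(mu, sigma, size=n_reads).astype(np.int64),
            min(config.min_read_length, max(L // 4, 1)),
        )
        for s, ln in zip(starts, lengths):
            e = min(int(s) + int(ln), L)
            if e - s < min(config.min_read_length, L // 4):
                continue
            read_id = f"sim_{hap.name}_{serial}"
            serial += 1
            recs, n_errors = _emit_read(
                hap, int(s), e, read_id, rng, config, hp_full
            )
            if not recs:
                continue
            records.extend(recs)
            manifest.reads.append({
                "read_id": read_id, "haplotype": hap.name,
                "chrom": hap.chrom, "hap_start": int(s), "hap_end": int(e),
                "n_errors": int(n_errors),
            })
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return records
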