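"""Alignment ingestion (SAM/BAM via pysam) and a naive exact-match aligner.

The production path consumes alignments produced by an external mapper.
"Uniquely mapped" is operationalized for SAM/BAM input as primary +
non-supplementary + MAPQ >= 20 (threshold configurable); "appropriate
configuration and spacing" for pairs as FR (face-to-face) orientation on the
same chromosome with insert <= 1000 bp -- fragments are 150-500 bp, so 1000
leaves headroom.  Records whose break-proximal 5' terminus is soft- or
hard-clipped are dropped.

:func:`exact_align` is a dependency-free test fixture: it finds all exact
occurrences of a read (or its reverse complement) in a synthetic genome and
either keeps only uniquely-placed reads or picks one occurrence at random
(seeded), mirroring the repeat-class handling of multi-mapping reads.

Coordinates are BED-style 0-based half-open everywhere internally; SAM's
1-based positions are converted at the boundary by pysam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pysam

from ._util import revcomp
from .readproc import FilterStats, RawRead
from .sim import SyntheticGenome

__all__ = [
    "AlignmentRecord",
    "AlignedPair",
    "exact_align",
    "pair_alignments",
    "load_alignments",
    "write_sam",
]


@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    mapq: int = 60
    unique: bool = True
    primary: bool = True
    proper_pair: bool = False

    @property
    def mate_id(self) -> str:
        """Pair key: read id with a trailing /1 or /2 mate tag removed."""
        if self.read_id[-2:] in ("/1", "/2"):
            return self.read_id[:-2]
        return self.read_id

    @property
    def mate_number(self) -> int | None:
        if self.read_id.endswith("/1"):
            return 1
        if self.read_id.endswith("/2"):
            return 2
        return None


@dataclass
class AlignedPair:
    """A kept pair; read 2 is the break-proximal mate."""

    read1_alignment: AlignmentRecord
    read2_alignment: AlignmentRecord
    insert_size: int


def _occurrences(seq: str, sub: str) -> list[int]:
    out = []
    i = seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


def exact_align(
    reads: Iterable[RawRead],
    genome: SyntheticGenome | Mapping[str, str],
    mode: str = "unique_only",
    seed: int | None = None,
) -> tuple[list[AlignmentRecord], FilterStats]:
    """Exact-match placement of error-free reads.

    ``unique_only`` keeps reads with exactly one occurrence over both
    strands of all chromosomes; ``random_best`` selects one occurrence
    uniformly at random (deterministic for a given ``seed``).
    """
    if mode not in ("unique_only", "random_best"):
        raise ValueError(f"unknown mode {mode!r}")
    sequences = genome.sequences if isinstance(genome, SyntheticGenome) else genome
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    stats = FilterStats()
    for read in reads:
        occ: list[tuple[str, int, str]] = []
        rc = revcomp(read.sequence)
        for chrom, seq in sequences.items():
            occ += [(chrom, s, "+") for s in _occurrences(seq, read.sequence)]
            occ += [(chrom, s, "-") for s in _occurrences(seq, rc)]
        if not occ:
            stats.drop("unaligned")
            continue
        if len(occ) > 1:
            if mode == "unique_only":
                stats.drop("non_unique")
                continue
            chrom, s, strand = occ[int(rng.integers(len(occ)))]
            unique = False
        else:
            chrom, s, strand = occ[0]
            unique = True
        records.append(
            AlignmentRecord(read.id, chrom, s, s + len(read.sequence), strand,
                            mapq=60 if unique else 0, unique=unique)
        )
        stats.keep()
    return records, stats


def pair_alignments(
    records: Iterable[AlignmentRecord], max_insert: int = 1000
) -> tuple[list[AlignedPair], FilterStats]:
    """Assemble face-to-face FR pairs from per-mate alignment records.

    Mates must share a chromosome, sit on opposite strands with the
    plus-strand mate leftmost, and span an insert of at most ``max_insert``.
    """
    by_id: dict[str, dict[int, AlignmentRecord]] = {}
    for rec in records:
        mn = rec.mate_number
        if mn is None:
            raise ValueError(f"record {rec.read_id} has no /1 or /2 mate tag")
        by_id.setdefault(rec.mate_id, {})[mn] = rec

    pairs: list[AlignedPair] = []
    stats = FilterStats()
    for mates in by_id.values():
        if len(mates) != 2:
            stats.drop("mate_missing")
            continue
        r1, r2 = mates[1], mates[2]
        if r1.chrom != r2.chrom:
            stats.drop("different_chrom")
            continue
        if r1.strand == r2.strand:
            stats.drop("same_strand")
            continue
        plus, minus = (r1, r2) if r1.strand == "+" else (r2, r1)
        if plus.start > minus.start or plus.end > minus.end:
            stats.drop("orientation")
            continue
        insert = minus.end - plus.start
        if insert > max_insert:
            stats.drop("insert")
            continue
        r1.proper_pair = r2.proper_pair = True
        pairs.append(AlignedPair(r1, r2, insert))
        stats.keep()
    return pairs, stats


def _five_prime_clipped(aln: pysam.AlignedSegment) -> bool:
    cig = aln.cigartuples
    if not cig:
        return False
    op = cig[-1][0] if aln.is_reverse else cig[0][0]
    return op in (4, 5)  # soft, hard clip


def load_alignments(
    source: str | pysam.AlignmentFile,
    chemistry: str = "ILM",
    min_mapq: int = 20,
    max_insert: int = 1000,
) -> tuple[list[AlignedPair] | list[AlignmentRecord], FilterStats]:
    """Read SAM/BAM and apply the uniqueness/pairing filters.

    Returns ``(pairs, stats)`` in ILM mode and ``(records, stats)`` in SMS
    mode.  Retains only mapped, primary, non-supplementary records with
    MAPQ >= ``min_mapq`` whose break-proximal 5' terminus is unclipped
    (read 2 in ILM mode, every read in SMS mode).
    """
    if chemistry not in ("ILM", "SMS"):
        raise ValueError(f"unknown chemistry {chemistry!r}")
    own = isinstance(source, str)
    af = pysam.AlignmentFile(source, check_sq=False) if own else source
    stats = FilterStats()
    records: list[AlignmentRecord] = []
    try:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                stats.drop("unmapped")
                continue
            if aln.is_secondary:
                stats.drop("secondary")
                continue
            if aln.is_supplementary:
                stats.drop("supplementary")
                continue
            if aln.mapping_quality < min_mapq:
                stats.drop("mapq")
                continue
            break_proximal = chemistry == "SMS" or aln.is_read2 or not aln.is_paired
            if break_proximal and _five_prime_clipped(aln):
                stats.drop("clipped")
                continue
            rid = aln.query_name
            if chemistry == "ILM" and aln.is_paired:
                rid += "/2" if aln.is_read2 else "/1"
            records.append(
                AlignmentRecord(
                    read_id=rid,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                )
            )
            stats.keep()
    finally:
        if own:
            af.close()
    if chemistry == "SMS":
        return records, stats
    pairs, pair_stats = pair_alignments(records, max_insert)
    return pairs, stats.merged(pair_stats)


def write_sam(
    path: str,
    genome: SyntheticGenome | Mapping[str, str],
    records: Iterable[AlignmentRecord],
    paired: bool = False,
) -> None:
    """Fixture SAM writer for round-tripping exact-aligner output.

    Query sequences are reconstructed from the reference (full-match CIGAR),
    which is exact for error-free fixture reads.
    """
    sequences = genome.sequences if isinstance(genome, SyntheticGenome) else genome
    chroms = list(sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(sequences[c])} for c in chroms],
    }
    recs = list(records)
    mates: dict[str, dict[int, AlignmentRecord]] = {}
    if paired:
        for r in recs:
            mates.setdefault(r.mate_id, {})[r.mate_number or 0] = r

    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.mate_id if paired else r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            length = r.end - r.start
            a.cigartuples = [(0, length)]
            seq = sequences[r.chrom][r.start : r.end]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if paired:
                flag |= 0x1
                mate = mates.get(r.mate_id, {})
                other = mate.get(2 if r.mate_number == 1 else 1)
                flag |= 0x40 if r.mate_number == 1 else 0x80
                if other is not None:
                    flag |= 0x2
                    if other.strand == "-":
                        flag |= 0x20
                    a.next_reference_name = other.chrom
                    a.next_reference_start = other.start
                else:
                    flag |= 0x8
            a.flag = flag
            out.write(a)
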