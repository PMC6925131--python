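"""Single-base SSB calling and the post-alignment filter chain.

A call is the single genomic base carrying the free 3'-OH terminus, reported
on the broken strand -- always the strand opposite to the source alignment,
because the sequenced strand is the complement primed from the polyA tail.

Coordinate rules (BED 0-based half-open):

* paired-end (ILM) chemistry -- the SSB is the first base after the T-run of
  read 2: a read 2 aligned '+' at [s, e) gives SSB [s, s+1) on '-'; aligned
  '-' at [s, e) gives [e-1, e) on '+'.
* single-molecule (SMS) chemistry -- the fill-and-lock step consumed one
  unsequenced base, so the alignment's 5' coordinate is extended by one: a
  '+' alignment [s, e) gives SSB [s-1, s) on '-'; a '-' alignment gives
  [e, e+1) on '+'.  Extension past a contig boundary drops the call.

The filter chain then applies, in order: the internal-priming filter
(T-fraction of the 20-base 5'-upstream window of the source alignment
> 40% removes the read), un-tailed control subtraction (strand- and
base-exact), and repeat masking (strand-blind, half-open).  Hotspot
analyses keep per-position read counts; everything else uses unique
(chrom, start, strand) coordinates.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._util import revcomp
from .align import AlignedPair, AlignmentRecord
from .readproc import FilterStats
from .sim import SyntheticGenome

__all__ = [
    "SSBCall",
    "BreakSet",
    "DSBCall",
    "call_ssb_ilm",
    "call_ssb_sms",
    "call_ssbs",
    "internal_priming_filter",
    "collapse",
    "subtract_control",
    "mask_repeats",
    "pair_dsb",
]


@dataclass
class SSBCall:
    """One single-base SSB; ``strand`` is the broken strand."""

    chrom: str
    start: int
    strand: str
    read_count: int = 1
    sample_id: str | None = None
    source_alignment: AlignmentRecord | None = None

    @property
    def end(self) -> int:
        return self.start + 1

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


@dataclass
class BreakSet:
    """Unique-coordinate SSB calls with per-position read counts."""

    calls: dict[tuple[str, int, str], SSBCall] = field(default_factory=dict)
    total_filtered_reads: int = 0
    provenance: list[str] = field(default_factory=list)
    sample_id: str | None = None

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self.calls

    def keys(self) -> set[tuple[str, int, str]]:
        return set(self.calls)

    def sorted_calls(self) -> list[SSBCall]:
        return [self.calls[k] for k in sorted(self.calls)]

    @property
    def conserved(self) -> bool:
        return sum(c.read_count for c in self.calls.values()) == self.total_filtered_reads


@dataclass
class DSBCall:
    """Two opposite-strand SSBs within a small gap, read as one DSB."""

    chrom: str
    plus_pos: int
    minus_pos: int

    @property
    def gap(self) -> int:
        return abs(self.plus_pos - self.minus_pos)


def call_ssb_ilm(pair: AlignedPair, sample_id: str | None = None) -> SSBCall:
    """SSB from a filtered pair: the base at the 5' terminus of read 2,
    reported on the strand opposite the read 2 alignment."""
    aln = pair.read2_alignment
    if aln.strand == "+":
        return SSBCall(aln.chrom, aln.start, "-",
                       sample_id=sample_id, source_alignment=aln)
    return SSBCall(aln.chrom, aln.end - 1, "+",
                   sample_id=sample_id, source_alignment=aln)


def call_ssb_sms(
    aln: AlignmentRecord,
    chrom_lengths: Mapping[str, int] | None = None,
    sample_id: str | None = None,
) -> SSBCall | None:
    """SSB from an SMS alignment with the one-base 5' extension.

    Returns None (call dropped) when the extension would step past a contig
    boundary: start 0 on '+', or end at the chromosome length on '-' when
    lengths are provided.
    """
    if aln.strand == "+":
        if aln.start == 0:
            return None
        return SSBCall(aln.chrom, aln.start - 1, "-",
                       sample_id=sample_id, source_alignment=aln)
    if chrom_lengths is not None and aln.end >= chrom_lengths[aln.chrom]:
        return None
    return SSBCall(aln.chrom, aln.end, "+",
                   sample_id=sample_id, source_alignment=aln)


def call_ssbs(
    source: Iterable[AlignedPair] | Iterable[AlignmentRecord],
    chemistry: str = "ILM",
    chrom_lengths: Mapping[str, int] | None = None,
    sample_id: str | None = None,
) -> tuple[list[SSBCall], FilterStats]:
    """Read-level calls for a whole sample (one call per kept read/pair)."""
    calls: list[SSBCall] = []
    stats = FilterStats()
    if chemistry == "ILM":
        for pair in source:
            calls.append(call_ssb_ilm(pair, sample_id))
            stats.keep()
    elif chemistry == "SMS":
        for aln in source:
            call = call_ssb_sms(aln, chrom_lengths, sample_id)
            if call is None:
                stats.drop("boundary")
            else:
                calls.append(call)
                stats.keep()
    else:
        raise ValueError(f"unknown chemistry {chemistry!r}")
    return calls, stats


def upstream_window(
    genome: SyntheticGenome | Mapping[str, str],
    aln: AlignmentRecord,
    window: int = 20,
) -> str:
    """The ``window``-base sequence 5' upstream of an alignment, on the
    alignment strand; truncated at contig ends."""
    sequences = genome.sequences if isinstance(genome, SyntheticGenome) else genome
    seq = sequences[aln.chrom]
    if aln.strand == "+":
        return seq[max(aln.start - window, 0) : aln.start]
    return revcomp(seq[aln.end : aln.end + window])


def internal_priming_filter(
    calls: Iterable[SSBCall],
    genome: SyntheticGenome | Mapping[str, str],
    threshold: float = 0.40,
    window: int = 20,
    drop_truncated: bool = False,
) -> tuple[list[SSBCall], FilterStats]:
    """Remove calls whose upstream window is polyT on the alignment strand.

    A call is dropped iff T-count / window-length > ``threshold`` (strict).
    Windows truncated at contig ends use the available bases with the same
    fractional threshold by default; ``drop_truncated`` discards them
    instead.
    """
    kept: list[SSBCall] = []
    stats = FilterStats()
    for call in calls:
        if call.source_alignment is None:
            raise ValueError("internal_priming_filter requires source alignments")
        win = upstream_window(genome, call.source_alignment, window)
        if len(win) < window and drop_truncated:
            stats.drop("truncated_window")
            continue
        if len(win) == 0:
            stats.drop("truncated_window")
            continue
        if win.count("T") / len(win) > threshold:
            stats.drop("internal_priming")
            continue
        kept.append(call)
        stats.keep()
    return kept, stats


def collapse(calls: Iterable[SSBCall], sample_id: str | None = None) -> BreakSet:
    """Collapse read-level calls to unique coordinates, summing read counts."""
    bs = BreakSet(sample_id=sample_id)
    n = 0
    for call in calls:
        n += call.read_count
        key = call.key
        if key in bs.calls:
            bs.calls[key].read_count += call.read_count
        else:
            bs.calls[key] = SSBCall(call.chrom, call.start, call.strand,
                                    read_count=call.read_count, sample_id=sample_id)
    bs.total_filtered_reads = n
    bs.provenance.append("collapse")
    return bs


def subtract_control(breaks: BreakSet, control: BreakSet) -> tuple[BreakSet, int]:
    """Remove every call whose (chrom, start, strand) occurs in the un-tailed
    control; strand- and base-exact."""
    out = BreakSet(sample_id=breaks.sample_id,
                   provenance=list(breaks.provenance))
    removed = 0
    for key, call in breaks.calls.items():
        if key in control.calls:
            removed += 1
        else:
            out.calls[key] = call
    out.total_filtered_reads = sum(c.read_count for c in out.calls.values())
    out.provenance.append(f"subtract_control(removed={removed})")
    return out, removed


def _build_repeat_index(
    repeats: Iterable[tuple[str, int, int]]
) -> dict[str, tuple[list[int], list[int]]]:
    """Per-chromosome merged, sorted (starts, ends) for bisect lookup."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, *_ in repeats:
        by_chrom.setdefault(chrom, []).append((start, end))
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        index[chrom] = ([s for s, _ in merged], [e for _, e in merged])
    return index


def mask_repeats(
    breaks: BreakSet, repeats: Iterable[tuple[str, int, int]]
) -> tuple[BreakSet, int]:
    """Remove calls whose base lies in any repeat interval (half-open,
    strand-blind)."""
    index = _build_repeat_index(repeats)
    out = BreakSet(sample_id=breaks.sample_id,
                   provenance=list(breaks.provenance))
    removed = 0
    for key, call in breaks.calls.items():
        starts_ends = index.get(call.chrom)
        inside = False
        if starts_ends is not None:
            starts, ends = starts_ends
            i = bisect_right(starts, call.start) - 1
            inside = i >= 0 and call.start < ends[i]
        if inside:
            removed += 1
        else:
            out.calls[key] = call
    out.total_filtered_reads = sum(c.read_count for c in out.calls.values())
    out.provenance.append(f"mask_repeats(removed={removed})")
    return out, removed


def pair_dsb(
    breaks: BreakSet, max_gap: int = 2, mode: str = "all"
) -> list[DSBCall]:
    """Opposite-strand SSB pairs within ``max_gap`` bases, read as DSBs.

    ``all`` reports every qualifying ('+', '-') pair (an SSB may appear in
    several); ``greedy`` assigns each '+' call to its nearest unclaimed '-'
    partner, scanning left to right with ties to the left.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if mode not in ("all", "greedy"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, pos, strand in breaks.calls:
        by_chrom.setdefault(chrom, ([], []))[0 if strand == "+" else 1].append(pos)

    out: list[DSBCall] = []
    for chrom, (plus, minus) in by_chrom.items():
        plus.sort()
        minus.sort()
        if mode == "all":
            j0 = 0
            for p in plus:
                while j0 < len(minus) and minus[j0] < p - max_gap:
                    j0 += 1
                j = j0
                while j < len(minus) and minus[j] <= p + max_gap:
                    out.append(DSBCall(chrom, p, minus[j]))
                    j += 1
        else:
            used = [False] * len(minus)
            j0 = 0
            for p in plus:
                best = None
                for j in range(len(minus)):
                    if used[j] or abs(minus[j] - p) > max_gap:
                        continue
                    if best is None or abs(minus[j] - p) < abs(minus[best] - p):
                        best = j
                if best is not None:
                    used[best] = True
                    out.append(DSBCall(chrom, p, minus[best]))
    out.sort(key=lambda d: (d.chrom, d.plus_pos, d.minus_pos))
    return out
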