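"""Pre-alignment read filtering and trimming for both library chemistries.

Paired-end (ILM) rule: keep a pair only when read 1 begins with at least 10
G's, read 2 begins with at least 12 T's, and every base of both reads has
Phred quality strictly greater than 20.  Trimming then removes the first 10
bases of read 1 (the polyC-primer G's; base 11 may be a genomic G, so the
trim is fixed-length) and the maximal leading T-run of read 2 (the V anchor
of the oligo-dT primer makes the 13th base non-T on clean data, so maximal
and fixed-12 trimming coincide there).

Single-molecule (SMS) rule: keep reads of length >= 25 bases.  Quality
heuristics beyond length are a configurable pass-through.

The quality rule is applied to the untrimmed reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from .sim import FastqRead as RawRead

__all__ = [
    "RawRead",
    "TrimmedPair",
    "FilterStats",
    "filter_ilm_pair",
    "filter_sms_read",
    "filter_ilm_pairs",
    "filter_sms_reads",
    "G_RUN",
    "T_RUN",
]

G_RUN = 10
T_RUN = 12

# documented drop-reason order: first failing rule wins
REASON_STRUCTURE1 = "structure1"
REASON_STRUCTURE2 = "structure2"
REASON_QUALITY = "quality"
REASON_LENGTH = "length"


@dataclass
class TrimmedPair:
    """A kept pair: read 1 minus its 10 G's, read 2 minus its leading T-run."""

    read1_trimmed: RawRead
    read2_trimmed: RawRead
    t_run_length: int


@dataclass
class FilterStats:
    """Per-rule accounting; ``input_count == passed_count + sum(drops)``."""

    input_count: int = 0
    passed_count: int = 0
    drops: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.input_count += 1
        self.drops[reason] = self.drops.get(reason, 0) + 1

    def keep(self) -> None:
        self.input_count += 1
        self.passed_count += 1

    @property
    def conserved(self) -> bool:
        return self.input_count == self.passed_count + sum(self.drops.values())

    def merged(self, other: "FilterStats") -> "FilterStats":
        drops = dict(self.drops)
        for k, v in other.drops.items():
            drops[k] = drops.get(k, 0) + v
        return FilterStats(self.input_count + other.input_count,
                           self.passed_count + other.passed_count, drops)


def _leading_run(seq: str, base: str) -> int:
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


def _check_read(read: RawRead) -> None:
    if len(read.sequence) != len(read.qualities):
        raise ValueError(
            f"read {read.id}: sequence length {len(read.sequence)} != "
            f"quality length {len(read.qualities)}"
        )


def filter_ilm_pair(
    read1: RawRead, read2: RawRead, min_phred: int = 21
) -> TrimmedPair | str:
    """Apply the paired-end structure/quality filter to one pair.

    Returns a :class:`TrimmedPair` when kept, otherwise the drop reason
    (``structure1``, ``structure2`` or ``quality``, in that order of
    precedence).  ``min_phred`` is the lowest acceptable quality; the
    default 21 implements the strict "> 20" rule.
    """
    _check_read(read1)
    _check_read(read2)
    if not read1.sequence or not read2.sequence:
        raise ValueError("empty read")

    if _leading_run(read1.sequence, "G") < G_RUN:
        return REASON_STRUCTURE1
    t_run = _leading_run(read2.sequence, "T")
    if t_run < T_RUN or t_run == len(read2.sequence):
        # an all-T read 2 has no genomic base left after trimming
        return REASON_STRUCTURE2
    if min(read1.qualities) < min_phred or min(read2.qualities) < min_phred:
        return REASON_QUALITY

    r1 = RawRead(read1.id, read1.sequence[G_RUN:], read1.qualities[G_RUN:])
    r2 = RawRead(read2.id, read2.sequence[t_run:], read2.qualities[t_run:])
    return TrimmedPair(r1, r2, t_run)


def filter_sms_read(
    read: RawRead,
    min_len: int = 25,
    quality_check: Callable[[RawRead], bool] | None = None,
) -> RawRead | str:
    """Length filter (>= ``min_len``, boundary inclusive) for SMS reads.

    ``quality_check`` is an optional caller-supplied predicate standing in
    for platform-specific quality filtration; reads failing it are dropped
    with reason ``quality``.
    """
    _check_read(read)
    if len(read.sequence) < min_len:
        return REASON_LENGTH
    if quality_check is not None and not quality_check(read):
        return REASON_QUALITY
    return read


def filter_ilm_pairs(
    pairs: Iterable[tuple[RawRead, RawRead]], min_phred: int = 21
) -> tuple[list[TrimmedPair], FilterStats]:
    kept: list[TrimmedPair] = []
    stats = FilterStats()
    for r1, r2 in pairs:
        out = filter_ilm_pair(r1, r2, min_phred)
        if isinstance(out, TrimmedPair):
            kept.append(out)
            stats.keep()
        else:
            stats.drop(out)
    return kept, stats


def filter_sms_reads(
    reads: Iterable[RawRead],
    min_len: int = 25,
    quality_check: Callable[[RawRead], bool] | None = None,
) -> tuple[list[RawRead], FilterStats]:
    kept: list[RawRead] = []
    stats = FilterStats()
    for read in reads:
        out = filter_sms_read(read, min_len, quality_check)
        if isinstance(out, RawRead):
            kept.append(out)
            stats.keep()
        else:
            stats.drop(out)
    return kept, stats
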