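"""Small shared helpers: sequence manipulation and interval arithmetic."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def seq_to_array(seq: str) -> np.ndarray:
    """DNA string -> uint8 array of ASCII codes (vector ops on big contigs)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval overlap."""
    return a_start < b_end and b_start < a_end


def total_length(intervals) -> int:
    """Total bases in a list of (chrom, start, end[, ...]) half-open intervals.

    Overlapping intervals on the same chromosome are merged first so each
    base is counted once.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        chrom, start, end = iv[0], iv[1], iv[2]
        by_chrom.setdefault(chrom, []).append((start, end))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def point_in_intervals(chrom: str, pos: int, intervals) -> bool:
    """Membership of a single base in any half-open (chrom, start, end) interval."""
    for iv in intervals:
        if iv[0] == chrom and iv[1] <= pos < iv[2]:
            return True
    return False
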