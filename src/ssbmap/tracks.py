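"""Piecewise-constant genomic signal tracks (replication timing, nucleosome
occupancy, conservation scores).

Tracks are held densely as one float array per chromosome, which is the
right trade-off at the scale of the synthetic genomes this package works
with; bedGraph and fixedStep wiggle text are the supported interchange
formats.  Positions on chromosomes a track does not cover evaluate to NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["SignalTrack"]


@dataclass
class SignalTrack:
    values: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""

    @classmethod
    def from_constant(cls, chrom_lengths: Mapping[str, int], value: float,
                      label: str = "") -> "SignalTrack":
        return cls({c: np.full(L, float(value)) for c, L in chrom_lengths.items()},
                   label)

    @classmethod
    def from_intervals(
        cls,
        chrom_lengths: Mapping[str, int],
        intervals: Iterable[tuple[str, int, int, float]],
        default: float = 0.0,
        label: str = "",
    ) -> "SignalTrack":
        """Dense track from (chrom, start, end, value) half-open intervals.

        Intervals must not overlap within a chromosome (later intervals
        would silently win); overlaps raise.
        """
        vals = {c: np.full(L, float(default)) for c, L in chrom_lengths.items()}
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, value in intervals:
            if chrom not in vals:
                raise KeyError(f"interval on unknown chromosome {chrom}")
            for s, e in seen.get(chrom, []):
                if start < e and s < end:
                    raise ValueError(
                        f"overlapping track intervals on {chrom}: "
                        f"[{s},{e}) and [{start},{end})"
                    )
            seen.setdefault(chrom, []).append((start, end))
            vals[chrom][start:end] = value
        return cls(vals, label)

    @classmethod
    def from_bedgraph(cls, path: str, chrom_lengths: Mapping[str, int],
                      default: float = 0.0, label: str = "") -> "SignalTrack":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                intervals.append((chrom, int(start), int(end), float(value)))
        return cls.from_intervals(chrom_lengths, intervals, default, label)

    @classmethod
    def from_fixedstep(cls, path: str, chrom_lengths: Mapping[str, int],
                       default: float = 0.0, label: str = "") -> "SignalTrack":
        """Parse fixedStep wiggle text (1-based starts per the wig spec)."""
        vals = {c: np.full(L, float(default)) for c, L in chrom_lengths.items()}
        chrom, pos, step, span = None, 0, 1, 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = fields["chrom"]
                    pos = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                    continue
                if chrom is None:
                    raise ValueError("wig data before fixedStep declaration")
                vals[chrom][pos : pos + span] = float(line)
                pos += step
        return cls(vals, label)

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.values.items():
                if len(arr) == 0:
                    continue
                change = np.nonzero(np.diff(arr))[0] + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(arr)]])
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")

    def value_at(self, chrom: str, pos: int) -> float:
        arr = self.values.get(chrom)
        if arr is None or not 0 <= pos < len(arr):
            return float("nan")
        return float(arr[pos])

    def values_at(self, positions: Iterable[tuple[str, int]]) -> np.ndarray:
        return np.array([self.value_at(c, p) for c, p in positions])

    def window_values(self, chrom: str, pos: int, flank: int) -> np.ndarray:
        """Values over [pos - flank, pos + flank], NaN outside the contig."""
        arr = self.values.get(chrom)
        out = np.full(2 * flank + 1, np.nan)
        if arr is None:
            return out
        lo, hi = pos - flank, pos + flank + 1
        s, e = max(lo, 0), min(hi, len(arr))
        if s < e:
            out[s - lo : e - lo] = arr[s:e]
        return out

    def mean(self, intervals: Iterable[tuple[str, int, int]] | None = None) -> float:
        """Length-weighted mean, over the whole track or given intervals."""
        if intervals is None:
            allv = np.concatenate([a for a in self.values.values() if len(a)])
            return float(np.nanmean(allv))
        chunks = []
        for chrom, start, end, *_ in intervals:
            arr = self.values.get(chrom)
            if arr is not None:
                chunks.append(arr[max(start, 0) : end])
        if not chunks:
            raise ValueError("no track coverage over the requested intervals")
        return float(np.nanmean(np.concatenate(chunks)))
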