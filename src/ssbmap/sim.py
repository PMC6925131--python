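"""Synthetic genomes, planted 3'-OH breaks and tailed-library read simulation.

The simulator emulates the data the break-mapping pipeline consumes so that
every downstream stage can be tested against known truth:

* random genomes with planted motifs, polyA runs, repeat annotations and
  genomic element annotations;
* planted single-strand breaks (SSBs) with known base and strand -- an SSB is
  the free 3'-OH terminal base of the broken strand;
* reads for two library chemistries.  In the paired-end (ILM) chemistry the
  break-proximal mate (read 2) begins with the 12 read T's left by the
  oligo-dT primer, followed by the complement of the broken strand read from
  the polyA tail inward; its mate (read 1) begins with 10 G's from the
  polyC-tail primer followed by the broken-strand sequence from the
  fragment's nuclease end toward the break.  In the single-molecule (SMS)
  chemistry the fill-and-lock step consumes the first template base after
  the tail, so the read starts one base 5' of the break base.
* internal-priming artifacts: oligo-dT annealing to genomic A-runs rather
  than an added tail, producing reads indistinguishable from break reads
  except for the A-rich genomic context downstream of the apparent break;
* un-tailed control libraries, in which true breaks emit no reads (no tail
  to prime from) and only the artifact/background channels remain.

Micrococcal-nuclease fragment ends carry 3'-P termini, which the terminal
transferase cannot tail; fragment boundaries are therefore recorded but
never emit break-like reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import gc_fraction, intervals_overlap, revcomp, seq_to_array

__all__ = [
    "SyntheticGenome",
    "SyntheticTruth",
    "LibraryConfig",
    "FastqRead",
    "LibraryResult",
    "make_genome",
    "simulate_breaks",
    "find_artifact_sites",
    "build_ilm_library",
    "build_sms_library",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: length of the read-T prefix on the break-proximal mate
T_PREFIX = 12
#: length of the G prefix on the nuclease-end mate
G_PREFIX = 10


@dataclass
class SyntheticGenome:
    """A synthetic reference with bookkeeping for everything planted in it.

    All intervals are BED-style 0-based half-open tuples
    ``(chrom, start, end, ...)``.
    """

    sequences: dict[str, str]
    planted_motifs: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    polyA_runs: list[tuple[str, int, int]] = field(default_factory=list)
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    element_annotations: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    seed: int = 0

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def gc(self) -> float:
        return gc_fraction("".join(self.sequences.values()))

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the requested strand (5'->3')."""
        s = self.sequences[chrom][max(start, 0) : end]
        return s if strand == "+" else revcomp(s)

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulator.

    ``breaks`` holds planted (chrom, pos, strand) SSBs where ``pos`` is the
    0-based coordinate of the 3'-OH terminal base on the broken strand.
    ``artifact_sites`` records where internal-priming reads were generated.
    ``per_read_origin`` maps every emitted read-pair id to one of
    ``break | artifact | background``.
    """

    breaks: list[tuple[str, int, str]] = field(default_factory=list)
    artifact_sites: list[tuple[str, int, str]] = field(default_factory=list)
    per_read_origin: dict[str, str] = field(default_factory=dict)

    def break_set(self) -> set[tuple[str, int, str]]:
        return set(self.breaks)


@dataclass
class LibraryConfig:
    """Tunable parameters of a simulated sequencing library.

    ``fragment_size_range`` defaults to 150-500 bp, the bulk of the
    nuclease-digest size distribution.  ``artifact_rate`` is the expected
    number of internal-priming reads per true break.  ``corrupt_fraction``
    sends one random base of that fraction of reads to Phred 20 to exercise
    the strict quality filter (which requires > 20 everywhere).
    """

    read_length: int = 50
    fragment_size_range: tuple[int, int] = (150, 500)
    substitution_error_rate: float = 0.0
    artifact_rate: float = 0.0
    background_rate: float = 0.0
    tailed: bool = True
    chemistry: str = "ILM"
    seed: int = 0
    sms_length_range: tuple[int, int] = (25, 60)
    quality: int = 30
    corrupt_fraction: float = 0.0
    corrupt_quality: int = 20

    def __post_init__(self) -> None:
        if self.chemistry not in ("ILM", "SMS"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        for name in ("substitution_error_rate", "artifact_rate",
                     "background_rate", "corrupt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        fmin, fmax = self.fragment_size_range
        if fmin > fmax or fmin < 1:
            raise ValueError("invalid fragment_size_range")
        if self.chemistry == "ILM":
            # a fragment must carry the genomic portions of both mates
            need = max(self.read_length - G_PREFIX, self.read_length - T_PREFIX)
            if fmin < need:
                raise ValueError(
                    f"fragment min {fmin} shorter than genomic read portion {need}"
                )


@dataclass
class FastqRead:
    id: str
    sequence: str
    qualities: list[int]


@dataclass
class LibraryResult:
    """Reads plus per-read origin bookkeeping from one simulated library."""

    reads1: list[FastqRead]
    reads2: list[FastqRead] | None  # None for single-end chemistry
    origin: dict[str, str]
    artifact_sites: list[tuple[str, int, str]] = field(default_factory=list)
    resampled_fragments: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.reads1)

    def counts_by_origin(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.origin.values():
            out[v] = out.get(v, 0) + 1
        return out


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def make_genome(
    seed: int,
    lengths: dict[str, int],
    gc: float = 0.41,
    motifs: list[tuple[str, int, str, str, str]] | None = None,
    polyA_runs: list[tuple[str, int, int]] | None = None,
    repeats: list[tuple[str, int, int]] | None = None,
    elements: dict[str, list[tuple[str, int, int]]] | None = None,
) -> SyntheticGenome:
    """Generate a random genome with planted features.

    Parameters
    ----------
    lengths
        chromosome name -> length in bases.
    gc
        target GC fraction of the random background, in (0, 1).
    motifs
        plans ``(chrom, start, motif_sequence, strand, label)``; the motif
        (or its reverse complement for '-') is written verbatim at
        [start, start + len(motif)).
    polyA_runs
        plans ``(chrom, start, run_length)``; an A-homopolymer is written at
        [start, start + run_length) on the plus strand.
    repeats, elements
        annotation-only intervals ``(chrom, start, end)``; the underlying
        sequence is left random.

    Sequence-altering features (motifs, polyA runs) must fit inside their
    chromosome and must not overlap one another; collisions are rejected
    with a message naming the colliding intervals.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"GC fraction must be in (0, 1), got {gc}")
    for chrom, L in lengths.items():
        if L <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {L}")

    motifs = motifs or []
    polyA_runs = polyA_runs or []
    repeats = list(repeats or [])
    elements = {k: list(v) for k, v in (elements or {}).items()}

    planted: list[tuple[str, int, int, str]] = []  # (chrom, start, end, what)
    for chrom, start, motif, strand, label in motifs:
        planted.append((chrom, start, start + len(motif), f"motif:{label}"))
    for chrom, start, run_len in polyA_runs:
        planted.append((chrom, start, start + run_len, "polyA"))
    for chrom, start, end, what in planted:
        if chrom not in lengths:
            raise ValueError(f"{what} planted on unknown chromosome {chrom}")
        if start < 0 or end > lengths[chrom]:
            raise ValueError(f"{what} [{start}, {end}) outside {chrom} bounds")
    for i in range(len(planted)):
        for j in range(i + 1, len(planted)):
            a, b = planted[i], planted[j]
            if a[0] == b[0] and intervals_overlap(a[1], a[2], b[1], b[2]):
                raise ValueError(
                    "planted features overlap: "
                    f"{a[3]} {a[0]}:[{a[1]},{a[2]}) vs {b[3]} {b[0]}:[{b[1]},{b[2]})"
                )

    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for chrom, L in lengths.items():
        arrays[chrom] = _random_sequence(rng, L, gc)

    motif_records: list[tuple[str, int, int, str, str]] = []
    for chrom, start, motif, strand, label in motifs:
        written = motif if strand == "+" else revcomp(motif)
        arrays[chrom][start : start + len(motif)] = seq_to_array(written)
        motif_records.append((chrom, start, start + len(motif), strand, label))
    polya_records: list[tuple[str, int, int]] = []
    for chrom, start, run_len in polyA_runs:
        arrays[chrom][start : start + run_len] = ord("A")
        polya_records.append((chrom, start, start + run_len))

    for chrom in lengths:
        sequences[chrom] = arrays[chrom].tobytes().decode("ascii")

    return SyntheticGenome(
        sequences=sequences,
        planted_motifs=motif_records,
        polyA_runs=polya_records,
        repeat_intervals=repeats,
        element_annotations=elements,
        seed=seed,
    )


def _a_run_lengths_ending_at(arr: np.ndarray, base: int) -> np.ndarray:
    """run[i] = length of the maximal run of ``base`` ending at i (inclusive)."""
    is_b = arr == base
    run = np.zeros(len(arr), dtype=np.int32)
    # vectorized run-length: positions where run restarts
    idx = np.arange(len(arr))
    last_non = np.where(~is_b, idx, -1)
    last_non = np.maximum.accumulate(last_non)
    run = np.where(is_b, idx - last_non, 0)
    return run


def _eligible_mask(
    genome: SyntheticGenome,
    chrom: str,
    strand: str,
    edge_margin: int,
    non_a_terminal: bool,
    avoid_priming_contexts: bool,
    avoid_repeats: bool,
    priming_window: int = 20,
    priming_max: int = 8,
) -> np.ndarray:
    """Boolean mask of positions where a recoverable break may be planted.

    A position is eligible when it is far enough from the contig ends to
    carry a full fragment, its terminal base on the broken strand is not A
    (the oligo-dT anchor would otherwise shift the apparent break), the
    20-base continuation 5'-ward of the tail is not A-rich enough to trip
    the internal-priming filter, and it does not fall in an annotated
    repeat.
    """
    arr = seq_to_array(genome.sequences[chrom])
    L = len(arr)
    mask = np.zeros(L, dtype=bool)
    if L <= 2 * edge_margin:
        return mask
    mask[edge_margin : L - edge_margin] = True

    if non_a_terminal:
        terminal = arr == (ord("A") if strand == "+" else ord("T"))
        mask &= ~terminal

    if avoid_priming_contexts:
        # count of A (on the broken strand) in the 20 bases past the break
        target = ord("A") if strand == "+" else ord("T")
        is_t = (arr == target).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(is_t)])
        counts = np.zeros(L, dtype=np.int32)
        if strand == "+":
            # window genome[pos+1 : pos+1+w]
            hi = np.minimum(np.arange(L) + 1 + priming_window, L)
            lo = np.minimum(np.arange(L) + 1, L)
        else:
            # window genome[pos-w : pos]
            lo = np.maximum(np.arange(L) - priming_window, 0)
            hi = np.maximum(np.arange(L), 0)
        counts = cs[hi] - cs[lo]
        mask &= counts <= priming_max

    if avoid_repeats:
        for rc, rs, re in genome.repeat_intervals:
            if rc == chrom:
                mask[rs:re] = False
    return mask


def simulate_breaks(
    genome: SyntheticGenome,
    n: int | None = None,
    positions: list[tuple[str, int, str]] | None = None,
    element_rates: dict[str, float] | None = None,
    seed: int = 0,
    edge_margin: int = 600,
    non_a_terminal: bool = True,
    avoid_priming_contexts: bool = True,
    avoid_repeats: bool = True,
) -> SyntheticTruth:
    """Plant SSBs, either from an explicit list or at random.

    Random placement is i.i.d. over eligible positions with relative rates
    taken from ``element_rates`` (element label -> rate relative to the
    background rate of 1).  Both strands are equally likely.  Explicit
    ``positions`` are reproduced verbatim (no eligibility screening).
    """
    if positions is not None:
        for chrom, pos, strand in positions:
            if chrom not in genome.sequences:
                raise ValueError(f"break on unknown chromosome {chrom}")
            if not 0 <= pos < genome.length(chrom):
                raise ValueError(f"break position {chrom}:{pos} out of bounds")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
        return SyntheticTruth(breaks=list(positions))

    if n is None:
        raise ValueError("either n or positions is required")
    if element_rates and any(r < 0 for r in element_rates.values()):
        raise ValueError("element rates must be >= 0")

    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    breaks: list[tuple[str, int, str]] = []

    # per (chrom, strand) weight arrays
    weights: list[tuple[str, str, np.ndarray]] = []
    for chrom in chroms:
        for strand in "+-":
            mask = _eligible_mask(
                genome, chrom, strand, edge_margin, non_a_terminal,
                avoid_priming_contexts, avoid_repeats,
            )
            w = mask.astype(np.float64)
            if element_rates:
                for label, rate in element_rates.items():
                    for ec, es, ee in genome.element_annotations.get(label, []):
                        if ec == chrom:
                            w[es:ee] *= rate
            weights.append((chrom, strand, w))

    totals = np.array([w.sum() for _, _, w in weights])
    if totals.sum() <= 0:
        raise ValueError("no eligible break positions under the given constraints")
    n_eligible = sum(int((w > 0).sum()) for _, _, w in weights)
    if n > n_eligible:
        raise ValueError(f"requested {n} breaks but only {n_eligible} eligible positions")

    counts = rng.multinomial(n, totals / totals.sum())
    for (chrom, strand, w), k in zip(weights, counts):
        if k == 0:
            continue
        p = w / w.sum()
        pos = rng.choice(len(w), size=k, p=p)
        breaks.extend((chrom, int(x), strand) for x in pos)
    rng.shuffle(breaks)
    return SyntheticTruth(breaks=breaks)


def find_artifact_sites(
    genome: SyntheticGenome, min_run: int = 9
) -> list[tuple[str, int, str]]:
    """Pseudo-break sites at genomic A-runs where internal priming can occur.

    A plus-strand site is the base immediately 5' of an A-run of length >=
    ``min_run`` on the plus strand (the oligo-dT primes on the run itself, so
    the apparent 3'-OH terminal base is the first non-A base before it); a
    minus-strand site mirrors this at T-runs.  With ``min_run`` >= 9 the
    20-base upstream window of the resulting alignment has T-fraction >= 0.45,
    guaranteeing removal by the >40% internal-priming filter.
    """
    sites: list[tuple[str, int, str]] = []
    for chrom, seq in genome.sequences.items():
        arr = seq_to_array(seq)
        for strand, base in (("+", ord("A")), ("-", ord("T"))):
            run = _a_run_lengths_ending_at(arr, base)
            L = len(arr)
            if strand == "+":
                # run ends at i with length >= min_run; site = start-1
                ends = np.nonzero(
                    (run >= min_run)
                    & np.concatenate([(arr[1:] != base), [True]])
                )[0]
                for e in ends:
                    site = int(e) - int(run[e])
                    if site >= 0:
                        sites.append((chrom, site, "+"))
            else:
                ends = np.nonzero(
                    (run >= min_run)
                    & np.concatenate([(arr[1:] != base), [True]])
                )[0]
                for e in ends:
                    site = int(e) + 1
                    if site < L:
                        sites.append((chrom, site, "-"))
    return sites


def _terminal_a_shift(genome: SyntheticGenome, chrom: str, pos: int, strand: str) -> int:
    """Length of the maximal A-run ending at the break's 3'-OH terminal base.

    When a break terminates in A's, the anchored oligo-dT cannot distinguish
    them from the added tail and the first genomic base of the break-proximal
    read shifts upstream past the run; the returned shift is 0 for non-A
    terminal breaks.
    """
    seq = genome.sequences[chrom]
    shift = 0
    if strand == "+":
        i = pos
        while i >= 0 and seq[i] == "A":
            shift += 1
            i -= 1
    else:
        i = pos
        L = len(seq)
        while i < L and seq[i] == "T":
            shift += 1
            i += 1
    return shift


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = seq_to_array(seq).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _make_quals(rng: np.random.Generator, length: int, cfg: LibraryConfig) -> list[int]:
    quals = [cfg.quality] * length
    if cfg.corrupt_fraction > 0 and rng.random() < cfg.corrupt_fraction:
        quals[int(rng.integers(length))] = cfg.corrupt_quality
    return quals


def _sample_artifact_channel(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    cfg: LibraryConfig,
    rng: np.random.Generator,
    n_artifact_reads: int | None,
) -> list[tuple[str, int, str]]:
    if n_artifact_reads is None:
        n_artifact_reads = int(round(cfg.artifact_rate * len(truth.breaks)))
    if n_artifact_reads == 0:
        return []
    pool = find_artifact_sites(genome)
    # keep sites far enough from contig ends for any fragment / read to fit
    margin = max(cfg.fragment_size_range[1], cfg.sms_length_range[1] + 1)
    pool = [
        (c, p, s) for c, p, s in pool
        if margin <= p < genome.length(c) - margin
    ]
    if not pool:
        raise ValueError("artifact reads requested but the genome has no "
                         "usable A-runs >= 9")
    idx = rng.integers(len(pool), size=n_artifact_reads)
    chosen = [pool[i] for i in idx]
    truth.artifact_sites.extend(sorted(set(chosen)))
    return chosen


def _ilm_pair_for_break(
    genome: SyntheticGenome,
    chrom: str,
    pos: int,
    strand: str,
    cfg: LibraryConfig,
    rng: np.random.Generator,
    honor_anchor_shift: bool,
) -> tuple[str, str] | None:
    """Sequences (read1, read2) for one tailed molecule, or None if no
    fragment fits.  ``pos`` is the 3'-OH terminal base on ``strand``."""
    seq = genome.sequences[chrom]
    L = len(seq)
    rl = cfg.read_length
    w2 = rl - T_PREFIX  # genomic portion of read 2
    w1 = rl - G_PREFIX  # genomic portion of read 1
    fmin, fmax = cfg.fragment_size_range

    if honor_anchor_shift:
        pos = pos - _terminal_a_shift(genome, chrom, pos, strand) if strand == "+" else \
            pos + _terminal_a_shift(genome, chrom, pos, strand)

    for _ in range(50):
        frag = int(rng.integers(fmin, fmax + 1))
        if strand == "+":
            fs, fe = pos + 1 - frag, pos + 1
            if fs < 0 or fe - fs < max(w1, w2):
                continue
            read2 = "T" * T_PREFIX + revcomp(seq[pos + 1 - w2 : pos + 1])
            read1 = "G" * G_PREFIX + seq[fs : fs + w1]
        else:
            fs, fe = pos, pos + frag
            if fe > L or fe - fs < max(w1, w2):
                continue
            read2 = "T" * T_PREFIX + seq[pos : pos + w2]
            read1 = "G" * G_PREFIX + revcomp(seq[fe - w1 : fe])
        return read1, read2
    return None


def build_ilm_library(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    cfg: LibraryConfig,
    read_prefix: str = "ilm",
    n_artifact_reads: int | None = None,
    honor_anchor_shift: bool = False,
) -> LibraryResult:
    """Paired-end reads for the tailed/amplified chemistry.

    Each sampled true break at base Z on strand s yields a face-to-face pair
    within one fragment: read 2 is 12 T's plus the reverse complement of the
    genomic window on s ending at and including Z; read 1 is 10 G's plus the
    sense sequence from the fragment's nuclease end toward the break.  With
    ``cfg.tailed`` False, only artifact/background reads are emitted.
    ``honor_anchor_shift`` enables the documented A-terminal-break bias
    (the dT-V-N anchor slides past a terminal A-run).
    """
    if cfg.chemistry != "ILM":
        raise ValueError("build_ilm_library requires chemistry='ILM'")
    rng = np.random.default_rng(cfg.seed)
    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []
    origin: dict[str, str] = {}
    resampled = 0

    channels: list[tuple[str, tuple[str, int, str]]] = []
    if cfg.tailed:
        channels += [("break", b) for b in truth.breaks]
    art_sites = _sample_artifact_channel(genome, truth, cfg, rng, n_artifact_reads)
    channels += [("artifact", s) for s in art_sites]

    for i, (label, (chrom, pos, strand)) in enumerate(channels):
        made = _ilm_pair_for_break(
            genome, chrom, pos, strand, cfg, rng, honor_anchor_shift
        )
        if made is None:
            resampled += 1
            continue
        r1, r2 = made
        r1 = _apply_errors(rng, r1, cfg.substitution_error_rate)
        r2 = _apply_errors(rng, r2, cfg.substitution_error_rate)
        rid = f"{read_prefix}:{i}"
        reads1.append(FastqRead(rid + "/1", r1, _make_quals(rng, len(r1), cfg)))
        reads2.append(FastqRead(rid + "/2", r2, _make_quals(rng, len(r2), cfg)))
        origin[rid] = label

    n_background = int(round(cfg.background_rate * max(len(truth.breaks), 1)))
    for j in range(n_background):
        chrom = list(genome.sequences)[int(rng.integers(len(genome.sequences)))]
        L = genome.length(chrom)
        s = int(rng.integers(0, max(L - cfg.read_length, 1)))
        frag = genome.sequences[chrom][s : s + cfg.read_length]
        rid = f"{read_prefix}:bg{j}"
        reads1.append(FastqRead(rid + "/1", frag, _make_quals(rng, len(frag), cfg)))
        reads2.append(FastqRead(rid + "/2", revcomp(frag), _make_quals(rng, len(frag), cfg)))
        origin[rid] = "background"

    truth.per_read_origin.update(origin)
    return LibraryResult(reads1, reads2, origin,
                         artifact_sites=art_sites, resampled_fragments=resampled)


def build_sms_library(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    cfg: LibraryConfig,
    read_prefix: str = "sms",
    n_artifact_reads: int | None = None,
) -> LibraryResult:
    """Single-end reads for the single-molecule chemistry.

    The fill-and-lock step consumes (does not read) the first template base
    after the polyA tail, so each break-derived read is the reverse
    complement of the genomic window ending one base 5' of the break base on
    the broken strand; the break base itself is skipped.  Read lengths are
    drawn uniformly from ``cfg.sms_length_range``.
    """
    if cfg.chemistry != "SMS":
        raise ValueError("build_sms_library requires chemistry='SMS'")
    rng = np.random.default_rng(cfg.seed)
    reads: list[FastqRead] = []
    origin: dict[str, str] = {}
    resampled = 0
    lmin, lmax = cfg.sms_length_range

    channels: list[tuple[str, tuple[str, int, str]]] = []
    if cfg.tailed:
        channels += [("break", b) for b in truth.breaks]
    art_sites = _sample_artifact_channel(genome, truth, cfg, rng, n_artifact_reads)
    channels += [("artifact", s) for s in art_sites]

    for i, (label, (chrom, pos, strand)) in enumerate(channels):
        seq = genome.sequences[chrom]
        L = len(seq)
        made = None
        for _ in range(50):
            rl = int(rng.integers(lmin, lmax + 1))
            if strand == "+":
                if pos - rl < 0:
                    continue
                made = revcomp(seq[pos - rl : pos])  # window excludes the break base
            else:
                if pos + 1 + rl > L:
                    continue
                made = seq[pos + 1 : pos + 1 + rl]
            break
        if made is None:
            resampled += 1
            continue
        made = _apply_errors(rng, made, cfg.substitution_error_rate)
        rid = f"{read_prefix}:{i}"
        reads.append(FastqRead(rid, made, _make_quals(rng, len(made), cfg)))
        origin[rid] = label

    n_background = int(round(cfg.background_rate * max(len(truth.breaks), 1)))
    for j in range(n_background):
        chrom = list(genome.sequences)[int(rng.integers(len(genome.sequences)))]
        L = genome.length(chrom)
        rl = int(rng.integers(lmin, lmax + 1))
        s = int(rng.integers(0, max(L - rl, 1)))
        rid = f"{read_prefix}:bg{j}"
        reads.append(FastqRead(rid, genome.sequences[chrom][s : s + rl],
                               _make_quals(rng, rl, cfg)))
        origin[rid] = "background"

    truth.per_read_origin.update(origin)
    return LibraryResult(reads, None, origin,
                         artifact_sites=art_sites, resampled_fragments=resampled)
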