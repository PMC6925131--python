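"""End-to-end convenience drivers: raw reads -> filtered -> aligned ->
called -> filtered BreakSet, with per-stage accounting.

These wire the per-module operations together in the documented order:
structure/quality filtering, alignment (fixture exact aligner or ingested
SAM/BAM), SSB calling, internal-priming filter, un-tailed control
subtraction, repeat masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import exact_align, pair_alignments
from .breakcall import (
    BreakSet,
    SSBCall,
    call_ssbs,
    collapse,
    internal_priming_filter,
    mask_repeats,
    subtract_control,
)
from .readproc import FilterStats, filter_ilm_pairs, filter_sms_reads
from .sim import FastqRead, SyntheticGenome

__all__ = ["PipelineResult", "run_ilm_pipeline", "run_sms_pipeline"]


@dataclass
class PipelineResult:
    breaks: BreakSet
    read_calls: list[SSBCall]
    stage_stats: dict[str, FilterStats] = field(default_factory=dict)
    control_removed: int = 0
    repeats_removed: int = 0

    @property
    def conserved(self) -> bool:
        """Every stage's accounting must balance."""
        return all(s.conserved for s in self.stage_stats.values()) and \
            self.breaks.conserved


def _ilm_read_calls(
    genome: SyntheticGenome,
    reads1: list[FastqRead],
    reads2: list[FastqRead],
    min_phred: int,
    max_insert: int,
    sample_id: str | None,
    stage_stats: dict[str, FilterStats],
    tag: str,
) -> list[SSBCall]:
    pairs_in = list(zip(reads1, reads2))
    trimmed, fs = filter_ilm_pairs(pairs_in, min_phred=min_phred)
    stage_stats[f"{tag}:read_filter"] = fs
    flat: list[FastqRead] = []
    for tp in trimmed:
        flat.append(tp.read1_trimmed)
        flat.append(tp.read2_trimmed)
    records, astats = exact_align(flat, genome, mode="unique_only")
    stage_stats[f"{tag}:align"] = astats
    pairs, pstats = pair_alignments(records, max_insert=max_insert)
    stage_stats[f"{tag}:pairing"] = pstats
    calls, cstats = call_ssbs(pairs, chemistry="ILM", sample_id=sample_id)
    stage_stats[f"{tag}:call"] = cstats
    kept, ipstats = internal_priming_filter(calls, genome)
    stage_stats[f"{tag}:internal_priming"] = ipstats
    return kept


def run_ilm_pipeline(
    genome: SyntheticGenome,
    reads1: list[FastqRead],
    reads2: list[FastqRead],
    control_reads1: list[FastqRead] | None = None,
    control_reads2: list[FastqRead] | None = None,
    repeats: list[tuple[str, int, int]] | None = None,
    sample_id: str | None = None,
    min_phred: int = 21,
    max_insert: int = 1000,
) -> PipelineResult:
    """Full paired-end pipeline on fixture-aligned reads.

    The un-tailed control reads, when given, run through the identical
    filter/align/call/priming chain before strand- and base-exact
    subtraction; repeat masking runs last.
    """
    stage_stats: dict[str, FilterStats] = {}
    kept = _ilm_read_calls(genome, reads1, reads2, min_phred, max_insert,
                           sample_id, stage_stats, "sample")
    bs = collapse(kept, sample_id=sample_id)
    control_removed = 0
    if control_reads1 is not None:
        ctrl_calls = _ilm_read_calls(genome, control_reads1, control_reads2 or [],
                                     min_phred, max_insert, None,
                                     stage_stats, "control")
        ctrl = collapse(ctrl_calls)
        bs, control_removed = subtract_control(bs, ctrl)
    repeats_removed = 0
    if repeats is not None:
        bs, repeats_removed = mask_repeats(bs, repeats)
    return PipelineResult(bs, kept, stage_stats, control_removed, repeats_removed)


def _sms_read_calls(
    genome: SyntheticGenome,
    reads: list[FastqRead],
    min_len: int,
    sample_id: str | None,
    stage_stats: dict[str, FilterStats],
    tag: str,
    mode: str = "unique_only",
    seed: int | None = None,
) -> list[SSBCall]:
    kept_reads, fs = filter_sms_reads(reads, min_len=min_len)
    stage_stats[f"{tag}:read_filter"] = fs
    records, astats = exact_align(kept_reads, genome, mode=mode, seed=seed)
    stage_stats[f"{tag}:align"] = astats
    calls, cstats = call_ssbs(records, chemistry="SMS",
                              chrom_lengths=genome.chrom_lengths,
                              sample_id=sample_id)
    stage_stats[f"{tag}:call"] = cstats
    kept, ipstats = internal_priming_filter(calls, genome)
    stage_stats[f"{tag}:internal_priming"] = ipstats
    return kept


def run_sms_pipeline(
    genome: SyntheticGenome,
    reads: list[FastqRead],
    control_reads: list[FastqRead] | None = None,
    repeats: list[tuple[str, int, int]] | None = None,
    sample_id: str | None = None,
    min_len: int = 25,
    mode: str = "unique_only",
    seed: int | None = None,
) -> PipelineResult:
    """Full single-end pipeline on fixture-aligned reads."""
    stage_stats: dict[str, FilterStats] = {}
    kept = _sms_read_calls(genome, reads, min_len, sample_id, stage_stats,
                           "sample", mode, seed)
    bs = collapse(kept, sample_id=sample_id)
    control_removed = 0
    if control_reads is not None:
        ctrl_calls = _sms_read_calls(genome, control_reads, min_len, None,
                                     stage_stats, "control", mode, seed)
        ctrl = collapse(ctrl_calls)
        bs, control_removed = subtract_control(bs, ctrl)
    repeats_removed = 0
    if repeats is not None:
        bs, repeats_removed = mask_repeats(bs, repeats)
    return PipelineResult(bs, kept, stage_stats, control_removed, repeats_removed)
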