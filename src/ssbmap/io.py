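"""Readers and writers for the standard text formats the pipeline touches.

FASTA via pyfaidx, FASTQ via Biopython (gzip-capable), BED via pandas,
SAM/BAM in :mod:`ssbmap.align` via pysam.  The VCF reader is a minimal
plain-text parser extracting position, REF/ALT class and the AF INFO field,
which is all the variant-overlap analysis consumes.
"""

from __future__ import annotations

import gzip
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from pyfaidx import Fasta

from .breakcall import BreakSet, SSBCall
from .sim import FastqRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "breakset_to_bed",
    "breakset_from_bed",
    "truth_to_bed",
    "read_vcf_records",
]


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str) -> dict[str, str]:
    with Fasta(str(path), build_index=True, rebuild=False) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str) -> list[FastqRead]:
    with _open_text(path) as fh:
        return [
            FastqRead(rec.id, str(rec.seq),
                      list(rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[FastqRead], path: str) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_bed(path: str) -> pd.DataFrame:
    """BED3-6 as a DataFrame with canonical column names."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(rows: Iterable[tuple], path: str) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def breakset_to_bed(breaks: BreakSet, path: str) -> None:
    """BED6: name = sample id, score = read count, strand = broken strand."""
    write_bed(
        (
            (c.chrom, c.start, c.end, c.sample_id or ".", c.read_count, c.strand)
            for c in breaks.sorted_calls()
        ),
        path,
    )


def breakset_from_bed(path: str, sample_id: str | None = None) -> BreakSet:
    df = read_bed(path)
    bs = BreakSet(sample_id=sample_id, provenance=["from_bed"])
    for row in df.itertuples(index=False):
        count = int(getattr(row, "score", 1))
        call = SSBCall(row.chrom, int(row.start), row.strand,
                       read_count=count, sample_id=sample_id)
        bs.calls[call.key] = call
    bs.total_filtered_reads = sum(c.read_count for c in bs.calls.values())
    return bs


def truth_to_bed(breaks: Iterable[tuple[str, int, str]], path: str,
                 name: str = "break") -> None:
    """Planted truth as BED6 single-base intervals."""
    write_bed(
        ((chrom, pos, pos + 1, name, 1, strand)
         for chrom, pos, strand in sorted(breaks)),
        path,
    )


def read_vcf_records(path: str) -> list[tuple[str, int, str, float]]:
    """(chrom, pos0, type, allele_frequency) from a plain-text VCF.

    ``type`` is SNP when REF and every ALT are single bases, else indel.
    AF comes from the AF INFO field (first value for multi-allelic sites);
    records without AF get NaN.
    """
    out: list[tuple[str, int, str, float]] = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alt = fields[:5]
            info = fields[7] if len(fields) > 7 else ""
            vtype = "SNP" if len(ref) == 1 and all(
                len(a) == 1 for a in alt.split(",")) else "indel"
            af = float("nan")
            for kv in info.split(";"):
                if kv.startswith("AF="):
                    af = float(kv[3:].split(",")[0])
                    break
            out.append((chrom, int(pos) - 1, vtype, af))
    return out
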