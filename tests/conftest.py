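import numpy as np
import pytest
from hypothesis import settings

from ssbmap import sim
from ssbmap.breakcall import BreakSet, SSBCall

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_breakset(records, sample_id=None):
    """BreakSet from (chrom, pos, strand[, read_count]) tuples."""
    bs = BreakSet(sample_id=sample_id)
    for rec in records:
        chrom, pos, strand = rec[0], rec[1], rec[2]
        count = rec[3] if len(rec) > 3 else 1
        call = SSBCall(chrom, pos, strand, read_count=count, sample_id=sample_id)
        if call.key in bs.calls:
            bs.calls[call.key].read_count += count
        else:
            bs.calls[call.key] = call
    bs.total_filtered_reads = sum(c.read_count for c in bs.calls.values())
    return bs


@pytest.fixture(scope="session")
def genome_small():
    """60 kb + 30 kb two-chromosome genome with planted features."""
    return sim.make_genome(
        seed=11,
        lengths={"chrA": 60_000, "chrB": 30_000},
        gc=0.41,
        motifs=[("chrA", 20_000 + 500 * i, "CCTCAGC", "+", "nick")
                for i in range(10)],
        polyA_runs=[("chrA", 40_000, 12), ("chrA", 45_000, 15)],
        repeats=[("chrA", 50_000, 52_000)],
        elements={"promoter": [("chrA", 10_000, 12_000)]},
    )


@pytest.fixture(scope="session")
def genome_1mb():
    """The end-to-end recovery genome: 1 Mb with A-runs for artifacts."""
    return sim.make_genome(
        seed=101,
        lengths={"chrA": 1_000_000},
        gc=0.41,
        polyA_runs=[("chrA", 100_000 + 3_000 * i, 12) for i in range(40)],
    )


@pytest.fixture(scope="session")
def truth_1mb(genome_1mb):
    return sim.simulate_breaks(genome_1mb, n=1000, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
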