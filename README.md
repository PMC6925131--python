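# ssbmap

Nucleotide-resolution mapping of single-strand DNA breaks (SSBs) from
polyA-tailed sequencing libraries, with a full "breakome" statistics suite
and a synthetic-data simulator that makes the entire pipeline testable with
known ground truth.

## The problem

SSBs are the most common form of DNA damage: free 3′-OH termini left by
oxidative damage, repair intermediates, and enzymes such as topoisomerases.
They can be tagged biochemically by adding an untemplated polyA tail to the
3′-OH with terminal transferase (TdT) after micrococcal-nuclease (MNase)
fragmentation — MNase leaves 3′-P ends, invisible to TdT, so only genuine
breaks get tails. Sequencing the tailed molecules places each break at a
single base on a single strand. `ssbmap` implements the computational half
of that experiment for two library chemistries:

- **ILM** (paired-end, PCR-amplified): read 1 starts with 10 G's from the
  polyC-tail primer, read 2 with 12 T's from the oligo-dT primer; the SSB is
  the first base after the T-run of read 2, on the strand opposite the
  read 2 alignment.
- **SMS** (single-molecule, amplification-free): the fill-and-lock step
  consumes one unsequenced template base after the tail, so the alignment's
  5′ coordinate is extended by 1: a `+` alignment `[s, e)` yields the SSB
  `[s−1, s)` on `−`, a `−` alignment yields `[e, e+1)` on `+`
  (all coordinates BED-style 0-based half-open).

Three artifact filters follow calling: reads whose upstream 20-mer on the
alignment strand is >40% T are removed as oligo-dT **internal priming** on
genomic A-runs; breaks present in the **un-tailed control** are subtracted
(strand- and base-exact); breaks in annotated **repeats** are masked.

## The statistics

For `k` of `n` breaks falling in an element of length `L_e` on a background
of length `L_bg`, enrichment is summarized by the odds ratio

```
OR = (k / (n − k)) / (L_e / (L_bg − L_e))
```

with a two-sided exact binomial p-value against `p₀ = L_e / L_bg` and a 95%
CI from the Clopper–Pearson interval on `k/n` transformed to OR scale. The
suite also provides template/non-template strand asymmetry per region class,
replication-timing and nucleosome-track comparisons (two-sided Wilcoxon
rank-sum), variant-proximity enrichment in ±0/2/5/10 bp windows,
conservation-score profiles in ±5/10/20 bp windows, per-base site profiles
around nickase motifs, normalized per-position scores
(`breaks at position × 10⁹ / total breaks`), detection-sensitivity and
library-complexity subsampling curves, hotspot partitioning (≥4 reads),
hypergeometric gene-set over-representation with Benjamini–Hochberg
adjustment, per-gene-strand break-density matrices
(`breaks / (gene kb × sample total) × 10⁶`) with PCA, and logistic/linear
age models reporting accuracy, AUC, McFadden pseudo-R², and fitted-vs-true
Pearson r.

## Worked example

Simulate a 500 kb genome with a promoter annotation, plant 400 breaks at a
3× promoter rate, build an error-free paired-end library plus 40
internal-priming artifact reads, run the full pipeline, and test promoter
enrichment:

```python
from ssbmap import sim, pipeline
from ssbmap.stats import element_enrichment

genome = sim.make_genome(
    seed=7, lengths={"chrA": 500_000}, gc=0.41,
    elements={"promoter": [("chrA", 100_000, 150_000)]},
)
truth = sim.simulate_breaks(genome, n=400,
                            element_rates={"promoter": 3.0}, seed=8)
library = sim.build_ilm_library(
    genome, truth, sim.LibraryConfig(chemistry="ILM", seed=9),
    n_artifact_reads=40)
result = pipeline.run_ilm_pipeline(
    genome, library.reads1, library.reads2, sample_id="demo")

enr = element_enrichment(result.breaks,
                         genome.element_annotations["promoter"],
                         [("chrA", 0, 500_000)])
```

This prints (via the obvious f-strings):

```
planted breaks        : 399
recovered exactly     : 399
priming-filtered reads: 40
promoter enrichment   : OR=3.21 (95% CI 2.55-4.03), p=1.7e-20
```

Every planted break is recovered at the exact base and strand, all 40
artifact reads die at the T-fraction filter, and the enrichment CI covers
the planted 3× rate. (399 rather than 400 planted breaks: two i.i.d.
draws landed on the same position and collapse to one unique coordinate.)

The same flow is available from the shell:

```sh
ssb sim --config cfg.json --out sim/ --seed 7
ssb filter-reads --chemistry ilm --in1 sim/reads_1.fastq --in2 sim/reads_2.fastq \
    --out1 f1.fastq --out2 f2.fastq
ssb fixture-align --genome sim/genome.fa --reads f1.fastq --reads2 f2.fastq \
    --out aln.sam
ssb call --chemistry ilm --sam aln.sam --genome sim/genome.fa --out breaks.bed
ssb stats enrich --breaks-bed breaks.bed --element-bed element.bed \
    --background-bed background.bed
```

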