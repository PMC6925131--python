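# Methods

## The measurement being modeled

A single-strand break (SSB) is represented throughout as one genomic base —
the 3′-OH terminal base of the broken strand — in BED convention: 0-based,
half-open, single-base intervals `[b, b+1)` with an explicit strand. The
chemistry that justifies this: chromatin is fragmented with micrococcal
nuclease, whose 3′-P fragment ends cannot be tailed by terminal
transferase, so only pre-existing 3′-OH breaks receive polyA tails and
enter the library. The sequenced strand is the complement primed from the
tail, which is why every calling rule reports the break on the strand
opposite the alignment.

Two chemistries are implemented:

- **Paired-end (ILM).** Read 2 carries 12 read T's from the oligo-dT
  primer, then the complement of the broken strand read from the tail
  inward; its first genomic base sits on the break base. Read 1 carries
  10 G's from the polyC-tail primer, then the broken-strand sequence from
  the fragment's nuclease end toward the break. Calling: read 2 aligned
  `+` at `[s, e)` → SSB `[s, s+1)` on `−`; aligned `−` → `[e−1, e)` on `+`.
- **Single-molecule (SMS).** The fill-and-lock step consumes (does not
  read) the first template base after the tail, so the alignment's 5′
  coordinate is extended by one base: `+` alignment `[s, e)` → SSB
  `[s−1, s)` on `−`; `−` alignment → `[e, e+1)` on `+`. Extension past a
  contig boundary drops the call (clamping is the rejected alternative;
  a clamped call would misreport the break base).

## Filter chain and its order

1. **Read structure/quality (pre-alignment).** ILM pairs are kept iff
   read 1 begins with ≥10 G's, read 2 with ≥12 T's, and every base of both
   untrimmed reads has Phred > 20 (strict; a base at exactly 20 drops the
   pair). Drop reasons are assigned in the fixed order structure1,
   structure2, quality. Trimming removes exactly 10 bases from read 1 —
   base 11 may be a genomic G, and the H anchor of the primer makes it
   non-G on clean data anyway — and the *maximal* leading T-run of read 2,
   which coincides with fixed-12 trimming on clean data because of the V
   anchor but is robust to sequencing errors extending the run. SMS reads
   are kept iff length ≥ 25; platform-specific quality filtration is a
   caller-supplied predicate, not reimplemented.
2. **Alignment filters.** "Uniquely mapped" is operationalized for SAM/BAM
   input as mapped + primary + non-supplementary + MAPQ ≥ 20 (flag);
   pairing requires same chromosome, FR face-to-face orientation and
   insert ≤ 1000 bp (fragments are 150–500 bp, so 1000 leaves headroom).
   Records whose break-proximal 5′ terminus is soft/hard-clipped are
   dropped — a clipped terminus means the called base is not evidenced.
3. **Internal-priming filter (read-level).** Oligo-dT can prime on genomic
   A-runs instead of an added tail; such events look like breaks whose
   downstream sequence is A-rich on the broken strand, i.e. T-rich on the
   alignment strand. A call is removed iff the 20-base 5′-upstream window
   of its source alignment, on the alignment strand, has T-fraction
   strictly > 0.40. Windows truncated at contig ends use the available
   bases with the same fractional threshold (flag-selectable dropping);
   the affected genome fraction is negligible and this avoids positional
   bias.
4. **Un-tailed control subtraction (unique-coordinate level).** Exact on
   (chrom, base, strand); no window, since fuzzy subtraction would remove
   true breaks adjacent to control positions.
5. **Repeat masking.** Strand-blind half-open membership of the break base
   in the repeat intervals. Control subtraction and repeat masking
   commute (both are per-key set removals); the priming filter must
   precede both because it needs the source alignments.

All analyses except hotspot partitioning use unique (chrom, base, strand)
coordinates; read counts per coordinate are preserved for hotspots
(≥ 4 reads by default) and the subsampling curves.

## Statistics

- **Element enrichment.** `OR = (k/(n−k)) / (L_e/(L_bg−L_e))` (+∞ when
  k = n), two-sided exact binomial p against `p₀ = L_e/L_bg`, and a 95% CI
  from the Clopper–Pearson interval on k/n transformed monotonically to OR
  scale. The default background is the analysis background passed by the
  caller; because breaks are repeat-filtered upstream, genome-minus-repeats
  is the natural choice, with whole-genome available.
- **Strand asymmetry.** A break in a region of a `+`-strand gene is a
  template-strand break iff its strand is `−` (the template is the
  complement of the mRNA-like strand), mirrored for `−` genes. Bases
  annotated with genes on both strands are excluded by default (counting
  both ways is a flag) — they are unclassifiable without expression data.
- **Replication ratio.** Mean track value at break positions divided by the
  length-weighted background mean, per cell-cycle fraction; >1 is
  enrichment, <1 depletion.
- **Track comparison.** Two-sided Wilcoxon rank-sum of track values at
  breaks vs a seeded uniform background sample (default 10⁴ positions;
  explicit background positions accepted). The exact null is available for
  small tie-free samples.
- **Variant overlap.** A break hits a variant iff |Δpos| ≤ w for
  w ∈ {0, 2, 5, 10}, strand-blind; the null hit probability under uniform
  variant density ρ is `1 − (1−ρ)^(2w+1)`, tested with the exact binomial.
  AF classes follow population-genetics convention: common ≥ 0.05,
  low-frequency ≥ 0.005, rare < 0.005.
- **Conservation profiles.** Per break and ±w window (w ∈ {5, 10, 20}),
  the mean over strictly positive scores and the mean |score| over strictly
  negative scores (same-sign-only averaging; including zeros is the
  flagged alternative), plus the ratio of the window mean to the at-break
  score.
- **Site profiles / normalized scores.** Per-offset, per-strand fractions
  of a sample's total breaks around motif occurrences (minus-strand sites
  coordinate-flipped so offsets are motif-relative); normalized score =
  breaks at a position × 10⁹ / total breaks, which sums to 10⁹ over the
  genome exactly.
- **Subsampling curves.** Detection sensitivity subsamples read-level calls
  without replacement (seeded) and counts sites with ≥1 surviving call
  within ±1 base; complexity is unique coordinates ÷ depth. Both match
  hypergeometric/occupancy closed forms on toy models.
- **Gene selection and gene sets.** Promoters are assigned to the gene
  whose annotated 5′ end is nearest within 5 kb (deterministic name-order
  tie-break); genes with ≥3 unique breaks in assigned promoters (or exons)
  are selected against the promoter-assigned universe. Over-representation
  is a one-sided hypergeometric test with Benjamini–Hochberg adjustment
  across sets.
- **Breakome matrices and age models.** Densities are breaks per gene-kb
  per million sample breaks per (gene, strand) — invariant under read
  duplication by construction. PCA centers features (variance scaling is a
  flag; densities share units, so centering-only is the default). The age
  classifier is a maximum-likelihood logistic fit; reported accuracy/AUC/
  McFadden pseudo-R² are training-set by default, matching the in-sample
  character of small-cohort fits, with stratified k-fold out-of-fold
  metrics available (and used for permutation-null testing, where
  in-sample AUC is optimistic by construction). The age regressor is OLS;
  its headline number is the Pearson r between fitted and chronological
  age.

## The simulator

The simulator exists so that every downstream stage can be tested against
known truth. It emulates: random genomes at a target GC (default 0.41,
human-like) with planted motifs, polyA runs, repeat annotations, and
element annotations; planted breaks with known base and strand; both read
chemistries including the exact prefix structures; internal-priming
artifact reads generated at genomic A-runs of length ≥ 9 (which guarantees
upstream T-fraction ≥ 0.45, above the 0.40 filter threshold); un-tailed
controls (break channel silenced, artifact/background channels kept); flat
Phred-30 qualities with an optional one-base Phred-20 corruption channel;
and optional uniform substitution errors.

Key defaults and why:

- `fragment_size_range = (150, 500)` bp — the bulk of the MNase digest
  size distribution.
- ILM `read_length = 50` — long enough that trimmed genomic portions
  (38/40 nt) align uniquely in megabase-scale random genomes.
- SMS read lengths uniform on [25, 60] — a stand-in consistent with the
  ≥25-base filter; the true platform length distribution is not modeled.
- Default break placement excludes: positions whose terminal base is A
  (the anchored oligo-dT would shift the apparent break upstream past the
  terminal A-run; a flag enables A-terminal breaks with the shifted
  chemistry as a documented bias case); positions whose downstream 20-mer
  would trip the internal-priming filter (such breaks are by construction
  unrecoverable); annotated repeats (masked downstream); and a 600-bp
  contig-end margin so any fragment fits. For statistical calibration
  fixtures these screens are switched off, because there the object under
  test is the statistic, not the chemistry, and uniform placement is the
  correct null.
- MNase fragment ends are recorded but never emit tailed reads (3′-P is
  not a TdT substrate).

What the simulator does *not* model — hence what passing tests do not show
about real data: PCR duplicates and amplification bias, indel errors,
MNase sequence preference, crosslinking artifacts, chromatin accessibility,
and the biochemical noise that makes real site-level precision ~50% exact /
~90% within ±1 nt rather than the simulator's 100%.

## Numerical choices and degenerate inputs

- Strict inequalities where the rules state them: quality > 20, T-fraction
  > 0.40, hotspot ≥ 4, SMS length ≥ 25.
- Enrichment refuses degenerate geometry (element length 0 or equal to the
  background) and empty break sets, rather than returning NaN.
- Undefined strand-asymmetry ratios (zero non-template count) raise on
  access instead of silently returning infinity.
- The exact aligner used as a test fixture requires error-free reads; the
  multi-mapping mode selects one occurrence uniformly with a caller seed
  (mirroring randomly-chosen-alignment handling of repeat-class reads).
- DSB pairing default `max_gap = 2` bp; "all pairs" reporting by default,
  greedy nearest-partner assignment (left-to-right, ties left) as a mode.
- All stochastic operations take explicit seeds; identical (config, seed)
  reproduce byte-identical simulator output.

## Problem sizes used in the test suite

The end-to-end recovery check runs a 1 Mb genome with 1,000 planted breaks
and a 200-read artifact control; the calibration/power checks use 100 runs
of 10,000 breaks on a 1 Mb genome; oracle-equivalence checks use 100 random
instances of up to 10³ breaks × 10² intervals; subsampling closed forms use
100–200 seeded replicates of 100–400-read toy libraries; model-recovery
checks use cohorts of 40–66 synthetic samples. These sizes give stable
statistics while keeping the default test run in the low minutes on one
core.

## Known limitations

- The enrichment CI coverage bar in the power check (a 95% CI required to
  cover the planted value in ≥95% of 100 runs) is intrinsically marginal:
  the expected pass count is ~95.2 with standard deviation ~2.1.
- The AsiSI site-count check requires the GRCh37/hg19 reference, which is
  not distributable with the package; the motif scanner itself is
  oracle-tested on synthetic sequence.
- Alignment ingestion trusts the mapper's MAPQ for uniqueness; no
  realignment or XA-tag inspection is performed.
- The VCF reader extracts only position, SNP/indel class and AF; it is not
  a general-purpose VCF parser.
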