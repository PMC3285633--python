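# Methods

This note documents the models implemented in `mgsim`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions the code relies on.

## Community model and read allocation

A community is a rank-ordered vector of relative organism abundances
`a_1 ≥ a_2 ≥ … ≥ a_n`, summing to 1. Three shapes are built in:

* **uniform** — `a_i = 1/n`; a maximally even community.
* **geometric** — `a_i ∝ r^i`, `r ∈ (0, 1]`; the classic niche-preemption
  series. `r = 0.5` (default) spans ~3 orders of magnitude by rank 10.
* **lognormal** — abundances proportional to lognormal quantiles at the
  plotting positions `(i + 0.5)/n` with log-scale parameters `mu`, `sigma`
  (default 0, 1). Using quantiles instead of sorted random draws makes the
  curve deterministic, which keeps community construction and read
  sampling independently seedable.

User-supplied abundance vectors are accepted and normalized/sorted.

Shotgun sequencing samples DNA, not organisms, so the expected share of
reads for genome *i* is `a_i·L_i / Σ_j a_j·L_j` (`L` = genome length).
Fractional counts are converted to integers by the largest-remainder
method: totals are conserved exactly and every count is within one read of
its real-valued share. Ties in the remainder are broken by rank order for
determinism.

## Quality models

Per-base quality Q maps to error probability P through the odds form
`Q = −10·log₁₀(P/(1−P))`, i.e. `P = 1/(1+10^(Q/10))`. This is the
convention under which the empirical run qualities this design targets were
expressed; the standard Phred form `Q = −10·log₁₀P` is available through
`convention="standard"` everywhere a conversion happens. At Q20 the two
differ by about 1% relative (1/101 vs 1/100); at low Q they diverge
strongly (odds-Q0 means P = 0.5, standard-Q0 means P = 1).

A quality model is per-cycle:

* **empirical** — a histogram of observed quality values per cycle, built
  by pooling the c-th quality of every read of a run (`.qual` input, one
  profile per file). Sampling draws each cycle independently from its
  histogram.
* **parametric** — per-cycle (mean, sd); sampling draws
  `round(Normal(mean_c, sd_c))` clipped to [0, 93]. Values are encoded
  as Sanger Phred+33 in FASTQ, capped at 93 (ASCII `~`).

Runs can be clustered into a small set of representative models with
k-means on their per-cycle mean-quality vectors (Euclidean distance); the
number of clusters is a free parameter because real run collections do not
dictate one. Centroids become consensus parametric profiles whose per-cycle
sd is the mean of the members' sds. Parametric families for fitting a
per-cycle curve are `constant`, `linear_decay` (least squares on the
0-based cycle index) and `piecewise` (two joined lines, breakpoint by
exhaustive SSE search); per-cycle residuals are retained as sds so fitted
models remain sampleable.

Built-in defaults (used when no `.qual` files are supplied; parametric
stand-ins, not fits to any particular machine):

| platform | model | default |
|---|---|---|
| Illumina | linear decay | Q35 → Q25 over 75 cycles, sd 3 |
| Sanger | rise–plateau–fall | Q15→Q40 over first 100 bases, plateau, fall to Q15 after 85% of the read; sd 5 |
| pyro | constant | Q28, sd 3 |

## Read simulation

Read lengths: Illumina fixed (default 75 bp); Sanger `Normal(800, 100)`
truncated at 100 bp; pyro `Normal(255, 50)` truncated at 50 bp. The
truncation points are 4–7 sd below the means, so the sample mean is
unaffected at the resolution of any test here.

Paired-end (Illumina): insert size `round(Normal(mean, sd))` clamped to
[read length, genome length], start uniform over valid positions, strand by
fair coin. Defaults 200 ± 20 bp — a typical short-insert shotgun library
compatible with 75 bp mates. Mate /1 is the first `read_length` bases of
the insert on its strand; mate /2 is the reverse complement of the last
`read_length` bases (innie orientation). Single-end platforms sample the
read window directly, strand by fair coin.

Error injection: each base is substituted independently with probability
`P(Q_c)`; the substitute is uniform over the three other bases. For pyro,
each maximal homopolymer run of length ≥ 2 additionally suffers a length
error with the error probability of the run's first base — a one-base
duplication or deletion (fair coin). Single-base "runs" are excluded:
their miscalls are already modeled as substitutions, and including them
would roughly double the effective per-base error rate. Insertions
duplicate the base's quality; deletions remove it, so sequence and quality
stay equal-length.

Every read gets a truth record: source genome, 0-based half-open reference
window, strand (minus-strand reads are stored as sequenced), mate, and the
positions/types of all injected errors (offsets in the final read, strictly
increasing). For substitution-only platforms the logged positions equal the
positionwise diff between read and reference window exactly; with indels
the edit distance to the window is bounded by the logged error count
(adjacent events can partially cancel, which the log does not collapse).
Read IDs redundantly encode provenance (`readNNN|genome:start-end:strand/mate`)
for debugging; the truth TSV is authoritative. A single seeded generator
drives the whole simulation, so equal configurations produce byte-identical
output files.

## Quality control

Three steps, in order:

1. **5' composition trim.** For each base b the per-cycle frequency
   `f_b(c)` is computed over the read set, then the mean and sd of `f_b`
   across cycles. The trim offset is the smallest `t` such that every
   cycle after `t` has all four frequencies within 2 sd of their mean.
   The statistic is population-level, so one global offset is applied to
   every read. Only the first 10 cycles (configurable) are eligible — the
   rule is a 5' prefix operation; deeper outlier cycles are ignored.
   When input lengths differ (e.g. a re-run on trimmed reads) the
   statistic uses only reads of the modal length, keeping the per-cycle
   denominators honest. Note the 2-sd rule is intentionally aggressive:
   with perfectly stable composition the cross-cycle sd reflects only
   sampling noise, and ~5% of cycles per base can exceed it by chance.
2. **3' quality trim.** Terminal bases with quality < 20 are removed until
   the read ends in a base ≥ Q20 (possibly emptying the read).
3. **Filters.** Reads shorter than 35 bases or with median quality < 20
   are discarded (reasons: `too_short`, `low_median_q`). The median of an
   even count of values is the mean of the two central values.

The report accounts for reads/bases in and out, the global 5' offset,
per-read 3' trim lengths, and the removal-reason histogram; removed reads
always equal the sum over reasons.

## Assembly assessment

**Read-back mapping.** An exhaustive ungapped k-mismatch mapper
(default ≤ 2 mismatches, seed length 15) re-creates the check of raw-read
accuracy against source genomes. Reads are split into `mismatches + 1`
segments; by pigeonhole at least one segment is exact, so looking up each
segment's leading k-mer in a genome hash finds every qualifying locus on
either strand. When reads are short the effective seed shrinks to
`len // (mismatches + 1)`. This is intended for desk-scale genomes (an
index of tens of Mb is the practical ceiling). Genome coverage is the
fraction of positions under at least one alignment.

**Chimericity.** Classic mode flags a contig whose reads (per the truth
table) come from more than one genome. Illumina mode counts only reads
uniquely assigned to one contig, because a short read can legitimately
match several genomes and assemblers may place it in several contigs. On
unique-only inputs the two definitions coincide. The degree of chimericity
is `1 − (majority-genome reads)/(all reads)`; majority ties are broken
lexicographically so the statistic is deterministic (the degree itself
depends only on the maximum count). Read-to-contig assignments may come
from an external mapper's TSV or from truth-based placement; both feed the
same metrics.

**Contig Score.** The contig is aligned locally (Smith–Waterman via
Biopython's `PairwiseAligner`; match +1, mismatch −2, gap open −5, gap
extend −2 — megablast-like, appropriate for high-identity contigs versus
their source genomes) against every genome window sharing an exact 15-mer
with the contig, on both strands. Percent identity is matches / alignment
columns (gaps count as columns); contig coverage is the aligned contig span
over the contig length. Score = pid% × cov% / 100 of the highest-scoring
HSP (ties: higher identity, then lower genome id). A contig sharing no
15-mer with any genome scores 0. The score is 100 iff the best HSP has
100% identity and covers the whole contig.

**Length statistics.** N50 uses the cumulative-from-largest convention:
sort lengths descending and report the first length at which the cumulative
sum reaches half the total. (The equivalent threshold form — the largest L
such that contigs ≥ L hold at least half the bases — is used as the
independent oracle in tests.) Assembly summaries restrict to contigs
strictly longer than a cutoff (500 bp default), matching how assembly
tables are usually presented; an empty filtered set is flagged rather than
an error. Scaftigs are the maximal N-free substrings of a scaffold, in
order; concatenating them with the removed N-runs reconstructs the scaffold.

## Functional profiles

Category counts normalize to probability distributions. Profile pairs are
zero-filled onto the union of their category universes before comparison.
Jensen–Shannon divergence uses log base 2 (maximum 1 bit); its square root
is a metric and is the distance used for ordination. The expected profile
weights each genome's counts by `a_i·L_i` — the same weight that governs
read allocation, so the expectation matches what unbiased sequencing of the
community would annotate. PCoA is classical MDS: double-center `−D²/2`,
eigendecompose, keep positive-eigenvalue axes (coordinates = eigenvectors ×
√eigenvalues); negative eigenvalues from non-Euclidean distances are
dropped and their magnitudes reported, not corrected. PCA (column
mean-centered, via scikit-learn) and Pearson correlation on the zero-filled
probability vectors complete the comparisons.

## What the synthetic data does and does not emulate

Synthetic genomes are i.i.d. base sequences at a chosen GC content. They
have no repeats, no shared homology between community members, no coding
structure and no compositional heterogeneity. Consequently:

* read mapping and chimericity results on synthetic data are *optimistic* —
  real inter-genome homology creates multi-mapping reads and genuine
  assembly chimeras that i.i.d. genomes cannot produce (tests plant
  duplicated segments explicitly when multi-mapping behaviour is the thing
  under test);
* Contig Scores near 100 are expected for error-free substrings by
  construction; the informative regime (partial coverage, sub-100 identity)
  is exercised with explicitly mutated or spliced contigs;
* QC results depend only on the quality model, not on sequence content, so
  they transfer to real data to the extent the quality model does.

Default study conditions used by the calibration checks: ten 20 kb genomes,
uniform abundance, 75 bp single-end reads, ~10⁵ reads for rate
measurements, 10⁴ draws for read-length means, 1 Mb/50 kb single genomes
for the length and Contig Score measurements. These sizes give 3-sigma
binomial/CLT tolerances well below the effects being measured while keeping
any single check under a minute on one CPU. The QC direction check (mapped
fraction rises after QC) simulates with a linear decay Q35 → Q10 — steeper
than the clean default Q35 → Q25 — to emulate the uncleaned 3' tails of a
raw run; with tails near Q10 (P ≈ 0.09 per base) untrimmed reads frequently
exceed the 2-mismatch budget, which is precisely the situation QC exists to
repair.

## Numerical conventions and edge cases

* Coordinates 0-based half-open throughout; strand `−` sequences stored as
  sequenced.
* Qualities are integers in [0, 93]; FASTQ encoding Phred+33.
* Probability vectors must sum to 1 within 1e-9; distance matrices must be
  symmetric with zero diagonal within 1e-12.
* PCoA keeps eigenvalues above `1e-12 × max(|λ|, 1)`; explained fractions
  are relative to the positive spectrum.
* Largest-remainder rounding breaks remainder ties by rank.
* `allocate_reads` with a zero total weight, empty read sets in QC, empty
  contigs/length lists, and all-zero count vectors raise `ValueError`
  rather than returning degenerate results.

## Known limitations

* The mapper and Contig Score aligner are exhaustive/desk-scale by design;
  they are not replacements for production mappers or BLAST on real-sized
  references.
* Sanger vector/linker contamination, chimeric library fragments, PCR
  duplicates and flowgram-level pyrosequencing effects are not simulated.
* The pyro homopolymer model is a single ±1-base event per run per read;
  real 454 error grows super-linearly with run length.
* Gene prediction and functional annotation are out of scope: functional
  profiles enter as per-genome/per-contig category counts.
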