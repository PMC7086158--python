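# Methods

## Coordinate and annotation conventions

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted on read, and refFlat/BED12 are accepted
as-is. When a gene id carries several transcripts, the transcript with the
longest genomic span is kept — a stated collapse rule, chosen so that every
derived region is defined from a single consistent exon chain. The
transcript span must equal its exon envelope so that exons and introns tile
`[tx_start, tx_end)` exactly; this invariant is what makes the read
categories a partition.

Strand conventions: TSS = `tx_start` on `+` and `tx_end` on `-`; TES is the
opposite end; the "first intron" is the intron nearest the TSS in
transcription direction, not in coordinate order. The TES window spans
TES→TES+20,000 bp downstream (clipped at contig ends rather than discarded,
so near-telomeric genes keep a truncated window); the promoter is TSS ± 1 kb
and the pause window TSS→TSS+250 bp, both strand-aware.

## Read classification

Each read surviving the rRNA mask (any ≥ 1 bp block overlap removes a read)
is classified against every overlapping gene with a fixed cascade: spliced →
exon_intron → intronic → exonic → tes → tes_rt. The precedence is a design
choice — junction evidence is the most informative signal a read can carry,
and pre-mRNA evidence (intron-touching) outranks mature evidence — the
category list itself does not imply an order. A gap counts as a junction
when both ends fall within 5 bp of an annotated intron's ends; the
tolerance absorbs small alignment slippage around junctions and is
configurable. "TES-overlapping" is read as spanning the TES base itself
(the alternative reading, spanning the far end of the 20 kb window, would
make the category a function of the window length rather than of
termination failure). Reads compatible with more than one gene are counted
as `ambiguous` and excluded from per-gene counts rather than multi-counted;
reads that overlap a gene but satisfy no rule (e.g. a block straddling the
TSS into upstream sequence) are tallied as intergenic. Together this makes
the accounting exact: per-gene categories + intergenic + ambiguous +
rRNA-removed = input reads, which the tests assert without tolerance.

Strandedness defaults to the fr-firststrand chemistry (single-end reads
antisense to their gene) with an `unstranded` escape hatch.

`first_intron` is a sub-count of `intronic` (not a partition member), so
conservation is preserved while first-intron retention remains queryable.

## Normalization and scores

Intronic counts are divided by total intron length in kb (per-kb rather than
per-bp is a display choice only — the unit cancels in no score but scales
all genes identically; it is configurable). Spliced counts are divided by
the number of exons. All categories are then scaled by the per-sample
library factor `min_j(retained_j)/retained_s`, the "normalize to the
smallest library" convention; the factor lies in (0, 1] with the smallest
library at 1. Subsampling to the smallest library (`subsample_reads`) is
provided as the equivalent read-level operation for track generation.

The splicing score is `spliced_norm / (intronic_norm + exon_intron)` and the
termination score `(tes + tes_rt) / (intronic_norm + exon_intron)`. Both use
the same pre-mRNA denominator, with the length-normalized intronic
component; using one denominator for both scores keeps them comparable and
is the single reading consistent with "pre-mRNA reads" naming one quantity.
Scores with a zero denominator are undefined and excluded — never imputed as
zero — and replicate means are taken over defined entries only. Genes whose
mean raw count across samples is below 1 are dropped (the boundary, mean
exactly 1, is kept).

Density summaries use a Gaussian kernel of fixed bandwidth 0.3 on log10
scores (the log is a display choice, configurable); zero scores are removed
by the log transform, which implements "genes without spliced reads
removed" for the splicing-score density. The Signal2Noise ranking floors
each group sd at 0.2·|group mean| (0.2 when the mean is zero), the
convention of the ranked-list GSEA tool this feeds; ties in the descending
ordering break on gene id so exports are deterministic. The enrichment walk
itself is out of scope — the `.rnk` file is the interface.

## ChIP-RX

The spike-in factor is `min_j(spikein_j)/spikein_s`, the min-ratio
convention of exogenous-reference normalization; it is isolated in one
function (`rx_factors`) with the library-size analogue
(`library_size_factors`) alongside as the deliberate counter-example. Peak
"presence in input" means any ≥ 1 bp interval overlap. Promoter proximity
is judged by the summit position (a summit is what peak callers report as
the binding point; any-overlap would make the call width-dependent).
Metagene profiles extract strand-aware windows (offsets count in
transcription direction), pad positions outside the contig with zeros,
scale by the supplied factor, and report mean ± SEM; SEM is 0 for a single
anchor. Dual-genome mapping is out of scope — the module consumes the
per-genome mapped-read accounting, which the simulator produces.

## Proteomics

Row filters (score < 40, localization probability ≤ 0.75, PEP ≥ 0.05,
reverse/contaminant flags, < 2 razor/unique peptides, valid values in at
least one group — with a configurable minimum for designs that accept 2–3
of 4) are applied as a conjunction, so the retained set is independent of
criterion order. Missing intensities are treated as NaN or 0
(`zero_is_missing`).

Imputation draws log10 intensities from `N(q05, 0.1)` where q05 is the 5%
quantile of all observed log10 intensities in the designated columns;
observed values are never overwritten and a fixed seed reproduces the table
bit-for-bit.

The binned-IQR caller bins proteins by mean log10 intensity over all bait
and control columns (summed vs mean intensity is unstated upstream; the
mean of logs is scale-equivariant, making calls invariant to multiplying
all intensities by a constant, which the tests assert). Bins are
consecutive equal slices of `ceil(n / floor(n/300))` rows so each holds at
least 300; fewer than 300 rows fall back to a single bin with a warning. A
ratio exactly on a fence is not an outlier ("outside" is strict) — the
standard boxplot convention, configurable.

The differential test is `t_s0 = Δmean / (SE_pooled + s0)`; s0 enters
observed and permuted statistics alike. The null pools |t| over balanced
group-label permutations (all of them when ≤ 500, otherwise sampled), the
FDR at a cut is expected false positives per permutation over observed
positives, and q-values are made monotone by the step-up cumulative
minimum. The overlap test is the upper-tail hypergeometric on an explicit
universe — the universe is a required argument, never inferred, because the
p-value is only as meaningful as that choice.

## The synthetic-data generators

`simulate_genome` places non-overlapping multi-exon genes with inter-gene
gaps larger than two TES windows, so readthrough windows never reach a
neighbor and reads have unambiguous ground truth; dedicated intergenic
zones and rRNA intervals sit clear of every gene-derived region. Exon and
intron lengths are log-normal (medians ≈ 180 bp and 900 bp, floors above
the read length), expression is log-normal across genes, and reads are
75 nt single-end — geometry chosen as typical for short-read nascent-RNA
libraries; none of it enters the scores.

`simulate_nascent_reads` draws each read's gene by expression weight, emits
a readthrough read with probability `readthrough_fraction` (placed in the
TES window, occasionally spanning the TES), otherwise a mature read
(junction-spanning or exonic) with probability equal to the condition's
splicing efficiency, else a pre-mRNA read (intronic or boundary-crossing).
The chase phase raises the effective efficiency to `eff + 0.5·(1 − eff)`,
emulating maturation between labeling and harvest. Default conditions
emulate the study design the scores were built for: a solvent control
(efficiency 0.55, readthrough 0.05), a kinase-inhibitor arm with impaired
splicing and more readthrough (0.40, 0.15), a splicing-inhibitor arm
(0.15, 0.08), and a pulse sample of the control.

`simulate_spikein` holds spike-in depth constant (Poisson) while a
per-condition factor scales the whole primary-genome signal — the exact
situation ChIP-RX exists to detect. `simulate_intensity_table` plants
interactors as a log2 shift in the bait columns. Control missingness is
soft detection-limit censoring at the configured overall rate, not
missing-at-random: in label-free MS it is predominantly low-abundance
measurements that drop out, and baseline imputation is only coherent when
the missing values truly were near the baseline. (Under MAR, abundant null
proteins with a missing control would receive floor imputations and
enormous spurious ratios, inflating every bin's IQR.)

What the generators do **not** emulate: sequence content and alignment
error, PCR duplicates, isoform mixtures within a gene, overlapping or
nested genes, copy-number or chromatin context in ChIP, correlated
replicate structure or batch effects in proteomics. Passing tests therefore
demonstrate correctness of the quantification and statistics given faithful
alignments and annotations, not robustness to upstream artifacts.

## Problem sizes and runtime choices

The recovery and calibration checks run at the sizes the analyses are
specified at — 200 genes × 3 replicates × 10⁵ reads per sample for the
efficiency/readthrough grids, 5,000 rows at 4 vs 4 for the FDR
calibration, 10⁴ rows/draws for the IQR-oracle and imputation checks —
which keeps the full suite around two minutes on one CPU. Unit tests use
smaller instances of the same generators.

## Known limitations

* With four replicates per group, a 3-sd planted shift has noncentrality
  ≈ 4.2 at ≈ 6 degrees of freedom; controlling permutation FDR at 1% over
  thousands of sites requires |t| cuts well beyond that, so the flag list
  is near-empty at this design point no matter the implementation. The
  ranking remains highly informative (planted sites dominate the top; see
  `examples/05_phospho_differential.py`), which is why downstream analyses
  should consume the ranking or relax the FDR, not read the flag count as
  power.
* The classifier assigns one category per read per gene; reads spanning
  three or more exons are classified by their first matching rule, and
  multi-gene-compatible reads are dropped as ambiguous rather than
  fractionally assigned.
* The RX factor assumes equal spike-in chromatin per sample; violations of
  that assumption propagate linearly into every normalized quantity.
* Peak calling, alignment, duplicate marking and database search are out of
  scope; the package starts from aligned reads, called peaks and quantified
  tables.
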