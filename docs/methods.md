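# Methods

`kmerdiff` re-implements a reference-free differential transcriptome
analysis for tumor vs. normal RNA-seq as a tested, reusable pipeline, and
exercises it end-to-end on synthetic cohorts with planted events. This note
documents the model, the choices that were genuinely open, and what the
synthetic benchmark does and does not show.

## The pipeline

Reads are decomposed into canonical k-mers (k = 31 by default; the
canonical form is the lexicographic minimum of a k-mer and its reverse
complement, appropriate for unstranded libraries). Three filters reduce
the k-mer x sample count matrix to candidate variant signal:

1. **Recurrence filter** — keep k-mers with count >= 5 in >= 10 samples.
   The two thresholds are read jointly per sample (>= 5 counts in >= 10
   samples), not as a total-count rule; both are configuration-exposed
   because synthetic cohorts are smaller than the tissue cohorts the
   defaults were tuned on, and analyses of low-recurrence designs (e.g.
   events carried by 6 of 10 tumor samples) must scale `min_samples`
   accordingly.
2. **Reference masking** — remove every k-mer occurring in the annotated
   (spliced) **transcriptome**. Masking against transcript sequences rather
   than the raw genome is deliberate: error-free reads of an unperturbed
   transcriptome then leave an empty matrix (annotated exon-exon junction
   k-mers are masked too), while the signal classes the method is built to
   find — intron retention, intergenic lincRNAs, novel junctions — all
   survive, because their k-mers are absent from spliced transcripts.
   Masking against the genome instead would remove every k-mer of an
   intron-retention or lincRNA event (both are genomic substrings) and
   leave annotated junction k-mers in, defeating both the null behaviour
   and the event taxonomy. `index_reference_kmers` is generic over any
   sequence set, so genome masking remains available to callers.
3. **Normalization** — median-of-ratios against a geometric-mean
   pseudo-reference: for sample *j*, the size factor is the median over
   all-positive rows *i* of c_ij / g_i with g_i the row's geometric mean.
   Size factors are **estimated on the filtered, pre-mask matrix** and then
   applied to the masked one: the pre-mask matrix is dominated by
   non-differential transcriptome k-mers, whereas the masked matrix
   contains mostly event-derived (differential) rows and would bias the
   median. Rows with any zero are excluded from estimation; if no
   all-positive row exists the fallback uses each row's geometric mean over
   its nonzero entries (with a warning). Size factors are only defined up
   to a common constant: scaling one of *n* libraries by λ moves its factor
   by λ^(1-1/n) absolutely (the pseudo-reference itself shifts by λ^(1/n))
   and by λ exactly relative to every other sample. Tests assert the exact
   relative form.

**Differential testing** operates on log2(x + c), c = 0.5 (pseudocount for
fold-change stability; configurable). The default test is a moderated t:
per-feature pooled variances are shrunk toward a prior estimated by
matching the moments of log(s²) to a scaled-F model (prior degrees of
freedom d0 from the inverse-trigamma of the excess log-variance spread;
when the spread does not exceed sampling noise, d0 is infinite and the
prior variance is the mean of the sample variances). This reproduces the
classic empirical-Bayes linear-model test numerically (a test cross-checks
p-values against the Bioconductor implementation through Rscript); a plain
Welch t is selectable for cross-checking. The reported effect size is
log2((mean_T + c)/(mean_N + c)) on the normalized scale. Multiple testing
uses Benjamini–Hochberg step-up (configurable: bonferroni/none), and
significance means padj < 0.05 **and** |log2FC| > 1 — the fold-change
filter is two-sided, since down-regulated features are reported alongside
up-regulated ones. The single-feature convenience `test_feature` uses the
Welch t: shrinkage needs an ensemble, so moderation lives on the matrix
path.

**Contig assembly** joins significant k-mers into unitigs: maximal
non-branching paths in the bidirected (k-1)-overlap graph. Each canonical
k-mer is a node with two orientations; extension stops at any branch
(a node without exactly one successor, or whose successor lacks exactly one
predecessor), at palindromic k-mers (their far side is orientationally
ambiguous), and when a cycle closes (tandem-repeat k-mer sets form perfect
cycles, emitted as one linear traversal from the lexicographically
smallest member). Unitig semantics — rather than a greedy heaviest-path
merge — make the output deterministic and checkable against brute-force
path enumeration, and suffice because significant k-mer sets are locally
linear around isolated variants: the canonical consequence is that a
single isolated substitution with full coverage yields exactly one 61-bp
contig (31 k-mers of 31 nt overlapping the variant base, which sits at
position 31). A caveat established while testing: when a k-mer set
contains a sequence that shares a (k-1)-mer with its own reverse
complement ("fold"), the maximal-path *partition* is not unique; the
implementation resolves such ties deterministically (sorted traversal
order), and the oracle comparison is restricted to fold-free instances.
Each contig is quantified by its **representative k-mer** — the member
with the smallest p-value (ties: smallest padj, then lexicographic) —
keeping the exact statistic that made the contig significant; both
normalized and raw representative counts are carried, because downstream
presence/absence screens are defined on raw counts.

**Annotation** aligns each contig with an internal exact-seed (15 nt) /
ungapped-extension aligner under a floor(0.05·len) mismatch budget:
full-length exact search first (>= 2 loci -> multi, 1 -> unique), then
seeded blocks combined into unique-with-mismatches (>= 95% coverage),
spliced (two query-adjacent same-strand blocks, genomic gap 20–100,000 nt),
partial/chimeric (discordant pair jointly >= 60%, or a single 25–95%
block) or unmapped. At toy-genome scale this is deterministic and
verifiable against exhaustive full-scan search, which a test performs for
every contig of the default cohort. Classification applies a fixed
precedence, each contig receiving exactly one class:

1. polyA — a terminal A-run or leading T-run of >= 10 nt whose trimmed
   core does not align;
2. split — partial/chimeric alignment;
3. repeat — multi-locus alignment or an exact tandem period <= 30 nt
   covering the whole contig with >= 2 full unit copies;
4. splice — spliced alignment;
5. SNV — unique alignment with >= 1 mismatch;
6. intron — unique perfect alignment with >= 50% of its bases in an
   annotated intron;
7. lincRNA — unique perfect alignment overlapping no gene span;
8. unmapped; and a residual "other" for unique exonic perfect matches
   (rare after transcriptome masking; exon-boundary-crossing residuals
   call as splice).

The poly-A check precedes everything because the homopolymer run destroys
alignability; anti-sense classes are deliberately not called (unstranded
libraries). Host genes are assigned by maximal overlap between aligned
blocks and gene spans (ties to the lexicographically smallest gene id).
The tumor-specific ("neo") flag — zero raw count in every normal sample,
positive in at least one tumor — is orthogonal to the class: an SNV contig
can also be tumor-specific.

**Downstream**, gene expression is quantified by an exact-substring
assigner (a read found in m annotated transcripts, on either strand,
contributes 1/m to each; TPM per transcript, summed per gene). This is
valid for the low-error synthetic reads it is applied to and is not a
general pseudoaligner. Gene-level differential expression reuses the same
contrast protocol on log2(TPM + 0.5). Each significant contig with a host
gene forms a **codirectional** pair when the gene is significant with the
same sign and a **DU (differential usage)** pair otherwise; pair
discordance is scored by a two-sided Wilcoxon signed-rank across samples
on within-feature z-scored per-sample values (contig vector vs. gene
vector). The paired form was chosen because the comparison is between a
contig and *its* host gene; a rank-sum alternative (contig tumor vs.
normal) is selectable. Constant vectors give p = 1; scipy's exact
small-sample mode covers cohorts under ~6 samples. **Neoantigen
candidates** are contigs with zero raw count in every normal sample and a
positive count in at least ceil(0.5 · n_tumor) tumor samples ("present"
means raw count > 0 — the criterion is presence/absence, not level). Their
peptides come from six-frame translation (contigs are unstranded), split
at stop codons, as all 8–11-aa windows — the standard MHC-I length range.
Binding prediction itself is delegated to a pluggable external command
hook; without a hook, candidates pass through unscored.

## The synthetic cohort

The generator emulates the structure of a tumor/normal bulk RNA-seq study:
a toy reference (default 2 chromosomes x 100 kb, 20 non-overlapping
three-exon genes, >= 1.2 kb intergenic gaps), one transcript per gene, and
one planted variant per event class — SNV, exon skip, intron retention,
intergenic lincRNA, tandem expansion (12-bp unit x 8 copies), poly-A
novelty, two-gene fusion, and a foreign sequence sharing no k-mer with the
reference. Samples are 10 tumor + 10 normal with 20k single-end 75-bp
reads each, uniform over transcripts (probability proportional to
abundance x length), random orientation, i.i.d. substitution errors
(default 0).

Abundance semantics: a variant's expression is `base_abundance` (default
0.25 of one baseline transcript — a minor isoform) times a per-condition
multiplier, default 4x tumor / 1x normal for differential events. The
0.25 base keeps planted variants a small fraction of the library, which
matters: median-of-ratios normalization assumes most features are
unchanged, and with variants as full-length transcripts at baseline-level
abundance they would dominate the library and flatten the very fold
changes being tested. Tumor-only events have zero normal abundance and an
optional `tumor_fraction` restricting them to a random (seeded) subset of
tumor samples, emulating recurrence. Every variant is asserted at
generation time to contain at least one canonical k-mer absent from the
transcriptome index.

What passing tests show — and do not. The cohort is error-free by default,
single-end, without indels, quality-score structure, positional bias, or
expression dispersion beyond multinomial sampling; alignment is
ungapped-exact at toy scale. Recovery of all eight planted classes here
demonstrates the pipeline's logic (filtering, normalization, testing,
assembly, classification) is correct, not that the method attains any
particular sensitivity on real tissue data; real cohorts add sequencing
error, isoform complexity and mappability structure that this benchmark
deliberately excludes.

## Numerical and degenerate-case choices

- Problem sizes were chosen so the default end-to-end run takes well under
  a minute of compute per cohort: 20 samples x 20k reads, ~18k distinct
  k-mers, ~1.1k masked k-mers, ~11 contigs.
- p-values are floored at 1e-300 and capped at 1; zero-difference features
  report p = 1 regardless of test.
- Welch/moderated t on constant groups: zero pooled variance with zero
  difference gives t = 0, p = 1; with nonzero difference the moderated
  posterior variance (prior-shrunk) keeps t finite.
- `detect_polya` takes the longer of a tail A-run and head T-run (tie:
  tail); `detect_tandem` returns the smallest exact period, the final
  unit copy may be truncated.
- Extension in the aligner trims terminal mismatches and stops after 3
  consecutive ones; block pairs overlapping on the query by up to
  2·budget + 4 nt are re-trimmed at the junction before the spliced /
  chimeric decision.
- GFF3 is written 1-based inclusive; all internal coordinates and BED
  output are 0-based half-open.
- Non-ACGT characters: k-mer windows containing them are skipped (FASTQ
  N's are routine); `canonical()` itself rejects them so callers choose
  the skip policy. The generator emits A/C/G/T only; N handling is
  exercised by hand-written fixtures.
- Seeds: every stochastic step takes an explicit seed; per-sample and
  per-stage seeds are derived from the master seed via `SeedSequence`.

## Known limitations

- The recurrence filter holds the whole matrix in memory; desk-scale
  inputs only (no external-memory or sketch counting).
- The aligner has no gapped alignment or repeat-family model; repeats are
  recognized by multi-mapping and exact periodicity, not family profiles.
- Tandem expansions shed flank-junction contigs that legitimately align
  partially and classify as split; the expansion itself is recovered from
  its periodic core contig.
- The gene quantifier requires reads to match transcripts exactly (up to
  strand); it under-counts variant-bearing reads by design.
- MHC-I binding is not predicted in-repo; the hook contract is
  `command peptides.txt` printing `peptide<TAB>score` lines.
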