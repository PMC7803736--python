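# Methods

## The assay and the computational problem

Rolling-circle amplification (RCA) of a circular RNA's cDNA followed by
nanopore sequencing yields raw reads that are tandem concatemers: many
error-bearing copies of one template, where the template is the circRNA's
spliced sequence read from a random starting position within the circle.
The computational task is to (1) recognize the tandem structure and call an
accurate consensus repeat unit per read, (2) map a two-copy concatemer of
that consensus to the genome so that the back-splice junction (BSJ) appears
as a wrap in the alignment and the forward-splice junctions (FSJs) as
introns, (3) correct and filter junctions into high-confidence calls, and
(4) collapse reads into a quantified, classified isoform catalog with
cross-sample statistics.

## Simulator

The simulator is the package's experimental ground: it emits a toy genome
of multi-exon genes, a GTF, a complete BSJ database, a repeat track, and
FASTQ reads with full ground truth, so every stage is a parameter-recovery
problem.

* **Genes.** `n_genes` genes on one chromosome, alternating strands at
  random; exons per gene, exon lengths (80–200 nt) and intron lengths
  (150–400 nt) drawn uniformly from configurable ranges. These sizes keep a
  gene locus in the low kilobases so a whole dataset aligns in seconds
  while still exercising multi-intron structure. Canonical motifs (GT after
  every donor, AG before every acceptor, in the strand-appropriate genomic
  spelling) are planted at every exon boundary — including circle-terminal
  boundaries — and at pre-placed *alternative* boundaries inside exons, so
  motif-based splice-site correction has the same information it would have
  on a real genome.
* **Isoforms.** Each draw picks a gene, a contiguous exon run, and an
  alternative-splicing event from `as_event_mix` (`none`, SE, A5SS, A3SS,
  RI). Event variants are paired with their event-free parent (same BSJ).
  An RI isoform merges two exons across their intron (an EIciRNA). For each
  *documented* variant a linear transcript carrying the variant junctions
  is added to the GTF; with probability `novel_site_rate` a variant is left
  undocumented, which is how novel (NIC/NNC) structures arise. The emitted
  BSJ database contains every simulated circle; tests that need novel BSJs
  subset it.
* **Reads.** A read is `rotation(template, offset)` repeated `k` times,
  `offset` uniform; `k` is drawn from a shifted geometric distribution
  (default) or shifted Poisson with mean `copy_number_mean` (default 14.5,
  the observed mean copy number in published RCA circRNA libraries) and
  floor `copy_number_min` (default 2 — the pipeline requires two copies to
  call a consensus, and sub-two-copy reads are dropped by design).
  Substitution/insertion/deletion errors are applied i.i.d. per base
  (defaults 4/2/2%, an 8% total typical of nanopore reads); reads are
  emitted on either strand with equal probability, and qualities are a
  constant Q score because no stage consumes them.
* **What is not emulated.** RT chemistry (overhang removal, ligation),
  chimeric/adapter artifacts, context-dependent error models, and partial
  terminal copies. Passing tests therefore demonstrate correctness of the
  *computational* contract, not robustness to every artifact of real
  libraries.

## Consensus calling

Tandem periodicity is detected from the read alone: distances between
successive occurrences of each 11-mer vote for a period, the vote histogram
is smoothed with a ±2% window (absorbing indel jitter), and peaks become
candidates. Harmonics of an accepted peak (integer multiples) are
suppressed, since a double-length unit explains the same repeat. A
candidate must explain ≥ 1.8 copies (nominal two, minus span-estimate
jitter); reads shorter than twice the minimum period (20 nt — anything
shorter is treated as low-complexity) or without periodic structure are
dropped with a reason code.

The consensus is called by majority vote: the first repeat copy is the
draft; the repeat span is partitioned into copies by prefix-aligning the
draft at each successive boundary (edlib); every copy is globally aligned
to the draft and per-column votes (base / deletion / insertion) are taken,
with ties broken in favor of the draft base — which makes the two-copy case
deterministic and biases toward the first copy, as documented. Two
polishing rounds are run (the round-one consensus becomes the draft for
round two). The reported `copy_number` is repeat span divided by consensus
length; the selection score is the total number of matched bases across
copies, so it weights both copy number and agreement. One consensus per
read is selected by (score, span, smaller subread start).

Expected behavior, verified by test: error-free reads give the template
exactly (up to rotation), and median consensus error decreases
monotonically with copy number, staying below the raw-read error at every
copy number.

## Spliced alignment

The aligner is an internal, deliberately simple semi-global dynamic program
adequate for toy genomes (≤ ~1 Mb): exact 13-mer seeds select candidate
windows and the query strand; within a window the DP is global in the query
and free-ended in the target with linear scores (match +2, mismatch −3,
gap −3/base) plus a flat −20 *genomic jump* of at least 30 nt forward (an
intron) or 20 nt backward (the back-splice wrap). Allowing backward jumps
is what lets a two-copy concatemer align as a single blocked record whose
wrap *is* the BSJ. Traceback ties are deterministic (diagonal > query gap >
target gap > forward jump > backward jump; shortest jump preferred). MAPQ
is 60/20/0 from the score margin between the two best seeded loci; records
below `MAPQ_MIN = 1` are discarded and the best survivor is chosen by
(aligned query length, identity, leftmost coordinate).

Boundary bases that match on both sides of an intron can sit on either side
of the junction in the raw alignment; splice-site correction (below)
normalizes them.

## Junction calling, correction and confidence

Blocks shorter than 8 nt are ignored; block-to-block target gaps ≥ 30 nt
are FSJ observations, negative gaps are BSJ (wrap) observations. Because
the concatemer traverses the circle exactly twice, each junction should be
observed twice. Concordance rules: all wrap observations must agree on one
BSJ after clustering within 8 nt; each FSJ must be seen twice, and a single
observation is accepted only when its twin — one template copy away along
the query — would fall within 50 nt of the query ends, where a partial
flanking copy may have been glued or clipped. More than two consistent
wraps (a consensus spanning several template copies) do not change the
call.

Each junction is then snapped, within a ±10 nt window, to the nearest
annotated donor+acceptor pair, or failing that to a canonical GT–AG
(CT–AC on the minus strand) motif, searching shifts in order of increasing
total displacement so an already-correct junction is a fixed point. The
circRNA's strand is set by the corrected BSJ motif. Junctions with no
annotated or canonical solution keep their coordinates with
`confidence=low`. Exon blocks are rebuilt from the corrected junctions, so
block coordinates are always consistent with the reported BSJ/FSJs.

Confidence: a BSJ whose sites are annotated (gene annotation, with site
sets built from *all* exon boundaries, terminal ones included) or whose
circle is in a provided circRNA database is high-confidence if correction
succeeded. A BSJ involving any novel site must additionally show ≥ 0.98
alignment identity in a ±20 nt window around the wrap and a canonical
motif — the stricter novel-site filter. A read with a high-confidence BSJ
is a candidate circRNA; if all its FSJs are also high-confidence it is a
full-length isoform. These thresholds are declared defaults, surfaced in
`JunctionParams`.

## Catalog

Reads with identical (chromosome, strand, circle, ordered FSJ list) merge;
read count is the number of independent reads per sample, distinct from the
within-read copy number. BSJ-level counts are sums over isoforms sharing a
circle, so count conservation holds by construction. Classification: BSJ
FSM ⇔ circle in a database (exact coordinates — correction already
normalized them, so fuzzy matching would double-count); NIC ⇔ both
back-splice sites annotated; NNC otherwise. FSJ set FSM ⇔ the ordered FSJ
list is a *contiguous* sub-chain of some transcript's junction chain
(a circle's exons are consecutive in its parent transcript); empty FSJ set
⇔ FSM; NIC ⇔ all sites annotated; NNC otherwise. Gene assignment takes the
strand-consistent gene sharing the most splice sites (ties → multiple
genes; zero shared sites → any strand-consistent gene with ≥ 1 bp overlap;
else NA). Isoforms are named `gene.circRNA.N` by descending median read
count across samples, ties by mean, then by structural key, making naming
input-order invariant.

Alternative-splicing events compare each gene's predominant isoform
(highest median count) to every other isoform, label the difference scope
(BSJ only / FSJs only / both), and decompose same-BSJ differences into
SE / A5SS / A3SS / RI by block-set comparison; RI is a block that exactly
spans two blocks of the partner plus the intervening intron. Unmatched
residual differences are labeled `complex` rather than forced into a type.

## Statistics

Conventions, where the underlying publication practice leaves a choice:
chi-square without continuity correction and without expected-count guards
beyond skipping zero-margin tables; Fisher tests two-sided (the one-tailed
test is the binomial one only); BH FDR for case (ii) tissue-specificity is
computed globally over tested isoform-tissue pairs, with a per-gene option;
control-BSJ sampling is without replacement and seeded; the Alu orientation
convention takes the element's strand as its pointing direction, with
*convergent* meaning the two flanking elements point toward the circle.
Thresholds default to FDR ≤ 0.05, proportion difference ≥ 0.05, stability
proportion > 0.5 (strict), and a two-read floor everywhere a read-count
floor applies; the control set defaults to 10,000 pairs and Alu windows to
1000/2000 nt. Kernels are scipy/statsmodels calls; the test suite holds
them to 1e-9 against enumeration oracles and checks the null calibration of
the whole two-step pairwise procedure (≤ nominal + 2 SE flagged genes on
500 null genes).

τ (Yanai's index) is Σᵢ(1 − xᵢ/x_max)/(n−1) over a non-negative expression
vector: 0 for uniform (housekeeping), 1 for single-tissue expression;
undefined for all-zero vectors, invariant to rescaling.

## Validation problem sizes

The standard recovery experiment is 50 isoforms over 12 genes (3–8 exons,
1–8 exons per circle, ≥ 5 SE and ≥ 5 RI events), 10 reads per isoform at
copy-number mean 14.5 and 8% total error — small enough to run in minutes
on one core, large enough that every event type, strand and copy-number
regime is exercised; recovery there is 100% exact with zero false isoforms
at the two-read floor. Consensus accuracy is profiled at fixed copy numbers
k ∈ {2, 5, 10, 20} on a 400-nt template, 25 reads per stratum; oracle
checks of the statistical kernels use 1000 randomized inputs each.

## Known limitations

The aligner is not suitable for real mammalian genomes (no heuristics, no
splice-model priors, quadratic DP); on real data the junction module's
pluggable alignment contract would be backed by a production long-read
spliced aligner. The error model is i.i.d. and context-free; homopolymer
behavior of real nanopore data is harsher. The simulator does not produce
chimeric or adapter-bearing reads, so the drop-reason taxonomy for such
artifacts is untested. Strand assignment relies on the corrected BSJ motif
and will mark junctions low-confidence in genomes without canonical motifs.
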