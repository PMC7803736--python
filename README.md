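# rollcirc

Full-length circular RNA (circRNA) isoform detection from rolling-circle
amplified (RCA) nanopore long reads, plus the cross-sample statistics used
to study circRNA isoform usage — with a built-in simulator so the whole
workflow is testable end to end without external data.

## The problem

circRNAs are closed loops produced by back-splicing: a downstream 5′ splice
site joins an upstream 3′ splice site. Short-read RNA-seq can count
back-splice junctions (BSJs) but cannot observe a circle's full exonic
structure. An RCA + long-read assay can: reverse-transcribing the circle
and amplifying it by rolling circle yields reads that contain many tandem
copies of the circRNA template, starting from a random position within the
circle. `rollcirc` implements the computational side of that assay:

1. **Consensus calling** — detect the tandem-repeat structure of each raw
   read (k-mer periodicity), majority-vote a consensus repeat unit, and
   report its copy number. Consensus error falls rapidly with copy number.
2. **Junction calling** — map a *two-copy concatemer* of the consensus to
   the genome with a spliced aligner that allows backward jumps, so the
   back-splice wrap and the forward-splice junctions (FSJs) appear in one
   alignment, each observed twice; require two-copy concordance, snap
   junctions to annotated splice sites or canonical GT–AG motifs, and
   apply stricter near-perfect-identity filters to BSJs with novel sites.
3. **Cataloging** — collapse reads into quantified isoforms; classify BSJ
   and FSJ sets as FSM / NIC / NNC (full splice match / novel in catalog /
   novel not in catalog) against circRNA databases and the gene
   annotation; assign genes by shared splice sites; name isoforms
   `gene.circRNA.N` by read-count rank; type alternative-splicing
   differences (SE, A5SS, A3SS, RI — retained introns mark EIciRNAs).
4. **Statistics** — replicate similarity (|A∩B|/|A∪B|), per-gene
   chi-square + BH and per-isoform Fisher tests of differential isoform
   proportions between tissues, tissue-stable/tissue-specific isoform
   calls (one-tailed binomial), Yanai's tissue-specificity index
   τ = Σᵢ(1 − xᵢ/x_max)/(n−1), inverted-Alu flanking classification of
   BSJs with seeded negative-control BSJ generation, and read-depth
   normalized BSJ counts.

The simulator (`rollcirc.sim`) generates toy genomes with planted splice
motifs, circRNA isoforms with configurable alternative-splicing event
mixes, and error-bearing RCA reads (copy-number mean 14.5 by default, 8%
total error) with complete ground truth.

## Worked example

```python
from rollcirc.sim import SimConfig, simulate_dataset
from rollcirc.pipeline import run_pipeline

cfg = SimConfig(seed=42, n_genes=4, n_isoforms=6, reads_per_isoform=4)
sim = simulate_dataset(cfg)
reads = [(r.read_id, r.sequence) for r in sim.reads]
result = run_pipeline({"hek293": reads}, sim.genome, sim.annotation, [sim.circ_db])
cat = result.catalog.filter_min_reads(2)
print(f"{len(sim.reads)} reads -> {len(cat.isoforms)} full-length circRNA isoforms")
for iso in cat.isoforms:
    print(f"{iso.name:22s} {iso.chrom}:{iso.circle[0]}-{iso.circle[1]} ({iso.strand}) "
          f"{iso.n_exons} exons, {iso.length} nt, {iso.bsj_category}/{iso.fsj_category}, "
          f"reads={iso.total_count()}")
```

prints

```
24 reads -> 6 full-length circRNA isoforms
G003.circRNA.1         chr1:15114-15658 (+) 2 exons, 215 nt, FSM/FSM, reads=4
G003.circRNA.2         chr1:15114-15658 (+) 2 exons, 202 nt, FSM/FSM, reads=3
G000.circRNA.1         chr1:1271-3585 (-) 6 exons, 931 nt, FSM/FSM, reads=4
G000.circRNA.2         chr1:2613-3039 (-) 2 exons, 264 nt, FSM/FSM, reads=4
G002.circRNA.1         chr1:10203-11195 (-) 3 exons, 435 nt, FSM/FSM, reads=4
G002.circRNA.2         chr1:10203-11195 (-) 2 exons, 301 nt, FSM/FSM, reads=4
```

Every simulated isoform is recovered with exact BSJ and FSJ coordinates
despite the 8% read error: the G003 pair shares one BSJ
(`chr1:15114-15658`) and differs by a 13-nt alternative splice site; both
classify FSM/FSM because the synthetic database and annotation are
complete. Counts are independent supporting reads per library, not
within-read copy numbers.

A `rollcirc` console script exposes the same stages
(`simulate`, `consensus`, `call`, `classify`, `stats …`); see
`rollcirc --help`.

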