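"""Simulator for rolling-circle circRNA sequencing experiments.

The generator builds a toy genome of multi-exon genes with canonical GT-AG
splice motifs planted at every (primary and alternative) splice site, draws
circRNA isoforms from those genes -- optionally carrying skipped-exon (SE),
alternative 5'/3' splice-site (A5SS/A3SS) or retained-intron (RI, EIciRNA)
events -- and emits raw reads that are tandem concatemers of a circRNA
template starting at a uniformly random rotation of the circle, with a
configurable copy-number distribution and i.i.d. substitution/insertion/
deletion errors.

Every simulated entity is recorded in a ground-truth structure so downstream
stages (consensus calling, junction detection, cataloging, statistics) can be
tested as parameter-recovery problems.  Identical seed and configuration give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rollcirc.annotation import (
    CircDB,
    Gene,
    GeneAnnotation,
    RepeatElement,
    Transcript,
    write_bed,
    write_gtf,
)

__all__ = [
    "SimConfig",
    "SimGene",
    "IsoformTruth",
    "ReadTruth",
    "SimRead",
    "SimResult",
    "EventInfeasibleError",
    "simulate_genome",
    "simulate_circ_isoform",
    "simulate_rca_read",
    "simulate_dataset",
    "write_fasta",
    "write_fastq",
    "read_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

EVENTS = ("none", "SE", "A5SS", "A3SS", "RI")


class EventInfeasibleError(ValueError):
    """Requested AS event cannot be realized on the given gene/run."""


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class SimConfig:
    """Knobs of the read simulator.

    ``copy_number_mean`` defaults to 14.5, the observed mean number of
    template copies per raw read in RCA circRNA libraries; the distribution
    shape is configurable (shifted geometric by default) because only the
    mean is an established quantity.  Error-rate defaults total 8%, typical
    of nanopore data.
    """

    seed: int = 0
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (150, 400)
    intergenic_len: tuple[int, int] = (1200, 2000)
    n_isoforms: int = 30
    as_event_mix: dict[str, float] = field(
        default_factory=lambda: {"none": 0.5, "SE": 0.15, "A5SS": 0.1, "A3SS": 0.1, "RI": 0.15}
    )
    novel_site_rate: float = 0.0
    copy_number_mean: float = 14.5
    copy_number_min: int = 2
    copy_number_dist: str = "geometric"  # or "poisson"
    sub_rate: float = 0.04
    ins_rate: float = 0.02
    del_rate: float = 0.02
    reads_per_isoform: int | tuple[int, int] = 10
    alu_mix: dict[str, float] = field(
        default_factory=lambda: {"convergent": 0.4, "divergent": 0.2, "both": 0.1, "none": 0.3}
    )
    alu_len: int = 300
    chrom: str = "chr1"

    def validate(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "novel_site_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if self.exon_len[0] < 60:
            raise ValueError("exon_len minimum must be >= 60 to leave room for alt sites")
        if abs(sum(self.as_event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("as_event_mix must sum to 1")
        if set(self.as_event_mix) - set(EVENTS):
            raise ValueError(f"unknown events in as_event_mix: {set(self.as_event_mix) - set(EVENTS)}")
        if self.copy_number_min < 1:
            raise ValueError("copy_number_min must be >= 1")
        if self.copy_number_mean < self.copy_number_min:
            raise ValueError("copy_number_mean must be >= copy_number_min")
        if self.copy_number_dist not in ("geometric", "poisson"):
            raise ValueError("copy_number_dist must be 'geometric' or 'poisson'")
        if self.n_genes < 1 or self.n_isoforms < 1:
            raise ValueError("n_genes and n_isoforms must be >= 1")
        if abs(sum(self.alu_mix.values()) - 1.0) > 1e-9:
            raise ValueError("alu_mix must sum to 1")


@dataclass
class SimGene:
    """A simulated gene: exon blocks plus pre-planted alternative sites.

    ``alt_end[i]`` / ``alt_start[i]`` give an alternative (shortened) 0-based
    half-open end / start for exon ``i``; canonical motifs for these sites
    are planted in the genome sequence, so alternative-splice-site isoforms
    remain recoverable by motif-aware junction correction.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    alt_end: dict[int, int] = field(default_factory=dict)
    alt_start: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class IsoformTruth:
    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]  # 0-based half-open, genomic order
    event: str  # AS event of the generating draw ('none' for parents)
    documented: bool  # variant transcript present in the emitted GTF

    @property
    def bsj(self) -> tuple[int, int]:
        """Circle interval (0-based half-open)."""
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def fsjs(self) -> tuple[tuple[int, int], ...]:
        """Forward junctions as (left_exon_end, right_exon_start), 1-based."""
        return tuple(
            (e1, s2 + 1) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])
        )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    isoform_id: str
    offset: int  # rotation start within the circle (spliced coordinates)
    copies: int
    orientation: str  # '+' template strand, '-' reverse complement


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    truth: ReadTruth


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    genes: list[SimGene]
    annotation: GeneAnnotation
    isoforms: list[IsoformTruth]
    reads: list[SimRead]
    repeats: list[RepeatElement]
    circ_db: CircDB
    event_draws: list[str]  # one entry per isoform draw, for mix recovery
    alu_truth: dict[str, str]  # gene_id -> planted flanking-Alu category

    def spliced_sequence(self, iso: IsoformTruth) -> str:
        g = self.genome[iso.chrom]
        seq = "".join(g[s:e] for s, e in iso.blocks)
        return revcomp(seq) if iso.strand == "-" else seq


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Build the toy genome.

    Returns ``(genome, genes, repeats)`` where genome maps chrom -> sequence,
    genes are :class:`SimGene` records (with alternative-site candidates),
    and repeats is the Alu-like element track.  Canonical splice motifs are
    planted at every exon boundary (GT after donors, AG before acceptors, in
    the strand-appropriate genomic spelling), including circle-terminal
    boundaries, so back-splice junctions are motif-recoverable.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    parts: list[np.ndarray] = []
    genes: list[SimGene] = []
    repeats: list[RepeatElement] = []
    alu_truth: dict[str, str] = {}
    cursor = 0
    lo_ig, hi_ig = config.intergenic_len

    for gi in range(config.n_genes):
        ig = int(rng.integers(lo_ig, hi_ig + 1))
        spacer = _rand_seq(rng, ig)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, size=n_ex)
        intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, size=max(n_ex - 1, 0))

        gene_len = int(exon_lens.sum() + intron_lens.sum())
        gseq = _rand_seq(rng, gene_len)
        exons = []
        p = 0
        for i in range(n_ex):
            exons.append((p, p + int(exon_lens[i])))
            p += int(exon_lens[i])
            if i < n_ex - 1:
                p += int(intron_lens[i])

        left_motif = "AG" if strand == "+" else "AC"  # upstream of acceptor/donor
        right_motif = "GT" if strand == "+" else "CT"
        gene = SimGene(f"G{gi:03d}", config.chrom, strand, tuple())
        abs_exons = []
        for i, (s, e) in enumerate(exons):
            abs_s = cursor + ig + s
            abs_e = cursor + ig + e
            abs_exons.append((abs_s, abs_e))
            # boundary motifs (first exon's left flank sits in the spacer)
            if i == 0:
                _plant(spacer, ig - 2, left_motif)
            else:
                _plant(gseq, s - 2, left_motif)
            if i < n_ex - 1:
                _plant(gseq, e, right_motif)
            # alternative (shortened) boundaries, planted inside the exon
            elen = e - s
            if elen >= 60:
                d_end = int(rng.integers(10, min(26, elen - 30)))
                d_start = int(rng.integers(10, min(26, elen - 30)))
                alt_e = e - d_end
                alt_s = s + d_start
                _plant(gseq, alt_e, right_motif)
                _plant(gseq, alt_s - 2, left_motif)
                gene.alt_end[i] = cursor + ig + alt_e
                gene.alt_start[i] = cursor + ig + alt_s
        gene.exons = tuple(abs_exons)

        # trailing donor motif of the last exon lives in the next spacer; plant
        # it at the start of a short tail appended to the gene body
        tail = _rand_seq(rng, 50)
        _plant(tail, 0, right_motif)

        # flanking Alu-like elements around the gene span
        cat = rng.choice(list(config.alu_mix), p=list(config.alu_mix.values()))
        alu_truth[gene.gene_id] = str(cat)
        gene_start = cursor + ig
        gene_end = cursor + ig + gene_len
        L = config.alu_len

        def _pair(up_strand: str, dn_strand: str, off: int) -> None:
            us = gene_start - off - L
            ds = gene_end + off
            if us > 0:
                repeats.append(RepeatElement(config.chrom, us, us + L, up_strand))
                repeats.append(RepeatElement(config.chrom, ds, ds + L, dn_strand))

        if cat == "convergent":
            _pair("+", "-", 120)
        elif cat == "divergent":
            _pair("-", "+", 120)
        elif cat == "both":
            _pair("+", "-", 120)
            _pair("-", "+", 520)

        parts.extend([spacer, gseq, tail])
        cursor += ig + gene_len + len(tail)
        genes.append(gene)

    parts.append(_rand_seq(rng, int(rng.integers(lo_ig, hi_ig + 1))))
    genome = {config.chrom: b"".join(p.tobytes() for p in parts).decode()}
    repeats.sort(key=lambda r: (r.chrom, r.start))
    return genome, genes, repeats, alu_truth


# ---------------------------------------------------------------------------
# isoform simulation
# ---------------------------------------------------------------------------

def _run_blocks(gene: SimGene, i: int, j: int) -> list[tuple[int, int]]:
    return [list(gene.exons[k]) for k in range(i, j + 1)]  # type: ignore[return-value]


def simulate_circ_isoform(
    gene: SimGene, event: str, rng: np.random.Generator
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
    """Draw one circRNA isoform from `gene` carrying the given AS event.

    Returns ``(blocks, parent_blocks)``: the variant's exon blocks and the
    blocks of its event-free counterpart over the same exon run (identical
    BSJ).  For ``event='none'`` the two are equal.  Raises
    :class:`EventInfeasibleError` when the gene cannot host the event.
    """
    n = len(gene.exons)
    need = {"none": 1, "SE": 3, "A5SS": 2, "A3SS": 2, "RI": 2}[event]
    if n < need:
        raise EventInfeasibleError(f"{gene.gene_id}: {event} needs >= {need} exons")
    run_len = int(rng.integers(need, n + 1))
    i = int(rng.integers(0, n - run_len + 1))
    j = i + run_len - 1
    parent = [tuple(b) for b in _run_blocks(gene, i, j)]
    blocks = [list(b) for b in parent]

    if event == "none":
        pass
    elif event == "SE":
        m = int(rng.integers(1, len(blocks) - 1))
        del blocks[m]
    elif event in ("A5SS", "A3SS"):
        k = int(rng.integers(0, len(blocks) - 1))  # internal junction index
        # donor side: exon k end (+) / exon k+1 start (-); acceptor mirrored
        want_donor = event == "A5SS"
        left_side = (gene.strand == "+") == want_donor
        if left_side:
            exon_idx = i + k
            alt = gene.alt_end.get(exon_idx)
            if alt is None:
                raise EventInfeasibleError(f"{gene.gene_id}: no alt end on exon {exon_idx}")
            blocks[k][1] = alt
        else:
            exon_idx = i + k + 1
            alt = gene.alt_start.get(exon_idx)
            if alt is None:
                raise EventInfeasibleError(f"{gene.gene_id}: no alt start on exon {exon_idx}")
            blocks[k + 1][0] = alt
    elif event == "RI":
        k = int(rng.integers(0, len(blocks) - 1))
        blocks[k] = [blocks[k][0], blocks[k + 1][1]]
        del blocks[k + 1]
    else:
        raise ValueError(f"unknown event {event!r}")

    return tuple(tuple(b) for b in blocks), tuple(parent)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _draw_copies(config: SimConfig, rng: np.random.Generator) -> int:
    extra = config.copy_number_mean - config.copy_number_min
    if extra <= 0:
        return config.copy_number_min
    if config.copy_number_dist == "geometric":
        p = 1.0 / (1.0 + extra)
        return config.copy_number_min + int(rng.geometric(p)) - 1
    return config.copy_number_min + int(rng.poisson(extra))


def _apply_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitution/insertion/deletion errors."""
    if config.sub_rate == config.ins_rate == config.del_rate == 0.0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = codes.size
    idx = np.searchsorted(_BASES, codes)  # ACGT -> 0..3
    keep = rng.random(n) >= config.del_rate
    sub = rng.random(n) < config.sub_rate
    ins = rng.random(n) < config.ins_rate
    shift = rng.integers(1, 4, size=n)
    idx = np.where(sub, (idx + shift) % 4, idx)
    slots = np.empty(2 * n, dtype=np.uint8)
    slots[0::2] = _BASES[idx]
    slots[1::2] = _BASES[rng.integers(0, 4, size=n)]
    mask = np.empty(2 * n, dtype=bool)
    mask[0::2] = keep
    mask[1::2] = ins
    return slots[mask].tobytes().decode()


def simulate_rca_read(
    template: str, config: SimConfig, rng: np.random.Generator, read_id: str = "read", isoform_id: str = ""
) -> SimRead:
    """Emit one rolling-circle read from a circRNA spliced sequence.

    The error-free read is ``rotation(template, offset)`` repeated ``k``
    times, with ``offset`` uniform over the template and ``k`` drawn from the
    configured copy-number distribution (truncated at ``copy_number_min``);
    errors are then applied i.i.d. per base, and the read is emitted on
    either strand with equal probability.
    """
    if len(template) < 1:
        raise ValueError("template must be non-empty")
    offset = int(rng.integers(0, len(template)))
    k = _draw_copies(config, rng)
    rot = template[offset:] + template[:offset]
    clean = rot * k
    seq = _apply_errors(clean, config, rng)
    orientation = "+" if rng.random() < 0.5 else "-"
    if orientation == "-":
        seq = revcomp(seq)
    return SimRead(read_id, seq, ReadTruth(read_id, isoform_id, offset, k, orientation))


# ---------------------------------------------------------------------------
# dataset orchestration
# ---------------------------------------------------------------------------

def _variant_transcript(gene: SimGene, blocks, event: str, tid: str) -> Transcript:
    """Linear transcript documenting an event variant over the full gene."""
    # full-gene exon list with the variant's blocks substituted over its run
    run_start = blocks[0][0]
    run_end = blocks[-1][1]
    exons: list[tuple[int, int]] = []
    for s, e in gene.exons:
        if e <= run_start or s >= run_end:
            exons.append((s, e))
    exons.extend(tuple(b) for b in blocks)
    exons.sort()
    return Transcript(tid, gene.gene_id, gene.chrom, gene.strand, tuple(exons))


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full simulation: genome, isoforms, annotation, reads, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome, genes, repeats, alu_truth = simulate_genome(config, rng)
    by_id = {g.gene_id: g for g in genes}

    events = list(config.as_event_mix)
    probs = np.array([config.as_event_mix[e] for e in events], dtype=float)

    isoforms: list[IsoformTruth] = []
    seen: dict[tuple, str] = {}
    event_draws: list[str] = []
    doc_transcripts: list[Transcript] = []
    iso_n = 0

    def _add(gene: SimGene, blocks, event: str, documented: bool) -> IsoformTruth | None:
        nonlocal iso_n
        key = (gene.chrom, gene.strand, blocks)
        if key in seen:
            return None
        iso = IsoformTruth(
            f"iso{iso_n:04d}", gene.gene_id, gene.chrom, gene.strand, blocks, event, documented
        )
        iso_n += 1
        seen[key] = iso.isoform_id
        isoforms.append(iso)
        return iso

    # primary transcripts always documented
    for g in genes:
        doc_transcripts.append(Transcript(f"{g.gene_id}.t0", g.gene_id, g.chrom, g.strand, g.exons))

    attempts = 0
    max_attempts = config.n_isoforms * 60
    while len(isoforms) < config.n_isoforms and attempts < max_attempts:
        attempts += 1
        gene = by_id[genes[int(rng.integers(0, len(genes)))].gene_id]
        event = str(rng.choice(events, p=probs))
        try:
            blocks, parent = simulate_circ_isoform(gene, event, rng)
        except EventInfeasibleError:
            continue
        novel = event != "none" and bool(rng.random() < config.novel_site_rate)
        iso = _add(gene, blocks, event, documented=not novel)
        if iso is None:
            continue
        event_draws.append(event)
        if event != "none":
            if not novel:
                doc_transcripts.append(
                    _variant_transcript(gene, blocks, event, f"{gene.gene_id}.t{len(doc_transcripts)}")
                )
            if len(isoforms) < config.n_isoforms:
                _add(gene, parent, "none", documented=True)

    annotation = GeneAnnotation(_group_transcripts(doc_transcripts))
    circ_db = CircDB(
        [(iso.chrom, iso.bsj[0], iso.bsj[1]) for iso in isoforms], source="synthetic_db"
    )

    reads: list[SimRead] = []
    rid = 0
    for iso in isoforms:
        g = genome[iso.chrom]
        seq = "".join(g[s:e] for s, e in iso.blocks)
        if iso.strand == "-":
            seq = revcomp(seq)
        if isinstance(config.reads_per_isoform, tuple):
            n_reads = int(rng.integers(config.reads_per_isoform[0], config.reads_per_isoform[1] + 1))
        else:
            n_reads = int(config.reads_per_isoform)
        for _ in range(n_reads):
            reads.append(simulate_rca_read(seq, config, rng, f"read{rid:05d}", iso.isoform_id))
            rid += 1

    return SimResult(
        config=config,
        genome=genome,
        genes=genes,
        annotation=annotation,
        isoforms=isoforms,
        reads=reads,
        repeats=repeats,
        circ_db=circ_db,
        event_draws=event_draws,
        alu_truth=alu_truth,
    )


def _group_transcripts(transcripts: list[Transcript]) -> list[Gene]:
    genes: dict[str, Gene] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, Gene(t.gene_id, t.chrom, t.strand)).transcripts.append(t)
    return sorted(genes.values(), key=lambda g: g.gene_id)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[SimRead], path, quality: str = "I") -> None:
    """4-line FASTQ with a constant Q score (qualities are unused downstream)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((h.strip().lstrip("@").split()[0], seq))
    return out


def write_truth(result: SimResult, iso_path, read_path) -> None:
    with open(iso_path, "w") as fh:
        fh.write("isoform_id\tgene_id\tchrom\tstrand\tblocks\tevent\tdocumented\tbsj_start\tbsj_end\n")
        for iso in result.isoforms:
            blocks = ",".join(f"{s}-{e}" for s, e in iso.blocks)
            fh.write(
                f"{iso.isoform_id}\t{iso.gene_id}\t{iso.chrom}\t{iso.strand}\t{blocks}\t"
                f"{iso.event}\t{int(iso.documented)}\t{iso.bsj[0]}\t{iso.bsj[1]}\n"
            )
    with open(read_path, "w") as fh:
        fh.write("read_id\tisoform_id\toffset\tcopies\torientation\n")
        for r in result.reads:
            t = r.truth
            fh.write(f"{t.read_id}\t{t.isoform_id}\t{t.offset}\t{t.copies}\t{t.orientation}\n")


def write_dataset(result: SimResult, outdir) -> None:
    """Write the standard file set: genome.fa, annot.gtf, reads.fastq, circ_db.bed,
    repeats.bed, truth_isoforms.tsv, truth_reads.tsv."""
    import os

    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(str(outdir), name)
    write_fasta(result.genome, join("genome.fa"))
    write_gtf(join("annot.gtf"), result.annotation)
    write_fastq(result.reads, join("reads.fastq"))
    write_bed(
        join("circ_db.bed"),
        [(c, s, e, f"bsj{i}", 0, ".") for i, (c, s, e) in enumerate(sorted(result.circ_db))],
    )
    write_bed(
        join("repeats.bed"),
        [(r.chrom, r.start, r.end, r.family, 0, r.strand) for r in result.repeats],
    )
    write_truth(result, join("truth_isoforms.tsv"), join("truth_reads.tsv"))
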