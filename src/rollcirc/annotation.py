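"""Linear-transcript annotation, circRNA BSJ databases and repeat tracks.

Coordinate conventions used throughout the package:

* exon blocks and BED records are 0-based half-open ``(start, end)``;
* splice-site positions (donor/acceptor) are 1-based positions of the last /
  first exonic base, matching GTF arithmetic;
* a BSJ is identified by the 0-based half-open genomic interval of the circle,
  ``(chrom, start, end)``, which is also the key used for database lookup.

A *donor* site is the exonic base 5' of an intron in transcript orientation,
an *acceptor* the exonic base 3' of it.  On the plus strand a donor therefore
sits at an exon end and an acceptor at an exon start; on the minus strand the
roles are mirrored.  Site sets include every exon boundary of every annotated
transcript, so back-splice sites reusing annotated boundaries are recognized
even when they coincide with terminal exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Transcript",
    "Gene",
    "GeneAnnotation",
    "CircDB",
    "RepeatElement",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_repeats_bed",
]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, genomic order

    def __post_init__(self) -> None:
        ex = self.exons
        for a, b in ex:
            if a >= b:
                raise ValueError(f"empty exon in {self.transcript_id}: {(a, b)}")
        for (_, b), (c, _) in zip(ex, ex[1:]):
            if c < b:
                raise ValueError(f"overlapping/unordered exons in {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def junction_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered FSJ chain as (left_exon_end, right_exon_start), 1-based.

        ``left_exon_end`` is the 1-based position of the last base of the
        genomically-left exon; ``right_exon_start`` the first base of the
        next exon.  The chain is in genomic order regardless of strand.
        """
        return tuple((e1, s2 + 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)

    def donor_sites(self) -> set[int]:
        """1-based genomic positions of donor (5') splice sites."""
        out: set[int] = set()
        for t in self.transcripts:
            for s, e in t.exons:
                out.add(e if self.strand == "+" else s + 1)
        return out

    def acceptor_sites(self) -> set[int]:
        out: set[int] = set()
        for t in self.transcripts:
            for s, e in t.exons:
                out.add(s + 1 if self.strand == "+" else e)
        return out


class GeneAnnotation:
    """Gene models plus fast splice-site and junction-chain lookups."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        # (chrom, strand, pos) sets
        self.donors: set[tuple[str, str, int]] = set()
        self.acceptors: set[tuple[str, str, int]] = set()
        self._chains: list[tuple[str, str, tuple[tuple[int, int], ...]]] = []
        for g in genes:
            for d in g.donor_sites():
                self.donors.add((g.chrom, g.strand, d))
            for a in g.acceptor_sites():
                self.acceptors.add((g.chrom, g.strand, a))
            for t in g.transcripts:
                self._chains.append((g.chrom, g.strand, t.junction_chain()))

    def is_donor(self, chrom: str, strand: str, pos: int) -> bool:
        return (chrom, strand, pos) in self.donors

    def is_acceptor(self, chrom: str, strand: str, pos: int) -> bool:
        return (chrom, strand, pos) in self.acceptors

    def chain_contains(self, chrom: str, strand: str, fsjs: tuple[tuple[int, int], ...]) -> bool:
        """True if `fsjs` is a contiguous sub-chain of some transcript chain."""
        k = len(fsjs)
        if k == 0:
            return True
        for c, s, chain in self._chains:
            if c != chrom or s != strand or len(chain) < k:
                continue
            for i in range(len(chain) - k + 1):
                if chain[i : i + k] == fsjs:
                    return True
        return False

    def genes_on(self, chrom: str, strand: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom and g.strand == strand]


class CircDB:
    """A known-BSJ database: set of (chrom, start, end) circle intervals.

    Matching is by exact coordinates (0-based half-open interval of the
    circle); strand, when present in the source BED, is carried but not used
    for lookup because splice-site correction already normalizes coordinates.
    """

    def __init__(self, bsjs, source: str = "db"):
        self.source = source
        self._set: set[tuple[str, int, int]] = {(c, int(s), int(e)) for c, s, e, *_ in bsjs}

    def __contains__(self, key: tuple[str, int, int]) -> bool:
        return key in self._set

    def __len__(self) -> int:
        return len(self._set)

    def __iter__(self):
        return iter(self._set)


@dataclass(frozen=True)
class RepeatElement:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    family: str = "Alu"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("repeat element with start >= end")


# ---------------------------------------------------------------------------
# GTF / BED I/O.  The toy GTFs written by the simulator carry only `exon`
# features with gene_id/transcript_id attributes, the subset every GTF2.2
# reader agrees on; parsing that subset directly keeps the round trip exact.
# ---------------------------------------------------------------------------

def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        k, _, v = part.partition(" ")
        out[k] = v.strip().strip('"')
    return out


def read_gtf(path) -> GeneAnnotation:
    """Read exon features from a GTF (1-based inclusive) into gene models."""
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = _parse_attrs(f[8])
            tid = attrs["transcript_id"]
            tx_meta[tid] = (attrs["gene_id"], f[0], f[6])
            tx_exons.setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
    genes: dict[str, Gene] = {}
    for tid, exons in tx_exons.items():
        gid, chrom, strand = tx_meta[tid]
        tr = Transcript(tid, gid, chrom, strand, tuple(sorted(exons)))
        genes.setdefault(gid, Gene(gid, chrom, strand)).transcripts.append(tr)
    return GeneAnnotation(sorted(genes.values(), key=lambda g: g.gene_id))


def write_gtf(path, annotation: GeneAnnotation | list[Gene]) -> None:
    genes = annotation.genes.values() if isinstance(annotation, GeneAnnotation) else annotation
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                    fh.write(
                        f"{t.chrom}\trollcirc\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


def read_bed(path, source: str | None = None) -> CircDB:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            rows.append((f[0], int(f[1]), int(f[2])))
    return CircDB(rows, source=source or str(path))


def write_bed(path, rows) -> None:
    """Write BED6 rows: iterable of (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_repeats_bed(path) -> list[RepeatElement]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            family = f[3] if len(f) > 3 else "Alu"
            strand = f[5] if len(f) > 5 else "+"
            out.append(RepeatElement(f[0], int(f[1]), int(f[2]), strand, family))
    return out
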