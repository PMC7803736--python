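"""Isoform cataloging: collapse per-read calls, classify, assign, name.

Per-read junction calls with identical structure -- same chromosome, strand,
back-splice circle and ordered FSJ list -- merge into one circRNA isoform
whose per-sample read counts accumulate ("read count" is the number of
independent reads, distinct from the within-read copy number).  BSJ-level
counts are the sums over isoforms sharing a circle.

Classification follows the long-read transcript nomenclature: a BSJ is FSM
(full splice match) when its circle is present in a circRNA database, NIC
(novel in catalog) when both back-splice sites are annotated splice sites,
and NNC otherwise; the FSJ set of an isoform is FSM when it matches a
contiguous run of some annotated transcript's junction chain (single-exon
circles, having no FSJ, are FSM by definition), NIC when all forward-splice
sites are annotated, and NNC otherwise.

Gene assignment picks the strand-consistent gene sharing the most splice
sites with the isoform (ties assign multiple genes; zero shared sites falls
back to any strand-consistent gene with >=1 bp overlap, else NA), and
isoforms are numbered per gene by descending median read count across
samples (mean, then structural key, break ties).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rollcirc.annotation import CircDB, Gene, GeneAnnotation
from rollcirc.junction import ReadCall

__all__ = [
    "CircIsoform",
    "CircCatalog",
    "ASEvent",
    "collapse_isoforms",
    "classify_bsj_known",
    "classify_bsj_category",
    "classify_fsj_category",
    "assign_gene",
    "name_isoforms",
    "annotate_catalog",
    "pair_alternative_splicing_events",
]


@dataclass
class CircIsoform:
    chrom: str
    strand: str
    circle: tuple[int, int]  # 0-based half-open
    fsjs: tuple[tuple[int, int], ...]  # 1-based (low, high)
    blocks: tuple[tuple[int, int], ...]
    counts: dict[str, int] = field(default_factory=dict)
    bsj_known: str = ""  # 'known' | 'novel'
    bsj_sources: tuple[str, ...] = ()
    bsj_category: str = ""  # FSM | NIC | NNC
    fsj_category: str = ""
    gene_ids: tuple[str, ...] = ()
    name: str = ""

    @property
    def key(self):
        return (self.chrom, self.strand, self.circle, self.fsjs)

    @property
    def bsj_key(self) -> tuple[str, int, int]:
        return (self.chrom, *self.circle)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def n_exons(self) -> int:
        return len(self.blocks)

    def total_count(self) -> int:
        return sum(self.counts.values())

    def splice_sites(self) -> set[tuple[str, int]]:
        """All (kind, 1-based position) splice sites incl. back-splice sites."""
        s0, e0 = self.circle
        if self.strand == "-":
            sites = {("donor", s0 + 1), ("acceptor", e0)}
        else:
            sites = {("donor", e0), ("acceptor", s0 + 1)}
        for lo, hi in self.fsjs:
            if self.strand == "-":
                sites.add(("donor", hi))
                sites.add(("acceptor", lo))
            else:
                sites.add(("donor", lo))
                sites.add(("acceptor", hi))
        return sites


@dataclass
class CircCatalog:
    isoforms: list[CircIsoform]
    counts: pd.DataFrame  # isoform name/index x sample
    bsj_counts: pd.DataFrame  # rows: (chrom, start, end), columns: samples

    def filter_min_reads(self, min_reads: int, per_sample: bool = False) -> "CircCatalog":
        """Keep isoforms with total (or any single-sample) read count >= cutoff."""
        if per_sample:
            keep = [i for i in self.isoforms if any(c >= min_reads for c in i.counts.values())]
        else:
            keep = [i for i in self.isoforms if i.total_count() >= min_reads]
        keys = {i.key for i in keep}
        counts = self.counts.loc[[k in keys for k in self.counts.index]]
        return CircCatalog(keep, counts, _bsj_table(keep, list(self.counts.columns)))


def _bsj_table(isoforms: list[CircIsoform], samples: list[str]) -> pd.DataFrame:
    agg: dict[tuple, Counter] = defaultdict(Counter)
    for iso in isoforms:
        for s, c in iso.counts.items():
            agg[iso.bsj_key][s] += c
    rows = []
    for key in sorted(agg):
        row = {"chrom": key[0], "start": key[1], "end": key[2]}
        for s in samples:
            row[s] = agg[key].get(s, 0)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", *samples])
    return df.set_index(["chrom", "start", "end"]) if rows else df


def collapse_isoforms(calls_by_sample: dict[str, list[ReadCall]]) -> CircCatalog:
    """Merge full-length per-read calls into quantified isoforms.

    Only calls with a high-confidence BSJ *and* all-high FSJs (full-length
    isoforms) enter the isoform catalog; BSJ-level counts are emitted as the
    sum over isoforms sharing a BSJ, so the conservation invariant
    ``sum(isoform counts of a BSJ) == BSJ count`` holds by construction.
    """
    samples = list(calls_by_sample)
    merged: dict[tuple, CircIsoform] = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            if not call.is_full_length:
                continue
            key = call.isoform_key
            iso = merged.get(key)
            if iso is None:
                iso = CircIsoform(call.chrom, call.strand, call.circle, call.fsjs, call.blocks)
                merged[key] = iso
            iso.counts[sample] = iso.counts.get(sample, 0) + 1
    isoforms = [merged[k] for k in sorted(merged)]
    keys = np.empty(len(isoforms), dtype=object)
    keys[:] = [iso.key for iso in isoforms]
    counts = pd.DataFrame(
        [[iso.counts.get(s, 0) for s in samples] for iso in isoforms],
        index=pd.Index(keys, name="isoform_key"),
        columns=samples,
        dtype=int,
    )
    return CircCatalog(isoforms, counts, _bsj_table(isoforms, samples))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_bsj_known(bsj_key: tuple[str, int, int], circ_dbs: list[CircDB]):
    """known/novel status plus the databases that contain the BSJ."""
    sources = tuple(db.source for db in circ_dbs if bsj_key in db)
    return ("known" if sources else "novel"), sources


def _bsj_donor_acceptor(iso: CircIsoform) -> tuple[int, int]:
    s0, e0 = iso.circle
    return (s0 + 1, e0) if iso.strand == "-" else (e0, s0 + 1)


def classify_bsj_category(
    iso: CircIsoform, circ_dbs: list[CircDB], annotation: GeneAnnotation
) -> str:
    if any(iso.bsj_key in db for db in circ_dbs):
        return "FSM"
    d, a = _bsj_donor_acceptor(iso)
    if annotation.is_donor(iso.chrom, iso.strand, d) and annotation.is_acceptor(
        iso.chrom, iso.strand, a
    ):
        return "NIC"
    return "NNC"


def classify_fsj_category(iso: CircIsoform, annotation: GeneAnnotation) -> str:
    if not iso.fsjs:
        return "FSM"  # single-exon circRNA
    if annotation.chain_contains(iso.chrom, iso.strand, iso.fsjs):
        return "FSM"
    for lo, hi in iso.fsjs:
        d, a = (hi, lo) if iso.strand == "-" else (lo, hi)
        if not (
            annotation.is_donor(iso.chrom, iso.strand, d)
            and annotation.is_acceptor(iso.chrom, iso.strand, a)
        ):
            return "NNC"
    return "NIC"


def assign_gene(iso: CircIsoform, annotation: GeneAnnotation) -> tuple[str, ...]:
    """Assigned gene(s) for an isoform, or () for NA."""
    candidates = annotation.genes_on(iso.chrom, iso.strand)
    if not candidates:
        return ()
    iso_sites = iso.splice_sites()
    shared: list[tuple[int, str]] = []
    for g in candidates:
        gd = g.donor_sites()
        ga = g.acceptor_sites()
        n = sum(
            1
            for kind, pos in iso_sites
            if (pos in gd if kind == "donor" else pos in ga)
        )
        shared.append((n, g.gene_id))
    best = max(n for n, _ in shared)
    if best > 0:
        return tuple(sorted(gid for n, gid in shared if n == best))
    s0, e0 = iso.circle
    overlapping = [
        g.gene_id for g in candidates if g.span[0] < e0 and g.span[1] > s0
    ]
    return tuple(sorted(overlapping))


def name_isoforms(isoforms: list[CircIsoform], counts: pd.DataFrame) -> None:
    """Assign geneID.circRNA.N names, in place.

    Rank within each gene by median read count across samples, ties by mean,
    remaining ties by structural key (documented fallback), so naming is
    invariant to the input order of isoforms.
    """
    groups: dict[str, list[CircIsoform]] = defaultdict(list)
    for iso in isoforms:
        label = ",".join(iso.gene_ids) if iso.gene_ids else "NA"
        groups[label].append(iso)
    samples = list(counts.columns)
    for label, members in groups.items():
        def rank_key(iso: CircIsoform):
            row = [iso.counts.get(s, 0) for s in samples]
            return (-float(np.median(row)), -float(np.mean(row)), iso.key)

        for n, iso in enumerate(sorted(members, key=rank_key), start=1):
            iso.name = f"{label}.circRNA.{n}"


def annotate_catalog(
    catalog: CircCatalog, circ_dbs: list[CircDB], annotation: GeneAnnotation
) -> CircCatalog:
    """Run known/novel + FSM/NIC/NNC classification, gene assignment, naming."""
    for iso in catalog.isoforms:
        iso.bsj_known, iso.bsj_sources = classify_bsj_known(iso.bsj_key, circ_dbs)
        iso.bsj_category = classify_bsj_category(iso, circ_dbs, annotation)
        iso.fsj_category = classify_fsj_category(iso, annotation)
        iso.gene_ids = assign_gene(iso, annotation)
    name_isoforms(catalog.isoforms, catalog.counts)
    return catalog


# ---------------------------------------------------------------------------
# alternative-splicing event pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ASEvent:
    gene: str
    predominant: str  # isoform name
    other: str
    scope: str  # 'BSJ only' | 'FSJs only' | 'both'
    etypes: tuple[str, ...]  # SE / A5SS / A3SS / RI / complex, internal only
    minor_count: int


def _internal_event_types(a_blocks, b_blocks, strand: str) -> tuple[str, ...]:
    """Decompose the block differences of two same-BSJ isoforms into events."""
    A, B = list(a_blocks), list(b_blocks)
    setA, setB = set(A), set(B)
    diffA = [x for x in A if x not in setB]
    diffB = [x for x in B if x not in setA]
    events: list[str] = []

    def consume_ri(src, src_blocks, dst):
        """Find blocks in `src` spanning two consecutive `dst` blocks + intron."""
        hit = []
        for x in list(src):
            for b1, b2 in zip(dst, dst[1:]):
                if x[0] == b1[0] and x[1] == b2[1] and b1[1] < b2[0]:
                    events.append("RI")
                    hit.append((x, b1, b2))
                    src.remove(x)
                    break
        for _, b1, b2 in hit:
            for lst in (diffA, diffB):
                for y in (b1, b2):
                    if y in lst:
                        lst.remove(y)

    consume_ri(diffA, A, B)
    consume_ri(diffB, B, A)

    # skipped exons: a block absent from the other isoform, not overlapping
    # any of its blocks
    for src, other_blocks in ((diffA, B), (diffB, A)):
        for x in list(src):
            if not any(x[0] < e and x[1] > s for s, e in other_blocks):
                events.append("SE")
                src.remove(x)

    # boundary shifts between remaining paired blocks
    used_b: set = set()
    for x in list(diffA):
        for y in diffB:
            if y in used_b:
                continue
            if x[0] == y[0] and x[1] != y[1]:
                events.append("A5SS" if strand == "+" else "A3SS")
                used_b.add(y)
                diffA.remove(x)
                break
            if x[1] == y[1] and x[0] != y[0]:
                events.append("A3SS" if strand == "+" else "A5SS")
                used_b.add(y)
                diffA.remove(x)
                break
    diffB = [y for y in diffB if y not in used_b]
    if diffA or diffB:
        events.append("complex")
    return tuple(sorted(events))


def pair_alternative_splicing_events(
    isoforms: list[CircIsoform], counts: pd.DataFrame
) -> list[ASEvent]:
    """Compare each gene's predominant isoform to every other isoform.

    The predominant isoform has the highest median read count across samples
    (mean on ties).  Each pair is labeled by where it differs (BSJ only,
    FSJs only, or both); pairs sharing the BSJ additionally get internal
    event types (SE/A5SS/A3SS/RI) from block-set comparison.  Minor-isoform
    read-count strata (>=2, >=5, >=10) are left to the caller via
    ``minor_count``.
    """
    groups: dict[str, list[CircIsoform]] = defaultdict(list)
    for iso in isoforms:
        label = ",".join(iso.gene_ids) if iso.gene_ids else "NA"
        groups[label].append(iso)
    events: list[ASEvent] = []
    samples = list(counts.columns)
    for label, members in groups.items():
        if len(members) < 2:
            continue
        def rank_key(iso: CircIsoform):
            row = [iso.counts.get(s, 0) for s in samples]
            return (-float(np.median(row)), -float(np.mean(row)), iso.key)

        members = sorted(members, key=rank_key)
        pred = members[0]
        for other in members[1:]:
            bsj_diff = pred.circle != other.circle or pred.chrom != other.chrom
            fsj_diff = pred.fsjs != other.fsjs
            if not bsj_diff and not fsj_diff:
                continue
            scope = "both" if (bsj_diff and fsj_diff) else ("BSJ only" if bsj_diff else "FSJs only")
            etypes: tuple[str, ...] = ()
            if not bsj_diff:
                etypes = _internal_event_types(pred.blocks, other.blocks, pred.strand)
            events.append(
                ASEvent(label, pred.name, other.name, scope, etypes, other.total_count())
            )
    return events


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def isoforms_table(catalog: CircCatalog) -> pd.DataFrame:
    samples = list(catalog.counts.columns)
    rows = []
    for iso in catalog.isoforms:
        rows.append(
            {
                "name": iso.name,
                "chrom": iso.chrom,
                "start": iso.circle[0],
                "end": iso.circle[1],
                "strand": iso.strand,
                "n_exons": iso.n_exons,
                "length": iso.length,
                "blocks": ",".join(f"{s}-{e}" for s, e in iso.blocks),
                "bsj_known": iso.bsj_known,
                "bsj_sources": ",".join(iso.bsj_sources),
                "bsj_category": iso.bsj_category,
                "fsj_category": iso.fsj_category,
                "genes": ",".join(iso.gene_ids) if iso.gene_ids else "NA",
                **{s: iso.counts.get(s, 0) for s in samples},
            }
        )
    return pd.DataFrame(rows)


def write_isoforms_bed12(catalog: CircCatalog, path) -> None:
    with open(path, "w") as fh:
        for iso in catalog.isoforms:
            s0, e0 = iso.circle
            sizes = ",".join(str(e - s) for s, e in iso.blocks)
            starts = ",".join(str(s - s0) for s, _ in iso.blocks)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        iso.chrom, s0, e0, iso.name or "iso", iso.total_count(),
                        iso.strand, s0, e0, "0,0,0", iso.n_exons, sizes, starts,
                    )
                )
                + "\n"
            )
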