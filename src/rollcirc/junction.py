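"""BSJ/FSJ calling from two-copy concatemer alignments.

Each selected consensus is doubled into a two-copy concatemer and
spliced-aligned; the alignment's forward genomic jumps are forward-splice
junctions (FSJs) and the backward wrap -- where the alignment runs off the
end of one template copy and resumes at the circle start -- is the
back-splice junction (BSJ).  Because the concatemer traverses the circle
exactly twice, every junction of the circle should be observed twice; this
two-copy concordance is required before a BSJ is emitted.

Called junctions are then corrected: donor/acceptor coordinates may shift by
up to a small search window to the nearest annotated splice-site pair, or
failing that to a canonical GT-AG (CT-AC on the minus strand) motif, which
also fixes the strand of the circRNA.  Finally, confidence filters are
applied: BSJs built from annotated or database-known sites are accepted as
called, while BSJs involving any novel splice site additionally require
near-perfect alignment identity in a window around the BSJ and a canonical
motif.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import product

import edlib
import numpy as np

from rollcirc.align import (
    AlignmentRecord,
    AlignParams,
    GenomeIndex,
    filter_alignments,
    spliced_align,
)
from rollcirc.annotation import CircDB, GeneAnnotation
from rollcirc.consensus import ConsensusRecord

__all__ = [
    "Junction",
    "JunctionParams",
    "ReadCall",
    "make_concatemer",
    "junction_observations",
    "call_junctions",
    "refine_splice_sites",
    "evaluate_confidence",
    "call_read",
]

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Junction:
    """A splice junction in genomic coordinates.

    ``low``/``high`` are 1-based positions of the two exonic boundary bases,
    with ``low < high``: for an FSJ, ``low`` is the last base of the left
    exon and ``high`` the first base of the right exon; for a BSJ they are
    the first and last base of the circle.  ``donor``/``acceptor`` follow
    from strand and junction type: an FSJ donor precedes its acceptor in the
    genome on the plus strand, while a BSJ donor lies *downstream* of its
    acceptor (the definition of back-splicing), mirrored on the minus strand.
    """

    chrom: str
    jtype: str  # 'BSJ' | 'FSJ'
    low: int
    high: int
    strand: str = "."
    motif: str = ""
    annotated_donor: bool = False
    annotated_acceptor: bool = False
    confidence: str = "low"

    def __post_init__(self) -> None:
        if self.jtype not in ("BSJ", "FSJ"):
            raise ValueError(f"bad jtype {self.jtype}")
        if self.low >= self.high:
            raise ValueError("junction low must be < high")

    @property
    def donor(self) -> int:
        if self.jtype == "FSJ":
            return self.low if self.strand != "-" else self.high
        return self.high if self.strand != "-" else self.low

    @property
    def acceptor(self) -> int:
        if self.jtype == "FSJ":
            return self.high if self.strand != "-" else self.low
        return self.low if self.strand != "-" else self.high

    @property
    def circle(self) -> tuple[int, int]:
        """0-based half-open genomic interval (BSJ only)."""
        if self.jtype != "BSJ":
            raise ValueError("circle interval is defined for BSJs only")
        return self.low - 1, self.high


@dataclass
class JunctionParams:
    mapq_min: int = 1
    refine_window: int = 10
    novel_window: int = 20
    novel_id_min: float = 0.98
    min_intron: int = 30
    end_slack: int = 50
    align: AlignParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.align is None:
            self.align = AlignParams(min_intron=self.min_intron)


def make_concatemer(consensus: ConsensusRecord | str) -> str:
    """Two copies of the consensus sequence, head to tail."""
    seq = consensus.consensus_seq if isinstance(consensus, ConsensusRecord) else consensus
    if not seq:
        raise ValueError("empty consensus")
    return seq + seq


# ---------------------------------------------------------------------------
# junction observations from alignment blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionObs:
    kind: str  # 'FSJ' | 'BSJ'
    low: int  # 1-based
    high: int
    qpos: int  # query offset of the junction


def junction_observations(aln: AlignmentRecord, min_intron: int = 30) -> list[JunctionObs]:
    obs = []
    for (q1s, q1e, t1s, t1e), (q2s, q2e, t2s, t2e) in zip(aln.blocks, aln.blocks[1:]):
        tgap = t2s - t1e
        if tgap >= min_intron:
            obs.append(JunctionObs("FSJ", t1e, t2s + 1, q1e))
        elif tgap < 0:
            # wrap: circle runs from t2s (start) to t1e (end)
            obs.append(JunctionObs("BSJ", t2s + 1, t1e, q1e))
        # small gaps are residual indels next to a jump; ignore
    return obs


def _cluster_obs(obs: list[JunctionObs], tol: int, total_q: int) -> list[list[JunctionObs]]:
    """Greedily cluster junction observations whose coordinates agree within
    `tol` (residual consensus errors jitter the jump point by a few bases)."""
    clusters: list[list[JunctionObs]] = []
    for o in sorted(obs, key=lambda o: (o.low, o.high, o.qpos)):
        for cl in clusters:
            if abs(o.low - cl[0].low) <= tol and abs(o.high - cl[0].high) <= tol:
                cl.append(o)
                break
        else:
            clusters.append([o])
    # representative = the observation farthest from the query ends, where the
    # alignment context is most reliable
    for cl in clusters:
        cl.sort(key=lambda o: (-min(o.qpos, total_q - o.qpos), o.qpos))
    return clusters


def call_junctions(
    aln: AlignmentRecord,
    min_intron: int = 30,
    end_slack: int = 50,
    min_terminal_block: int = 8,
    merge_tol: int = 8,
) -> tuple[Junction | None, list[Junction], dict]:
    """Extract the BSJ and FSJ set from a concatemer alignment.

    Requires two-copy concordance: all wrap observations must agree on a
    single BSJ (within `merge_tol` of coordinate jitter), and every distinct
    FSJ must be observed twice.  A junction seen only once is tolerated only
    when its twin -- expected one template copy away along the query --
    would fall within ``end_slack`` of the query ends, where the flanking
    partial copy may have been clipped.  Returns ``(bsj, fsjs, info)``;
    ``bsj`` is None (with ``info['reason']``) when no confident call can be
    made.
    """
    blocks = [b for b in aln.blocks if b[1] - b[0] >= min_terminal_block]
    aln2 = replace_blocks(aln, blocks)
    obs = junction_observations(aln2, min_intron)
    info: dict = {"n_obs": len(obs)}
    total_q = aln.query_length
    unit = total_q // 2  # concatemer = two template copies

    bsj_obs = [o for o in obs if o.kind == "BSJ"]
    fsj_obs = [o for o in obs if o.kind == "FSJ"]
    if not bsj_obs:
        info["reason"] = "no_bsj"
        return None, [], info
    bsj_clusters = _cluster_obs(bsj_obs, merge_tol, total_q)
    if len(bsj_clusters) > 1:
        info["reason"] = "discordant_bsj"
        return None, [], info
    rep = bsj_clusters[0][0]
    s, e = rep.low, rep.high
    # template length estimate: spacing of wrap points (robust if the chosen
    # consensus spans more than one template copy), else half the concatemer
    wrap_q = sorted(o.qpos for o in bsj_obs)
    if len(wrap_q) >= 2:
        unit = int(np.median(np.diff(wrap_q)))
    n_traversals = len(wrap_q) + 1

    fsjs: list[Junction] = []
    for cl in _cluster_obs(fsj_obs, merge_tol, total_q):
        if len(cl) > n_traversals:
            info["reason"] = "discordant_fsj"
            return None, [], info
        if len(cl) == 1:
            q = cl[0].qpos
            twins = (q - unit, q + unit)
            if not any(t <= end_slack or t >= total_q - end_slack for t in twins):
                info["reason"] = "discordant_fsj"
                return None, [], info
        lo, hi = cl[0].low, cl[0].high
        if not (s <= lo < hi <= e):
            info["reason"] = "fsj_outside_circle"
            return None, [], info
        fsjs.append(Junction(aln.chrom, "FSJ", lo, hi))

    bsj = Junction(aln.chrom, "BSJ", s, e)
    fsjs.sort(key=lambda f: f.low)
    for f1, f2 in zip(fsjs, fsjs[1:]):
        if f2.low <= f1.high:
            info["reason"] = "overlapping_fsjs"
            return None, [], info
    info["wrap_qpos"] = [o.qpos for o in bsj_obs]
    return bsj, fsjs, info


def replace_blocks(aln: AlignmentRecord, blocks) -> AlignmentRecord:
    out = AlignmentRecord(
        aln.query_id, aln.chrom, aln.strand, list(blocks), aln.score, aln.mapq,
        aln.identity, aln.query_length, aln.matches, aln.oriented_query,
    )
    return out


# ---------------------------------------------------------------------------
# splice-site correction
# ---------------------------------------------------------------------------

def donor_motif(gseq: str, strand: str, d: int) -> str:
    """Intron dinucleotide just past a donor base (1-based), read 5'->3'."""
    if strand == "-":
        return gseq[d - 3 : d - 1].translate(_RC)[::-1]
    return gseq[d : d + 2]


def acceptor_motif(gseq: str, strand: str, a: int) -> str:
    if strand == "-":
        return gseq[a : a + 2].translate(_RC)[::-1]
    return gseq[a - 3 : a - 1]


@lru_cache(maxsize=8)
def _shift_order(w: int) -> tuple[tuple[int, int], ...]:
    return tuple(
        sorted(product(range(-w, w + 1), repeat=2), key=lambda t: (abs(t[0]) + abs(t[1]), t[0], t[1]))
    )


def _da_to_lowhigh(jtype: str, strand: str, d: int, a: int) -> tuple[int, int]:
    if jtype == "FSJ":
        return (d, a) if strand != "-" else (a, d)
    return (a, d) if strand != "-" else (d, a)


def refine_splice_sites(
    j: Junction,
    genome: dict[str, str],
    annotation: GeneAnnotation | None,
    search_window: int = 10,
    strands: str = "+-",
) -> Junction:
    """Snap a junction to nearby annotated splice sites or canonical motifs.

    Search order: annotated donor+acceptor pairs first, then canonical
    GT-AG motifs, at increasing total shift (so an already-annotated or
    already-canonical junction is a fixed point).  The strand is set by the
    matching orientation.  If nothing matches within the window the junction
    keeps its coordinates with ``confidence='low'``.
    """
    if search_window < 0:
        raise ValueError("search_window must be >= 0")
    gseq = genome[j.chrom]
    shifts = _shift_order(search_window)

    for mode in ("annotated", "canonical"):
        if mode == "annotated" and annotation is None:
            continue
        for dd, da in shifts:
            for strand in strands:
                d0 = (j.high if ((j.jtype == "BSJ") != (strand == "-")) else j.low) + dd
                a0 = (j.low if ((j.jtype == "BSJ") != (strand == "-")) else j.high) + da
                lo, hi = _da_to_lowhigh(j.jtype, strand, d0, a0)
                if lo >= hi or lo < 3 or hi + 2 > len(gseq):
                    continue
                if mode == "annotated":
                    ok = annotation.is_donor(j.chrom, strand, d0) and annotation.is_acceptor(
                        j.chrom, strand, a0
                    )
                else:
                    ok = (
                        donor_motif(gseq, strand, d0) == "GT"
                        and acceptor_motif(gseq, strand, a0) == "AG"
                    )
                if ok:
                    return Junction(
                        j.chrom,
                        j.jtype,
                        lo,
                        hi,
                        strand=strand,
                        motif=f"{donor_motif(gseq, strand, d0)}-{acceptor_motif(gseq, strand, a0)}",
                        annotated_donor=annotation.is_donor(j.chrom, strand, d0)
                        if annotation
                        else False,
                        annotated_acceptor=annotation.is_acceptor(j.chrom, strand, a0)
                        if annotation
                        else False,
                        confidence="high",
                    )
    strand = j.strand if j.strand in "+-" else "+"
    d0 = j.high if ((j.jtype == "BSJ") != (strand == "-")) else j.low
    a0 = j.low if ((j.jtype == "BSJ") != (strand == "-")) else j.high
    return replace(
        j,
        strand=strand,
        motif=f"{donor_motif(gseq, strand, d0)}-{acceptor_motif(gseq, strand, a0)}",
        confidence="low",
    )


# ---------------------------------------------------------------------------
# confidence evaluation
# ---------------------------------------------------------------------------

def bsj_window_identity(
    query: str, wrap_qpos: int, gseq: str, s: int, e: int, w: int = 20
) -> float:
    """Alignment identity of the query around the wrap vs the back-splice
    reference (last w bases of the circle joined to its first w bases).

    ``s``/``e`` are the 1-based first/last circle bases; ``query`` is the
    genome-oriented concatemer.
    """
    ref = gseq[max(0, e - w) : e] + gseq[s - 1 : s - 1 + w]
    qs = max(0, wrap_qpos - w)
    qe = min(len(query), wrap_qpos + w)
    seg = query[qs:qe]
    if not seg or not ref:
        return 0.0
    d = edlib.align(seg, ref, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(seg), len(ref))


def evaluate_confidence(
    bsj: Junction,
    fsjs: list[Junction],
    circ_dbs: list[CircDB],
    window_identity: float | None = None,
    novel_id_min: float = 0.98,
) -> tuple[bool, bool]:
    """Decide (bsj_high, all_fsj_high).

    A BSJ whose donor and acceptor are both annotated (gene annotation) or
    whose circle is present in a circRNA database is high-confidence when
    splice-site correction succeeded.  A BSJ involving any novel site must
    additionally show near-perfect local alignment identity around the BSJ
    (``window_identity >= novel_id_min``) and a canonical motif.  A consensus
    with a high-confidence BSJ is a candidate circRNA; a candidate whose
    FSJs are all high-confidence is a full-length circRNA isoform.
    """
    in_db = any((bsj.chrom, *bsj.circle) in db for db in circ_dbs)
    known_sites = (bsj.annotated_donor and bsj.annotated_acceptor) or in_db
    if known_sites:
        bsj_high = bsj.confidence == "high"
    else:
        wid = -1.0 if window_identity is None else window_identity
        bsj_high = bsj.confidence == "high" and bsj.motif == "GT-AG" and wid >= novel_id_min
    all_fsj_high = all(f.confidence == "high" for f in fsjs)
    return bsj_high, all_fsj_high


# ---------------------------------------------------------------------------
# per-read orchestration
# ---------------------------------------------------------------------------

@dataclass
class ReadCall:
    read_id: str
    drop_reason: str | None = None
    chrom: str = ""
    strand: str = "."
    circle: tuple[int, int] | None = None  # 0-based half-open
    fsjs: tuple[tuple[int, int], ...] = ()  # 1-based (low, high) pairs
    blocks: tuple[tuple[int, int], ...] = ()  # 0-based half-open exon blocks
    bsj: Junction | None = None
    fsj_junctions: tuple[Junction, ...] = ()
    bsj_high: bool = False
    all_fsj_high: bool = False

    @property
    def is_candidate(self) -> bool:
        return self.bsj_high

    @property
    def is_full_length(self) -> bool:
        return self.bsj_high and self.all_fsj_high

    @property
    def isoform_key(self):
        return (self.chrom, self.strand, self.circle, self.fsjs)


def blocks_from_junctions(circle: tuple[int, int], fsjs) -> tuple[tuple[int, int], ...]:
    """Exon blocks (0-based half-open) from a circle interval and FSJ list."""
    s0, e0 = circle
    bounds = [s0]
    for lo, hi in fsjs:
        bounds.extend([lo, hi - 1])
    bounds.append(e0)
    blocks = []
    for i in range(0, len(bounds), 2):
        a, b = bounds[i], bounds[i + 1]
        if a >= b:
            raise ValueError("empty exon block")
        blocks.append((a, b))
    return tuple(blocks)


def call_read(
    cons: ConsensusRecord,
    index: GenomeIndex,
    annotation: GeneAnnotation | None,
    circ_dbs: list[CircDB],
    params: JunctionParams | None = None,
) -> ReadCall:
    """Full junction pipeline for one selected consensus."""
    par = params or JunctionParams()
    query = make_concatemer(cons)
    records = spliced_align(query, index, cons.read_id, par.align)
    aln = filter_alignments(records, par.mapq_min)
    if aln is None:
        reason = "unmapped" if not records else "low_mapq"
        return ReadCall(cons.read_id, drop_reason=reason)

    bsj_raw, fsjs_raw, info = call_junctions(aln, par.min_intron, par.end_slack)
    if bsj_raw is None:
        return ReadCall(cons.read_id, drop_reason=info.get("reason", "no_bsj"))

    genome = index.genome
    bsj = refine_splice_sites(bsj_raw, genome, annotation, par.refine_window)
    strands = bsj.strand if bsj.confidence == "high" else "+-"
    fsjs = [refine_splice_sites(f, genome, annotation, par.refine_window, strands) for f in fsjs_raw]

    s, e = bsj.low, bsj.high
    fsj_pairs = sorted({(f.low, f.high) for f in fsjs})
    try:
        blocks = blocks_from_junctions((s - 1, e), fsj_pairs)
    except ValueError:
        return ReadCall(cons.read_id, drop_reason="inconsistent_blocks")

    wrap_qpos = info.get("wrap_qpos", [])
    qlen = aln.query_length
    wid = None
    if wrap_qpos:
        best = max(wrap_qpos, key=lambda q: min(q, qlen - q))
        wid = bsj_window_identity(aln.oriented_query, best, genome[bsj.chrom], s, e, par.novel_window)
    bsj_high, all_fsj_high = evaluate_confidence(bsj, fsjs, circ_dbs, wid, par.novel_id_min)
    if not bsj_high:
        return ReadCall(
            cons.read_id,
            drop_reason="low_confidence_bsj",
            chrom=bsj.chrom,
            strand=bsj.strand,
            circle=(s - 1, e),
            fsjs=tuple(fsj_pairs),
            blocks=blocks,
            bsj=bsj,
            fsj_junctions=tuple(fsjs),
        )
    return ReadCall(
        cons.read_id,
        chrom=bsj.chrom,
        strand=bsj.strand,
        circle=(s - 1, e),
        fsjs=tuple(fsj_pairs),
        blocks=blocks,
        bsj=bsj,
        fsj_junctions=tuple(fsjs),
        bsj_high=True,
        all_fsj_high=all_fsj_high,
    )
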