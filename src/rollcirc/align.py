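"""Internal spliced aligner for consensus concatemers on toy genomes.

The mapping contract of the pipeline is a block structure: intron-aware
alignments of a two-copy consensus concatemer, where the alignment may jump
*forward* along the genome (an intron / forward-splice junction) or
*backward* (the wrap from the end of one template copy to the start of the
next -- the back-splice junction).  The aligner here implements that contract
exactly for small genomes: k-mer seeding selects a candidate window and
strand, then a semi-global dynamic program (global in the query, free ends in
the target) with flat-penalty genomic jumps in both directions produces the
optimal blocked alignment.  It is deliberately simple rather than fast, and
is adequate for genomes up to ~1 Mb; the seeding/DP parameters are exposed
for tuning.

Scores are linear (no affine gaps): match +2, mismatch -3, gap -3/base, and
a flat -20 for any genomic jump of at least ``min_intron`` forward or
``min_back`` backward.  Ties in the traceback are broken deterministically
(diagonal > query-gap > target-gap > forward jump > backward jump; shortest
jump preferred).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AlignParams", "AlignmentRecord", "GenomeIndex", "spliced_align", "filter_alignments"]

_RC = str.maketrans("ACGTN", "TGCAN")

NEG = -(10**8)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class AlignParams:
    match: int = 2
    mismatch: int = -3
    gap: int = -3
    jump: int = -20
    min_intron: int = 30
    min_back: int = 20
    seed_k: int = 13
    seed_step: int = 5
    min_seed_hits: int = 4
    window_pad: int = 300
    max_cluster_gap: int = 8000
    mapq_margin: int = 30


@dataclass
class AlignmentRecord:
    """A blocked spliced alignment.

    ``blocks`` are ``(query_start, query_end, target_start, target_end)``
    tuples, 0-based half-open, ordered along the query.  Consecutive blocks
    with ``target_start >= previous target_end + min_intron`` are separated
    by an intron (FSJ); a *smaller* target start than the previous target end
    marks the back-splice wrap of the concatemer.  ``strand`` is the strand
    of the query against the reference; for '-' the blocks refer to the
    reverse-complemented query (stored in ``oriented_query``).
    """

    query_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int, int, int]]
    score: int
    mapq: int
    identity: float
    query_length: int
    matches: int
    oriented_query: str = ""

    @property
    def aligned_query_length(self) -> int:
        return sum(qe - qs for qs, qe, _, _ in self.blocks)


class GenomeIndex:
    """Exact k-mer index over a genome dict (chrom -> sequence)."""

    def __init__(self, genome: dict[str, str], k: int = 13, max_occ: int = 32):
        self.genome = genome
        self.k = k
        self._idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.items():
            for p in range(len(seq) - k + 1):
                self._idx[seq[p : p + k]].append((chrom, p))
        self._idx = {km: v for km, v in self._idx.items() if len(v) <= max_occ}

    def hits(self, seq: str, step: int) -> dict[str, list[int]]:
        out: dict[str, list[int]] = defaultdict(list)
        for q in range(0, len(seq) - self.k + 1, step):
            for chrom, p in self._idx.get(seq[q : q + self.k], ()):
                out[chrom].append(p)
        return out


def _clusters(positions: list[int], max_gap: int) -> list[tuple[int, int, int]]:
    """Group sorted hit positions into windows: (n_hits, lo, hi)."""
    out = []
    positions = sorted(positions)
    lo = prev = positions[0]
    n = 1
    for p in positions[1:]:
        if p - prev > max_gap:
            out.append((n, lo, prev))
            lo, n = p, 0
        n += 1
        prev = p
    out.append((n, lo, prev))
    return out


def _spliced_dp(q: str, t: str, par: AlignParams):
    """Semi-global spliced DP; returns (score, H matrix) for traceback."""
    n, m = len(q), len(t)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = 0
    jarr = np.arange(m + 1, dtype=np.int64)
    gap = par.gap
    for i in range(1, n + 1):
        prev = H[i - 1]
        sc = np.where(ta == qa[i - 1], par.match, par.mismatch)
        raw = np.empty(m + 1, dtype=np.int64)
        raw[0] = prev[0] + gap
        np.maximum(prev[:-1] + sc, prev[1:] + gap, out=raw[1:])
        # horizontal (target-consuming) gaps, linear cost, via prefix-max trick
        B = raw - gap * jarr
        C = np.maximum.accumulate(B)
        R = C + gap * jarr
        row = R.copy()
        # forward jump (intron) and backward jump (back-splice wrap)
        if m + 1 > par.min_intron:
            amax = np.maximum.accumulate(R)
            row[par.min_intron :] = np.maximum(
                row[par.min_intron :], amax[: m + 1 - par.min_intron] + par.jump
            )
        if m + 1 > par.min_back:
            smax = np.maximum.accumulate(R[::-1])[::-1]
            row[: m + 1 - par.min_back] = np.maximum(
                row[: m + 1 - par.min_back], smax[par.min_back :] + par.jump
            )
        H[i] = row
    best_j = int(np.argmax(H[n]))
    return int(H[n, best_j]), H, best_j


def _traceback(q: str, t: str, H: np.ndarray, end_j: int, par: AlignParams):
    """Recover blocks from the DP matrix by row recomputation."""
    n, m = len(q), len(t)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    jarr = np.arange(m + 1, dtype=np.int64)
    gap = par.gap

    blocks: list[list[int]] = []
    cur: list[int] | None = None  # [qs, qe, ts, te]
    matches = mismatches = gapbases = 0
    i, j = n, end_j

    row_cache: dict[int, tuple] = {}

    def row_arrays(i: int):
        if i in row_cache:
            return row_cache[i]
        prev = H[i - 1]
        sc = np.where(ta == qa[i - 1], par.match, par.mismatch)
        raw = np.empty(m + 1, dtype=np.int64)
        raw[0] = prev[0] + gap
        np.maximum(prev[:-1] + sc, prev[1:] + gap, out=raw[1:])
        B = raw - gap * jarr
        C = np.maximum.accumulate(B)
        R = C + gap * jarr
        amax = np.maximum.accumulate(R)
        smax = np.maximum.accumulate(R[::-1])[::-1]
        row_cache.clear()
        row_cache[i] = (prev, sc, raw, R, amax, smax)
        return row_cache[i]

    while i > 0:
        prev, sc, raw, R, amax, smax = row_arrays(i)
        h = H[i, j]
        if h != R[j]:
            # a jump landed here; close the current block
            if h == (amax[j - par.min_intron] + par.jump if j >= par.min_intron else NEG):
                lim = j - par.min_intron
                tgt = amax[lim]
                k = lim
                # prefer the largest k (shortest intron)
                ks = np.nonzero(R[: lim + 1] == tgt)[0]
                k = int(ks[-1])
            else:
                lim = j + par.min_back
                tgt = smax[lim]
                ks = np.nonzero(R[lim:] == tgt)[0]
                k = int(lim + ks[0])  # smallest k: shortest back jump
            if cur is not None:
                blocks.append(cur)
                cur = None
            j = k
            continue
        if R[j] != raw[j]:
            # horizontal gap: walk back to its origin raw cell
            k = j - 1
            while raw[k] + gap * (j - k) != R[j]:
                k -= 1
            if cur is not None:
                gapbases += j - k
                cur[2] = k  # extend block start over the deleted target bases
            j = k
            continue
        # raw cell: diagonal or query-gap
        if j >= 1 and raw[j] == prev[j - 1] + sc[j - 1]:
            if cur is None:
                cur = [i, i, j, j]
            cur[0] = i - 1
            cur[2] = j - 1
            if qa[i - 1] == ta[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        else:
            # query base against a gap
            if cur is not None:
                cur[0] = i - 1
                gapbases += 1
            i -= 1
    if cur is not None:
        blocks.append(cur)
    blocks.reverse()
    out = [(qs, qe, ts, te) for qs, qe, ts, te in blocks if qe > qs]
    return out, matches, mismatches, gapbases


def spliced_align(
    query: str,
    index: GenomeIndex,
    query_id: str = "query",
    params: AlignParams | None = None,
    max_records: int = 2,
) -> list[AlignmentRecord]:
    """Map a sequence to the genome, allowing introns and back-splice wraps.

    Returns alignment records sorted by score (best first) with mapq set
    from the score margin between the two best candidate loci.  Unmappable
    queries (too few seed hits anywhere) give an empty list.
    """
    par = params or AlignParams()
    candidates = []  # (n_hits, strand, chrom, lo, hi)
    for strand in "+-":
        seq = query if strand == "+" else revcomp(query)
        for chrom, positions in index.hits(seq, par.seed_step).items():
            for nh, lo, hi in _clusters(positions, par.max_cluster_gap):
                if nh >= par.min_seed_hits:
                    candidates.append((nh, strand, chrom, lo, hi))
    if not candidates:
        return []
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    records: list[AlignmentRecord] = []
    for nh, strand, chrom, lo, hi in candidates[:max_records]:
        seq = query if strand == "+" else revcomp(query)
        gseq = index.genome[chrom]
        ws = max(0, lo - par.window_pad)
        we = min(len(gseq), hi + index.k + par.window_pad)
        target = gseq[ws:we]
        score, H, end_j = _spliced_dp(seq, target, par)
        blocks, matches, mism, gaps = _traceback(seq, target, H, end_j, par)
        if not blocks:
            continue
        aligned = matches + mism + gaps
        identity = matches / aligned if aligned else 0.0
        records.append(
            AlignmentRecord(
                query_id=query_id,
                chrom=chrom,
                strand=strand,
                blocks=[(qs, qe, ts + ws, te + ws) for qs, qe, ts, te in blocks],
                score=score,
                mapq=60,
                identity=identity,
                query_length=len(query),
                matches=matches,
                oriented_query=seq,
            )
        )
    records.sort(key=lambda r: (-r.score, r.chrom, r.blocks[0][2]))
    if len(records) >= 2:
        margin = records[0].score - records[1].score
        records[0].mapq = 60 if margin >= par.mapq_margin else (20 if margin >= 10 else 0)
        for r in records[1:]:
            r.mapq = 0
    return records


def filter_alignments(
    records: list[AlignmentRecord], mapq_min: int = 1
) -> AlignmentRecord | None:
    """Drop low-mapq records, then keep the best record.

    Best = maximal (aligned query length, identity), ties broken by leftmost
    genomic coordinate then chromosome name -- deterministic.
    """
    ok = [r for r in records if r.mapq >= mapq_min]
    if not ok:
        return None
    return min(ok, key=lambda r: (-r.aligned_query_length, -r.identity, r.chrom, r.blocks[0][2]))
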