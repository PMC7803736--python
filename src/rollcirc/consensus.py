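"""Tandem-repeat detection and consensus calling for rolling-circle reads.

A raw RCA read is (ideally) ``k`` error-bearing copies of one circRNA
template.  :func:`detect_tandem_repeat` estimates the repeat unit length and
the repeat span from the read alone, via the distribution of distances
between repeated k-mers (self-alignment periodicity); :func:`call_consensus`
then chops the repeat region into copies, aligns each copy to a draft and
majority-votes a polished consensus; :func:`select_optimal_consensus` picks
one consensus per read with a deterministic ranking.

The consensus error rate decreases with copy number because per-column votes
average out the i.i.d. read errors; the zero-error case reproduces the
template exactly (up to rotation, since the read starts at an arbitrary
position within the circle).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib

__all__ = [
    "RawRead",
    "RepeatCandidate",
    "ConsensusRecord",
    "detect_tandem_repeat",
    "call_consensus",
    "select_optimal_consensus",
    "is_rotation",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read")
        if set(self.sequence) - _ALPHABET:
            raise ValueError(f"non-ACGTN characters in read {self.read_id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatCandidate:
    unit_length: int
    span: tuple[int, int]  # 0-based half-open offsets in the raw read
    score: int  # k-mer period support votes

    @property
    def copies(self) -> float:
        return (self.span[1] - self.span[0]) / self.unit_length


@dataclass(frozen=True)
class ConsensusRecord:
    read_id: str
    consensus_seq: str
    unit_length: int
    copy_number: float
    subread_start: int
    subread_end: int
    score: float

    def __post_init__(self) -> None:
        if self.subread_end - self.subread_start < self.unit_length:
            raise ValueError("subread span shorter than unit length")


def is_rotation(a: str, b: str) -> bool:
    """True if `b` is a cyclic rotation of `a` (exact string test)."""
    return len(a) == len(b) and b in a + a


# ---------------------------------------------------------------------------
# tandem-repeat detection
# ---------------------------------------------------------------------------

def detect_tandem_repeat(
    read: RawRead | str,
    min_period: int = 20,
    max_period: int = 20000,
    k: int = 11,
    min_votes: int = 5,
    max_kmer_occ: int = 64,
    max_candidates: int = 3,
) -> list[RepeatCandidate]:
    """Find candidate repeat periods in a raw read.

    Distances between successive occurrences of each k-mer vote for a period;
    the vote histogram is scanned for peaks (with a +/-2% smoothing window to
    absorb indel jitter).  Candidates are returned sorted by support, and a
    candidate must explain at least two copies.  Reads shorter than
    ``2 * min_period`` or without periodic structure yield an empty list.
    """
    if min_period < 20:
        raise ValueError("min_period must be >= 20 (shorter periods are low-complexity)")
    seq = read.sequence if isinstance(read, RawRead) else read
    n = len(seq)
    if n < 2 * min_period:
        return []
    # a two-copy read has period ~ n/2; allow ~10% indel jitter past that
    hi = min(max_period, int(n / 1.8))

    positions: dict[str, int] = {}
    counts: dict[str, int] = defaultdict(int)
    pairs: list[tuple[int, int]] = []  # (diff, left position)
    for p in range(0, n - k + 1):
        kmer = seq[p : p + k]
        c = counts[kmer]
        counts[kmer] = c + 1
        if c >= max_kmer_occ:
            continue
        q = positions.get(kmer)
        positions[kmer] = p
        if q is not None:
            d = p - q
            if min_period <= d <= hi:
                pairs.append((d, q))
    if not pairs:
        return []

    hist: dict[int, int] = defaultdict(int)
    for d, _ in pairs:
        hist[d] += 1

    def window_score(center: int) -> int:
        r = max(2, round(0.02 * center))
        return sum(hist.get(center + o, 0) for o in range(-r, r + 1))

    candidates: list[RepeatCandidate] = []
    remaining = dict(hist)
    for _ in range(max_candidates):
        if not remaining:
            break
        # deterministic peak pick: best smoothed score, smallest period on ties
        center = min(remaining, key=lambda d: (-window_score(d), d))
        score = window_score(center)
        if score < min_votes:
            break
        r = max(2, round(0.02 * center))
        sel = [(d, p) for d, p in pairs if abs(d - center) <= r]
        unit = round(sum(d for d, _ in sel) / len(sel))
        s = min(p for _, p in sel)
        e = min(n, max(p + d for d, p in sel) + k)
        if (e - s) / unit >= 1.8 and unit >= min_period:
            candidates.append(RepeatCandidate(unit, (s, e), score))
        # suppress periods near this peak and near its integer multiples
        # (harmonics of one repeat unit, e.g. a double-length unit, would
        # otherwise re-enter as spurious candidates)
        def _is_harmonic(d: int) -> bool:
            ratio = d / center
            mult = round(ratio)
            return mult >= 1 and abs(ratio - mult) <= 0.3 / max(1, mult**0.5)

        remaining = {d: c for d, c in remaining.items() if not _is_harmonic(d)}

    candidates.sort(key=lambda c: (-c.score, c.unit_length, c.span[0]))
    return candidates


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def _chop_copies(seq: str, s: int, e: int, draft: str) -> list[str]:
    """Partition seq[s:e] into successive repeat copies by prefix-aligning the
    draft at each boundary."""
    L = len(draft)
    copies: list[str] = []
    cur = s
    while e - cur >= 0.6 * L:
        window = seq[cur : min(cur + int(1.6 * L) + 16, e)]
        res = edlib.align(draft, window, mode="SHW", task="locations")
        end_in_window = res["locations"][0][1] + 1
        if end_in_window <= max(1, L // 3):
            break
        copies.append(seq[cur : cur + end_in_window])
        cur += end_in_window
    return copies


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _vote(draft: str, copies: list[str]) -> str:
    """Majority-vote a consensus over copies aligned to the draft.

    Ties are broken in favor of the draft (i.e., first-copy) base, which
    makes the two-copy case deterministic: a substitution present in only
    one copy survives only if it sits in the draft copy itself.
    """
    L = len(draft)
    votes = [Counter() for _ in range(L)]
    dels = [0] * L
    ins: dict[int, Counter] = defaultdict(Counter)
    ins_copies = [0] * (L + 1)
    n = len(copies)

    for copy in copies:
        res = edlib.align(copy, draft, mode="NW", task="path")
        qi = ti = 0
        seen_ins: set[int] = set()
        for length, op in _parse_cigar(res["cigar"]):
            if op in ("=", "X", "M"):
                for _ in range(length):
                    votes[ti][copy[qi]] += 1
                    qi += 1
                    ti += 1
            elif op == "D":  # draft base absent from this copy
                for _ in range(length):
                    dels[ti] += 1
                    ti += 1
            elif op == "I":  # extra bases in this copy, before draft pos ti
                ins[ti][copy[qi : qi + length]] += 1
                if ti not in seen_ins:
                    ins_copies[ti] += 1
                    seen_ins.add(ti)
                qi += length

    out: list[str] = []
    for ti in range(L + 1):
        if 2 * ins_copies[ti] > n:
            best = min(ins[ti].items(), key=lambda kv: (-kv[1], kv[0]))[0]
            out.append(best)
        if ti == L:
            break
        base_votes = votes[ti]
        d = dels[ti]
        total_support = max(base_votes.values(), default=0)
        if d > total_support and 2 * d > n:
            continue  # majority deletion
        if not base_votes:
            continue
        draft_base = draft[ti]
        best_count = max(base_votes.values())
        winners = sorted(b for b, c in base_votes.items() if c == best_count)
        out.append(draft_base if draft_base in winners else winners[0])
    return "".join(out)


def call_consensus(
    read: RawRead | str,
    candidate: RepeatCandidate,
    read_id: str | None = None,
    rounds: int = 2,
    max_copy_divergence: float = 0.45,
) -> ConsensusRecord | None:
    """Call a polished consensus for one repeat candidate.

    The first repeat copy serves as the draft; every copy is globally aligned
    to the draft and a per-column majority vote (with the draft as the
    deterministic tie-breaker) produces the consensus, which is then used as
    the draft for a second polishing round.  Returns None when fewer than two
    usable copies remain (degenerate candidate).
    """
    if isinstance(read, RawRead):
        seq, rid = read.sequence, read.read_id
    else:
        seq, rid = read, (read_id or "read")
    s, e = candidate.span
    if candidate.copies < 1.8:  # nominal two copies, with indel jitter
        return None
    draft = seq[s : s + candidate.unit_length]

    cons = draft
    for _ in range(rounds):
        copies = _chop_copies(seq, s, e, cons)
        L = len(cons)
        full = [c for c in copies if len(c) >= 0.6 * L]
        usable = []
        for c in full:
            dist = edlib.align(c, cons, mode="NW", task="distance")["editDistance"]
            if dist <= max_copy_divergence * L:
                usable.append(c)
        if len(usable) < 2:
            return None
        cons = _vote(cons, usable)
        if not cons:
            return None

    L = len(cons)
    score = 0.0
    for c in usable:
        dist = edlib.align(c, cons, mode="NW", task="distance")["editDistance"]
        score += max(0.0, L - dist)
    copy_number = (e - s) / L
    if copy_number < 1.0:
        return None
    return ConsensusRecord(rid, cons, L, copy_number, s, e, score)


def select_optimal_consensus(records: list[ConsensusRecord]) -> ConsensusRecord | None:
    """Pick one consensus per read.

    Ranking key: copy-number-weighted support score, then subread span,
    then smaller subread start (a deterministic, documented tie-break).
    """
    if not records:
        return None
    return min(
        records,
        key=lambda r: (-r.score, -(r.subread_end - r.subread_start), r.subread_start),
    )
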