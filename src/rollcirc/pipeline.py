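"""End-to-end orchestration: raw reads -> consensus -> junctions -> catalog."""

from __future__ import annotations

from dataclasses import dataclass, field

from rollcirc.align import GenomeIndex
from rollcirc.annotation import CircDB, GeneAnnotation
from rollcirc.catalog import CircCatalog, annotate_catalog, collapse_isoforms
from rollcirc.consensus import (
    ConsensusRecord,
    call_consensus,
    detect_tandem_repeat,
    select_optimal_consensus,
)
from rollcirc.junction import JunctionParams, ReadCall, call_read

__all__ = ["ConsensusParams", "PipelineResult", "consensus_for_read", "process_sample", "run_pipeline", "read_fasta"]


@dataclass
class ConsensusParams:
    min_period: int = 20
    max_period: int = 20000


@dataclass
class PipelineResult:
    catalog: CircCatalog
    calls_by_sample: dict[str, list[ReadCall]]
    consensus_by_sample: dict[str, list[ConsensusRecord]]
    drop_log: list[tuple[str, str, str]] = field(default_factory=list)  # sample, read, reason


def consensus_for_read(
    read_id: str, sequence: str, params: ConsensusParams | None = None
) -> tuple[ConsensusRecord | None, str | None]:
    """Detect the tandem repeat and call the optimal consensus for one read.

    Returns (record, drop_reason); reads without tandem-repeat structure are
    dropped with a reason code, mirroring the filter to tandem-repeat reads.
    """
    par = params or ConsensusParams()
    candidates = detect_tandem_repeat(sequence, par.min_period, par.max_period)
    if not candidates:
        return None, "no_tandem_repeat"
    records = []
    for cand in candidates:
        rec = call_consensus(sequence, cand, read_id)
        if rec is not None:
            records.append(rec)
    best = select_optimal_consensus(records)
    if best is None:
        return None, "no_consensus"
    return best, None


def process_sample(
    reads: list[tuple[str, str]],
    index: GenomeIndex,
    annotation: GeneAnnotation | None,
    circ_dbs: list[CircDB],
    junction_params: JunctionParams | None = None,
    consensus_params: ConsensusParams | None = None,
) -> tuple[list[ReadCall], list[ConsensusRecord], list[tuple[str, str]]]:
    """Run consensus + junction calling on one sample's reads."""
    jpar = junction_params or JunctionParams()
    calls: list[ReadCall] = []
    consensi: list[ConsensusRecord] = []
    drops: list[tuple[str, str]] = []
    for read_id, seq in reads:
        cons, reason = consensus_for_read(read_id, seq, consensus_params)
        if cons is None:
            drops.append((read_id, reason or "no_consensus"))
            continue
        consensi.append(cons)
        call = call_read(cons, index, annotation, circ_dbs, jpar)
        calls.append(call)
        if call.drop_reason:
            drops.append((read_id, call.drop_reason))
    return calls, consensi, drops


def run_pipeline(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    genome: dict[str, str],
    annotation: GeneAnnotation | None,
    circ_dbs: list[CircDB],
    junction_params: JunctionParams | None = None,
    consensus_params: ConsensusParams | None = None,
) -> PipelineResult:
    """Full pipeline over multiple samples, returning the annotated catalog."""
    index = GenomeIndex(genome)
    calls_by_sample: dict[str, list[ReadCall]] = {}
    cons_by_sample: dict[str, list[ConsensusRecord]] = {}
    drop_log: list[tuple[str, str, str]] = []
    for sample, reads in reads_by_sample.items():
        calls, consensi, drops = process_sample(
            reads, index, annotation, circ_dbs, junction_params, consensus_params
        )
        calls_by_sample[sample] = calls
        cons_by_sample[sample] = consensi
        drop_log.extend((sample, rid, why) for rid, why in drops)
    catalog = collapse_isoforms(calls_by_sample)
    if annotation is not None:
        annotate_catalog(catalog, circ_dbs, annotation)
    return PipelineResult(catalog, calls_by_sample, cons_by_sample, drop_log)


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
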