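"""Cataloging: collapse/counting, FSM-NIC-NNC rules, genes, names, AS events."""

import numpy as np
import pandas as pd
import pytest

from rollcirc.annotation import CircDB, Gene, GeneAnnotation, Transcript
from rollcirc.catalog import (
    ASEvent,
    CircIsoform,
    assign_gene,
    classify_bsj_category,
    classify_bsj_known,
    classify_fsj_category,
    collapse_isoforms,
    name_isoforms,
    pair_alternative_splicing_events,
)
from rollcirc.junction import ReadCall, blocks_from_junctions


def _call(read_id, circle, fsjs=(), chrom="c", strand="+", full=True):
    return ReadCall(
        read_id, None, chrom, strand, circle, tuple(fsjs),
        blocks_from_junctions(circle, fsjs), bsj_high=True, all_fsj_high=full,
    )


def _iso(circle, fsjs=(), chrom="c", strand="+", counts=None):
    return CircIsoform(
        chrom, strand, circle, tuple(fsjs), blocks_from_junctions(circle, fsjs),
        counts=dict(counts or {}),
    )


# annotation: one + gene with 3 exons at [100,200) [300,400) [500,600),
# a skipping transcript, and one - gene at [1000,1100) [1200,1300)
@pytest.fixture(scope="module")
def toy_annotation():
    t_full = Transcript("tA1", "GA", "c", "+", ((100, 200), (300, 400), (500, 600)))
    t_skip = Transcript("tA2", "GA", "c", "+", ((100, 200), (500, 600)))
    t_b = Transcript("tB1", "GB", "c", "-", ((1000, 1100), (1200, 1300)))
    return GeneAnnotation([Gene("GA", "c", "+", [t_full, t_skip]), Gene("GB", "c", "-", [t_b])])


# -- collapse ----------------------------------------------------------------

def test_three_reads_same_key_merge_to_count_three():
    calls = {"s1": [_call(f"r{i}", (100, 600), [(200, 301), (400, 501)]) for i in range(3)]}
    cat = collapse_isoforms(calls)
    assert len(cat.isoforms) == 1
    assert cat.isoforms[0].counts == {"s1": 3}


def test_same_bsj_different_fsjs_two_isoforms_one_bsj_record():
    calls = {
        "s1": [
            _call("r1", (100, 600), [(200, 301), (400, 501)]),
            _call("r2", (100, 600), [(200, 301), (400, 501)]),
            _call("r3", (100, 600), [(200, 501)]),
        ]
    }
    cat = collapse_isoforms(calls)
    assert len(cat.isoforms) == 2
    assert len(cat.bsj_counts) == 1
    # conservation: BSJ count equals the sum over its isoforms
    assert int(cat.bsj_counts.iloc[0]["s1"]) == 3


def test_min_read_filter_drops_singletons():
    calls = {
        "s1": [_call("r1", (100, 600)), _call("r2", (100, 600)), _call("r3", (700, 900))]
    }
    cat = collapse_isoforms(calls).filter_min_reads(2)
    assert len(cat.isoforms) == 1
    assert cat.isoforms[0].circle == (100, 600)


def test_non_full_length_calls_do_not_enter_isoform_catalog():
    calls = {"s1": [_call("r1", (100, 600), full=False), _call("r2", (100, 600))]}
    cat = collapse_isoforms(calls)
    assert len(cat.isoforms) == 1
    assert cat.isoforms[0].counts == {"s1": 1}


# -- BSJ known/novel and categories -----------------------------------------

def test_bsj_known_per_source_flags():
    db1 = CircDB([("c", 100, 600)], source="db1")
    db2 = CircDB([("c", 700, 900)], source="db2")
    assert classify_bsj_known(("c", 100, 600), [db1, db2]) == ("known", ("db1",))
    assert classify_bsj_known(("c", 1, 50), [db1, db2]) == ("novel", ())
    both = CircDB([("c", 100, 600)], source="db2")
    assert classify_bsj_known(("c", 100, 600), [db1, both])[1] == ("db1", "db2")


def test_bsj_category_fsm_by_database(toy_annotation):
    db = CircDB([("c", 100, 600)], source="db")
    iso = _iso((100, 600))
    assert classify_bsj_category(iso, [db], toy_annotation) == "FSM"


def test_bsj_category_nic_when_both_sites_annotated(toy_annotation):
    # back-splice of exon3 end to exon1 start: both are annotated boundaries
    iso = _iso((100, 600))
    assert classify_bsj_category(iso, [], toy_annotation) == "NIC"


def test_bsj_category_nnc_with_novel_site(toy_annotation):
    iso = _iso((100, 555))  # 555 is not an annotated donor
    assert classify_bsj_category(iso, [], toy_annotation) == "NNC"


# -- FSJ categories ----------------------------------------------------------

def test_fsj_category_fsm_contiguous_subchain(toy_annotation):
    iso = _iso((100, 600), [(200, 301), (400, 501)])
    assert classify_fsj_category(iso, toy_annotation) == "FSM"


def test_fsj_category_fsm_requires_contiguity(toy_annotation):
    # skip junction exists in tA2, so it is FSM via that transcript
    iso = _iso((100, 600), [(200, 501)])
    assert classify_fsj_category(iso, toy_annotation) == "FSM"


def test_fsj_category_nic_novel_combination(toy_annotation):
    # junction pairing exon1 donor with exon3 acceptor is absent once tA2 is
    # removed: rebuild annotation without the skipping transcript
    t_full = Transcript("tA1", "GA", "c", "+", ((100, 200), (300, 400), (500, 600)))
    ann = GeneAnnotation([Gene("GA", "c", "+", [t_full])])
    iso = _iso((100, 600), [(200, 501)])
    assert classify_fsj_category(iso, ann) == "NIC"


def test_fsj_category_nnc_novel_site(toy_annotation):
    iso = _iso((100, 600), [(200, 311)])  # 311 not an annotated acceptor
    assert classify_fsj_category(iso, toy_annotation) == "NNC"


def test_single_exon_is_fsm(toy_annotation):
    assert classify_fsj_category(_iso((100, 600)), toy_annotation) == "FSM"


def test_minus_strand_fsj_chain(toy_annotation):
    iso = _iso((1000, 1300), [(1100, 1201)], strand="-")
    assert classify_fsj_category(iso, toy_annotation) == "FSM"


# -- gene assignment ---------------------------------------------------------

def test_gene_assignment_by_shared_splice_sites(toy_annotation):
    iso = _iso((100, 600), [(200, 301), (400, 501)])
    assert assign_gene(iso, toy_annotation) == ("GA",)


def test_gene_assignment_tie_gives_multiple_genes():
    tx1 = Transcript("t1", "G1", "c", "+", ((100, 200), (300, 400)))
    tx2 = Transcript("t2", "G2", "c", "+", ((100, 200), (300, 400)))
    ann = GeneAnnotation([Gene("G1", "c", "+", [tx1]), Gene("G2", "c", "+", [tx2])])
    iso = _iso((100, 400), [(200, 301)])
    assert assign_gene(iso, ann) == ("G1", "G2")


def test_gene_assignment_overlap_fallback_and_na(toy_annotation):
    # no shared sites, but overlaps GA on the + strand
    iso = _iso((150, 180))
    assert assign_gene(iso, toy_annotation) == ("GA",)
    # intergenic circle: NA
    assert assign_gene(_iso((5000, 5300)), toy_annotation) == ()
    # strand-inconsistent: GB is on '-', a + circle there is NA
    assert assign_gene(_iso((1000, 1300)), toy_annotation) == ()


# -- naming ------------------------------------------------------------------

def _named(counts_per_iso):
    isoforms = []
    rows = []
    for i, counts in enumerate(counts_per_iso):
        tag = int(10 * counts.get("a", 0))  # structural key tracks the counts
        iso = _iso((100 + tag, 600 + tag), counts=counts)
        iso.gene_ids = ("G",)
        isoforms.append(iso)
        rows.append(counts)
    samples = sorted({s for c in counts_per_iso for s in c})
    counts = pd.DataFrame([[c.get(s, 0) for s in samples] for c in counts_per_iso], columns=samples)
    name_isoforms(isoforms, counts)
    return isoforms


def test_naming_by_median_read_count():
    isos = _named([
        {"a": 5, "b": 5}, {"a": 3, "b": 3}, {"a": 1, "b": 1},
    ])
    assert [i.name for i in isos] == ["G.circRNA.1", "G.circRNA.2", "G.circRNA.3"]


def test_naming_tie_on_median_broken_by_mean():
    isos = _named([
        {"a": 1, "b": 3, "c": 8},  # median 3, mean 4.0
        {"a": 2, "b": 3, "c": 2.5},  # median ~3 lower mean
    ])
    assert isos[0].name == "G.circRNA.1"


def test_naming_invariant_to_input_order():
    counts = [{"a": 5}, {"a": 9}, {"a": 1}]
    a = _named(counts)
    b = _named(counts[::-1])
    names_a = {i.circle: i.name for i in a}
    names_b = {i.circle: i.name for i in b}
    assert names_a == names_b


# -- alternative-splicing event pairing --------------------------------------

def _events(iso_specs):
    isoforms = []
    for circle, fsjs, counts in iso_specs:
        iso = _iso(circle, fsjs, counts=counts)
        iso.gene_ids = ("G",)
        isoforms.append(iso)
    samples = sorted({s for _, _, c in iso_specs for s in c})
    counts = pd.DataFrame(
        [[c.get(s, 0) for s in samples] for _, _, c in iso_specs], columns=samples
    )
    name_isoforms(isoforms, counts)
    return pair_alternative_splicing_events(isoforms, counts)


def test_skipped_exon_event():
    ev = _events([
        ((100, 600), [(200, 301), (400, 501)], {"a": 10}),  # includes middle exon
        ((100, 600), [(200, 501)], {"a": 2}),  # skips it
    ])
    assert len(ev) == 1
    assert ev[0].scope == "FSJs only"
    assert ev[0].etypes == ("SE",)
    assert ev[0].minor_count == 2


def test_alternative_five_prime_event_plus_strand():
    ev = _events([
        ((100, 600), [(200, 301)], {"a": 10}),
        ((100, 600), [(180, 301)], {"a": 3}),  # donor shifted into exon1
    ])
    assert ev[0].etypes == ("A5SS",)


def test_alternative_three_prime_event_plus_strand():
    ev = _events([
        ((100, 600), [(200, 301)], {"a": 10}),
        ((100, 600), [(200, 321)], {"a": 3}),
    ])
    assert ev[0].etypes == ("A3SS",)


def test_retained_intron_event():
    ev = _events([
        ((100, 600), [(200, 301), (400, 501)], {"a": 10}),
        ((100, 600), [(200, 301)], {"a": 3}),  # intron 2 retained (EIciRNA)
    ])
    assert ev[0].etypes == ("RI",)


def test_bsj_only_difference():
    ev = _events([
        ((100, 600), [(200, 301)], {"a": 10}),
        ((100, 650), [(200, 301)], {"a": 3}),
    ])
    assert ev[0].scope == "both" or ev[0].scope == "BSJ only"
    # FSJs identical => BSJ only
    assert ev[0].scope == "BSJ only"
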