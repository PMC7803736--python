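"""Statistics: closed-form examples, brute-force oracles, invariants."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaincc

from rollcirc.annotation import RepeatElement
from rollcirc.stats import (
    UndefinedStatisticError,
    alu_flank_classify,
    bh_adjust,
    binomial_greater,
    enrichment_test,
    flag_differential_genes,
    gene_proportion_test,
    isoform_fisher,
    make_control_bsjs,
    normalized_bsj_count,
    pairwise_tissue_comparison,
    similarity,
    similarity_matrix,
    tau_index,
    tissue_specific,
    tissue_stable,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def chi2_oracle(table):
    """Pearson chi-square by explicit loops; p via the regularized gamma tail."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = rows[i] * cols[j] / total
            stat += (t[i, j] - e) ** 2 / e
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(gammaincc(df / 2.0, stat / 2.0))


def fisher_oracle(table):
    """Two-sided Fisher p by exact hypergeometric enumeration (rationals)."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), math.comb(n, c1))

    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1) if pmf(k) <= p_obs)
    return float(total)


def bh_oracle(pvals):
    """Step-up BH by the direct O(m^2) definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def binom_tail_oracle(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def test_similarity_examples():
    assert similarity({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
    assert similarity({"a"}, {"a"}) == 1.0
    assert similarity({"a"}, {"b"}) == 0.0


def test_similarity_undefined_for_two_empty_sets():
    with pytest.raises(UndefinedStatisticError):
        similarity(set(), set())


def test_similarity_symmetric_and_identity(rng):
    for _ in range(20):
        a = set(rng.integers(0, 30, size=rng.integers(1, 15)).tolist())
        b = set(rng.integers(0, 30, size=rng.integers(1, 15)).tolist())
        assert similarity(a, b) == similarity(b, a)
        assert (similarity(a, b) == 1.0) == (a == b)


def test_similarity_matrix_diagonal_is_one():
    m = similarity_matrix({"x": {1, 2}, "y": {2, 3}})
    assert (np.diag(m.to_numpy()) == 1.0).all()


# ---------------------------------------------------------------------------
# chi-square / BH / Fisher / binomial kernels
# ---------------------------------------------------------------------------

def test_chi2_homogeneous_table_is_zero():
    stat, p = gene_proportion_test([10, 10], [10, 10])
    assert stat == 0.0 and p == 1.0


def test_chi2_perfect_separation_hand_computed():
    stat, p = gene_proportion_test([20, 0], [0, 20])
    assert stat == pytest.approx(40.0)


def test_chi2_matches_oracle_on_random_tables(rng):
    for _ in range(300):
        k = int(rng.integers(2, 5))
        t1 = rng.integers(1, 40, size=k)
        t2 = rng.integers(1, 40, size=k)
        stat, p = gene_proportion_test(t1, t2)
        ostat, op = chi2_oracle(np.vstack([t1, t2]))
        assert stat == pytest.approx(ostat, abs=1e-9)
        assert p == pytest.approx(op, abs=1e-9)


def test_chi2_undefined_on_zero_tissue_total():
    with pytest.raises(UndefinedStatisticError):
        gene_proportion_test([5, 5], [0, 0])


def test_bh_single_and_hand_example():
    assert bh_adjust([0.05]).tolist() == [0.05]
    assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])


def test_bh_matches_oracle_and_is_monotone(rng):
    for _ in range(100):
        p = rng.random(int(rng.integers(1, 25)))
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p.tolist()), atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def test_fisher_hand_examples():
    p, _ = isoform_fisher([[2, 0], [0, 2]])
    assert p == pytest.approx(1 / 3)
    p, d = isoform_fisher([[5, 5], [5, 5]])
    assert p == 1.0 and d == 0.0


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(300):
        t = rng.integers(0, 15, size=(2, 2))
        if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
            continue
        p, _ = isoform_fisher(t)
        assert p == pytest.approx(fisher_oracle(t.tolist()), abs=1e-9)


def test_fisher_zero_margin_convention():
    assert isoform_fisher([[0, 0], [3, 7]])[0] == 1.0


def test_binomial_closed_form():
    # 10 of 10 at p0=0.5: p = 0.5^10
    assert binomial_greater(10, 10, 0.5) == pytest.approx(0.5**10)
    assert binomial_greater(0, 10, 0.5) == pytest.approx(1.0)


def test_binomial_matches_tail_sum_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(1, 40))
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.random())
        assert binomial_greater(k, n, p0) == pytest.approx(
            binom_tail_oracle(k, n, p0), abs=1e-9
        )


# ---------------------------------------------------------------------------
# differential flags and tissue specificity
# ---------------------------------------------------------------------------

def test_flag_differential_genes_requires_both_conditions():
    fdr = {"g1": 0.04, "g2": 0.04, "g3": 0.06}
    dp = {"g1": 0.10, "g2": 0.03, "g3": 0.30}
    assert flag_differential_genes(fdr, dp) == {"g1"}


def test_pairwise_comparison_flags_strong_shift():
    counts = pd.DataFrame(
        {"t1": [40, 2, 10, 10], "t2": [2, 40, 10, 10]},
        index=["i1", "i2", "i3", "i4"],
    )
    genes = pd.Series(["gA", "gA", "gB", "gB"], index=counts.index)
    res = pairwise_tissue_comparison(counts, genes)
    out = res.genes.set_index("gene")
    assert bool(out.loc["gA", "differential"])
    assert not bool(out.loc["gB", "differential"])
    sig = res.isoforms[res.isoforms["significant"]]
    assert set(sig["isoform"]) == {"i1", "i2"}


def test_tissue_stable_rules():
    assert tissue_stable([0.8, 0.8, 0.8], [5, 5, 5])
    assert not tissue_stable([0.8, 0.5, 0.8], [5, 5, 5])  # strict > 0.5
    assert not tissue_stable([0.8, 0.8, 0.8], [5, 1, 5])  # count floor


def test_tissue_specific_exclusive_gene():
    counts = pd.DataFrame(
        {"testis": [8, 4], "brain": [0, 0], "liver": [0, 0]}, index=["i1", "i2"]
    )
    genes = pd.Series(["g", "g"], index=counts.index)
    out = tissue_specific(counts, genes)
    assert set(out["isoform"]) == {"i1", "i2"}
    assert (out["tissue"] == "testis").all()
    assert (out["case"] == "exclusive").all()


def test_tissue_specific_uniform_gene_flags_nothing():
    counts = pd.DataFrame(
        {t: [20, 20] for t in ("a", "b", "c", "d")}, index=["i1", "i2"]
    )
    genes = pd.Series(["g", "g"], index=counts.index)
    assert len(tissue_specific(counts, genes)) == 0


def test_tissue_specific_proportion_shift_detected():
    # i1 dominates tissue 'a' only, strongly and with plenty of reads
    counts = pd.DataFrame(
        {"a": [90, 10], "b": [5, 95], "c": [5, 95], "d": [5, 95]},
        index=["i1", "i2"],
    )
    genes = pd.Series(["g", "g"], index=counts.index)
    out = tissue_specific(counts, genes)
    assert ("i1", "a") in set(zip(out["isoform"], out["tissue"]))


# ---------------------------------------------------------------------------
# tau and enrichment
# ---------------------------------------------------------------------------

def test_tau_closed_forms():
    assert tau_index([5, 5, 5, 5]) == 0.0
    assert tau_index([0, 7, 0]) == 1.0
    assert tau_index([8, 2, 2]) == pytest.approx(0.75)


def test_tau_range_and_scale_invariance(rng):
    for _ in range(50):
        x = rng.random(int(rng.integers(2, 15))) * 100
        t = tau_index(x)
        assert 0.0 <= t <= 1.0
        assert tau_index(x * 7.3) == pytest.approx(t)


def test_tau_undefined_for_all_zero():
    with pytest.raises(UndefinedStatisticError):
        tau_index([0.0, 0.0])


def test_enrichment_diagonal_vs_independent():
    _, p = enrichment_test([[50, 5], [5, 50]])
    assert p < 1e-10
    odds, p = enrichment_test([[10, 10], [10, 10]])
    assert p == 1.0 and odds == 1.0
    assert enrichment_test([[0, 0], [5, 5]])[1] == 1.0


# ---------------------------------------------------------------------------
# Alu flanking
# ---------------------------------------------------------------------------

def alu_oracle(bsj, repeats, window):
    """Exhaustive all-pairs scan over (upstream, downstream) elements."""
    chrom, s, e = bsj
    up = [r for r in repeats if r.chrom == chrom and r.start < s and r.end > max(0, s - window)]
    dn = [r for r in repeats if r.chrom == chrom and r.start < e + window and r.end > e]
    conv = div = False
    for u in up:
        for d in dn:
            if u.strand == d.strand:
                continue  # not inverted
            if u.strand == "+" and d.strand == "-":
                conv = True
            if u.strand == "-" and d.strand == "+":
                div = True
    return "both" if (conv and div) else "convergent" if conv else "divergent" if div else "none"


def test_alu_convergent_example():
    reps = [
        RepeatElement("c", 400, 700, "+"),
        RepeatElement("c", 2100, 2400, "-"),
    ]
    assert alu_flank_classify(("c", 1000, 2000), reps, window=1000) == "convergent"


def test_alu_none_without_flanking_elements():
    reps = [RepeatElement("c", 5000, 5300, "+")]
    assert alu_flank_classify(("c", 1000, 2000), reps, window=1000) == "none"


def test_alu_requires_opposite_strands():
    reps = [RepeatElement("c", 400, 700, "+"), RepeatElement("c", 2100, 2400, "+")]
    assert alu_flank_classify(("c", 1000, 2000), reps, window=1000) == "none"


@pytest.mark.parametrize("window", [1000, 2000])
def test_alu_matches_exhaustive_oracle(window, rng):
    reps = [
        RepeatElement("c", int(p), int(p) + 300, "+" if rng.random() < 0.5 else "-")
        for p in rng.integers(0, 50000, size=200)
    ]
    for _ in range(50):
        s = int(rng.integers(1000, 45000))
        e = s + int(rng.integers(200, 3000))
        bsj = ("c", s, e)
        assert alu_flank_classify(bsj, reps, window) == alu_oracle(bsj, reps, window)


# ---------------------------------------------------------------------------
# control BSJs and normalization
# ---------------------------------------------------------------------------

def test_control_bsjs_geometry_and_count(rng):
    donors = [("c", "+", p) for p in range(1000, 3000, 100)]
    acceptors = [("c", "+", p) for p in range(900, 2900, 100)]
    out = make_control_bsjs(donors, acceptors, n=10, rng=rng)
    assert len(out) == 10
    for chrom, s, e, strand in out:
        assert e > s  # donor downstream of acceptor: valid circle interval


def test_control_bsjs_exclude_observed_sites(rng):
    donors = [("c", "+", p) for p in (1000, 2000)]
    acceptors = [("c", "+", p) for p in (500, 1500)]
    with pytest.warns(UserWarning):
        out = make_control_bsjs(
            donors, acceptors, n=100, rng=rng,
            exclude_donors={("c", "+", 2000)}, exclude_acceptors={("c", "+", 500)},
        )
    # only donor 1000 x acceptor 1500 remains, which violates geometry -> none
    assert out == []


def test_control_bsjs_minus_strand_geometry(rng):
    donors = [("c", "-", 1000)]
    acceptors = [("c", "-", 2000)]
    out = make_control_bsjs(donors, acceptors, n=1, rng=rng)
    assert out == [("c", 999, 2000, "-")]


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=100)
@given(
    a=st.sets(st.integers(0, 50), max_size=20),
    b=st.sets(st.integers(0, 50), max_size=20),
)
def test_similarity_properties(a, b):
    if not (a | b):
        return
    s = similarity(a, b)
    assert 0.0 <= s <= 1.0
    assert s == similarity(b, a)
    assert (s == 1.0) == (a == b)


@settings(derandomize=True, max_examples=100)
@given(
    x=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=12),
    scale=st.floats(0.01, 100.0),
)
def test_tau_properties(x, scale):
    if max(x) == 0:
        return
    t = tau_index(x)
    assert 0.0 <= t <= 1.0 + 1e-12
    assert tau_index([v * scale for v in x]) == pytest.approx(t, abs=1e-9)


def test_normalized_bsj_count():
    assert normalized_bsj_count(100, 10**6) == pytest.approx(1e-4)
    assert normalized_bsj_count(0, 100) == 0.0
    assert normalized_bsj_count(100, 10**6) == normalized_bsj_count(200, 2 * 10**6)
    with pytest.raises(ValueError):
        normalized_bsj_count(1, 0)
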