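"""Cross-sample statistics for circRNA isoform catalogs.

Implements the downstream analyses of a multi-sample circRNA isoform study:

* replicate similarity (Jaccard-style shared fraction of BSJs/isoforms);
* pairwise-tissue differential isoform usage: per-gene Pearson chi-square on
  the isoform x tissue read-count table with Benjamini-Hochberg FDR, then
  per-isoform two-sided Fisher exact tests on 2x2 (isoform vs rest) tables;
* tissue-stable and tissue-specific isoform calls (isoform proportions,
  one-tailed binomial tests against the overall proportion);
* Yanai's tissue-specificity index tau, and the Fisher enrichment of
  tissue-specific isoforms in tissue-specific genes;
* inverted-Alu flanking classification of BSJs with negative-control BSJ
  generation;
* read-depth normalization of BSJ counts.

All thresholds default to the conventional values (FDR <= 0.05, isoform
proportion difference >= 0.05, stability proportion > 0.5, read-count floor
2) and are exposed as parameters.  Statistical kernels delegate to scipy /
statsmodels; the tests of this package validate them against brute-force
enumeration oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from rollcirc.annotation import RepeatElement

__all__ = [
    "similarity",
    "similarity_matrix",
    "gene_proportion_test",
    "bh_adjust",
    "flag_differential_genes",
    "isoform_fisher",
    "pairwise_tissue_comparison",
    "tissue_stable",
    "tissue_specific",
    "tau_index",
    "enrichment_test",
    "alu_flank_classify",
    "make_control_bsjs",
    "normalized_bsj_count",
]


class UndefinedStatisticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def similarity(set_a, set_b) -> float:
    """Shared fraction: |A & B| / |A | B| (both sets empty is undefined)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise UndefinedStatisticError("similarity of two empty sets is undefined")
    return len(a & b) / len(union)


def similarity_matrix(sets_by_sample: dict[str, set]) -> pd.DataFrame:
    samples = list(sets_by_sample)
    m = pd.DataFrame(index=samples, columns=samples, dtype=float)
    for i in samples:
        for j in samples:
            m.loc[i, j] = similarity(sets_by_sample[i], sets_by_sample[j])
    return m


# ---------------------------------------------------------------------------
# differential isoform usage between two tissues
# ---------------------------------------------------------------------------

def gene_proportion_test(counts1, counts2) -> tuple[float, float]:
    """Pearson chi-square on a gene's isoform x tissue contingency table.

    No continuity correction.  Isoforms absent from both tissues are
    dropped; a tissue with zero gene total makes the test undefined.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.shape != c2.shape or c1.size < 2:
        raise ValueError("need counts for >= 2 isoforms in both tissues")
    keep = (c1 + c2) > 0
    c1, c2 = c1[keep], c2[keep]
    if c1.size < 2:
        raise UndefinedStatisticError("fewer than 2 detected isoforms")
    if c1.sum() == 0 or c2.sum() == 0:
        raise UndefinedStatisticError("zero gene total in one tissue")
    table = np.vstack([c1, c2])
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def isoform_fisher(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 isoform-vs-rest table.

    Rows are tissues: ``[[iso_t1, rest_t1], [iso_t2, rest_t2]]``.  Returns
    (p, delta_proportion).  A zero margin gives p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    n1, n2 = t[0].sum(), t[1].sum()
    if n1 == 0 or n2 == 0 or t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
        d = abs(t[0, 0] / n1 - t[1, 0] / n2) if n1 and n2 else 0.0
        return 1.0, float(d)
    p = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
    return p, float(abs(t[0, 0] / n1 - t[1, 0] / n2))


def flag_differential_genes(
    fdr_by_gene: dict[str, float],
    max_dprop_by_gene: dict[str, float],
    fdr_cutoff: float = 0.05,
    dprop_cutoff: float = 0.05,
) -> set[str]:
    """Genes with FDR <= cutoff AND some isoform proportion shift >= cutoff."""
    return {
        g
        for g, q in fdr_by_gene.items()
        if q <= fdr_cutoff and max_dprop_by_gene.get(g, 0.0) >= dprop_cutoff
    }


@dataclass
class PairwiseResult:
    genes: pd.DataFrame  # gene, chi2, p, fdr, max_dprop, differential
    isoforms: pd.DataFrame  # gene, isoform, p, dprop, significant


def pairwise_tissue_comparison(
    counts: pd.DataFrame,
    gene_of: pd.Series,
    min_reads: int = 2,
    fdr_cutoff: float = 0.05,
    dprop_cutoff: float = 0.05,
    fisher_p_cutoff: float = 0.05,
) -> PairwiseResult:
    """Two-step differential isoform-usage analysis between two tissues.

    `counts` has one row per isoform and exactly two columns (the tissues);
    `gene_of` maps isoform index to gene.  Isoforms need >= `min_reads`
    reads in at least one tissue to enter.  Step 1 flags genes (chi-square +
    BH, plus a max isoform-proportion shift); step 2 localizes the shifted
    isoforms within flagged genes (Fisher + proportion shift).
    """
    if counts.shape[1] != 2:
        raise ValueError("pairwise comparison needs exactly two tissue columns")
    t1, t2 = counts.columns
    eligible = counts[(counts >= min_reads).any(axis=1)]
    gene_rows: list[dict] = []
    per_gene: dict[str, pd.DataFrame] = {}
    for gene, idx in eligible.groupby(gene_of.reindex(eligible.index)).groups.items():
        sub = eligible.loc[idx]
        if len(sub) < 2:
            continue
        tot1, tot2 = sub[t1].sum(), sub[t2].sum()
        try:
            stat, p = gene_proportion_test(sub[t1].to_numpy(), sub[t2].to_numpy())
        except UndefinedStatisticError:
            continue
        p1 = sub[t1] / tot1 if tot1 else sub[t1] * 0.0
        p2 = sub[t2] / tot2 if tot2 else sub[t2] * 0.0
        gene_rows.append(
            {"gene": gene, "chi2": stat, "p": p, "max_dprop": float((p1 - p2).abs().max())}
        )
        per_gene[gene] = sub
    genes = pd.DataFrame(gene_rows, columns=["gene", "chi2", "p", "max_dprop"])
    if len(genes):
        genes["fdr"] = bh_adjust(genes["p"].to_numpy())
    else:
        genes["fdr"] = []
    genes["differential"] = (genes["fdr"] <= fdr_cutoff) & (genes["max_dprop"] >= dprop_cutoff)

    iso_rows: list[dict] = []
    for _, grow in genes[genes["differential"]].iterrows():
        sub = per_gene[grow["gene"]]
        tot1, tot2 = sub[t1].sum(), sub[t2].sum()
        for key, row in sub.iterrows():
            tbl = [[row[t1], tot1 - row[t1]], [row[t2], tot2 - row[t2]]]
            p, dprop = isoform_fisher(tbl)
            iso_rows.append(
                {
                    "gene": grow["gene"],
                    "isoform": key,
                    "p": p,
                    "dprop": dprop,
                    "significant": p <= fisher_p_cutoff and dprop >= dprop_cutoff,
                }
            )
    isoforms = pd.DataFrame(iso_rows, columns=["gene", "isoform", "p", "dprop", "significant"])
    return PairwiseResult(genes, isoforms)


# ---------------------------------------------------------------------------
# tissue-stable / tissue-specific isoforms
# ---------------------------------------------------------------------------

def tissue_stable(proportions, counts, prop_cutoff: float = 0.5, min_reads: int = 2) -> bool:
    """Stable = proportion strictly > cutoff AND count >= floor in *every* tissue."""
    props = np.asarray(proportions, dtype=float)
    cnts = np.asarray(counts, dtype=int)
    return bool(np.all(props > prop_cutoff) and np.all(cnts >= min_reads))


def binomial_greater(k: int, n: int, p0: float) -> float:
    """One-tailed (greater) binomial test p-value."""
    if n == 0:
        return 1.0
    return float(sps.binomtest(k, n, p0, alternative="greater").pvalue)


def tissue_specific(
    counts: pd.DataFrame,
    gene_of: pd.Series,
    min_reads: int = 2,
    fdr_cutoff: float = 0.05,
    dprop_cutoff: float = 0.05,
    fdr_scope: str = "global",
) -> pd.DataFrame:
    """Tissue-specific isoform-tissue pairs across a multi-tissue count matrix.

    Case (i): genes whose isoforms are all detected in a single tissue --
    their isoforms are tissue-specific by definition.  Case (ii): genes with
    heterogeneous isoform proportions across tissues (chi-square, BH
    FDR <= cutoff); within them, isoform-tissue pairs whose proportion
    significantly exceeds the overall isoform proportion (one-tailed
    binomial test, BH FDR <= cutoff over the tested pairs -- globally by
    default, per gene with ``fdr_scope='gene'``), with a proportion
    difference vs all other tissues >= cutoff and >= `min_reads` reads in
    the tissue.
    """
    if fdr_scope not in ("global", "gene"):
        raise ValueError("fdr_scope must be 'global' or 'gene'")
    eligible = counts[(counts >= min_reads).any(axis=1)]
    out_rows: list[dict] = []
    binom_rows: list[dict] = []

    for gene, idx in eligible.groupby(gene_of.reindex(eligible.index)).groups.items():
        sub = eligible.loc[idx]
        tissue_tot = sub.sum(axis=0)
        detected = tissue_tot[tissue_tot > 0]
        if len(detected) == 1:  # case (i)
            tissue = detected.index[0]
            for key in sub.index:
                out_rows.append(
                    {"gene": gene, "isoform": key, "tissue": tissue, "case": "exclusive"}
                )
            continue
        if len(sub) < 2:
            continue
        tbl = sub.to_numpy(dtype=float)
        keep = tbl.sum(axis=1) > 0
        cols = tbl.sum(axis=0) > 0
        tbl2 = tbl[np.ix_(keep, cols)]
        if tbl2.shape[0] < 2 or tbl2.shape[1] < 2:
            continue
        chi_p = float(sps.chi2_contingency(tbl2, correction=False).pvalue)
        gene_total = float(tbl.sum())
        for key, row in sub.iterrows():
            overall = row.sum() / gene_total
            for tissue in sub.columns:
                n_t = int(tissue_tot[tissue])
                k_t = int(row[tissue])
                if n_t == 0:
                    continue
                other_n = gene_total - n_t
                other_k = row.sum() - k_t
                dprop = k_t / n_t - (other_k / other_n if other_n else 0.0)
                binom_rows.append(
                    {
                        "gene": gene,
                        "isoform": key,
                        "tissue": tissue,
                        "chi_p": chi_p,
                        "binom_p": binomial_greater(k_t, n_t, overall),
                        "dprop": dprop,
                        "count": k_t,
                    }
                )

    binom = pd.DataFrame(
        binom_rows, columns=["gene", "isoform", "tissue", "chi_p", "binom_p", "dprop", "count"]
    )
    if len(binom):
        gene_p = binom.groupby("gene")["chi_p"].first()
        gene_fdr = pd.Series(bh_adjust(gene_p.to_numpy()), index=gene_p.index)
        binom["gene_fdr"] = binom["gene"].map(gene_fdr)
        binom = binom[binom["gene_fdr"] <= fdr_cutoff].copy()
    if len(binom):
        if fdr_scope == "global":
            binom["fdr"] = bh_adjust(binom["binom_p"].to_numpy())
        else:
            binom["fdr"] = binom.groupby("gene")["binom_p"].transform(
                lambda p: bh_adjust(p.to_numpy())
            )
        hits = binom[
            (binom["fdr"] <= fdr_cutoff)
            & (binom["dprop"] >= dprop_cutoff)
            & (binom["count"] >= min_reads)
        ]
        for _, row in hits.iterrows():
            out_rows.append(
                {
                    "gene": row["gene"],
                    "isoform": row["isoform"],
                    "tissue": row["tissue"],
                    "case": "proportion_shift",
                }
            )
    return pd.DataFrame(out_rows, columns=["gene", "isoform", "tissue", "case"]).drop_duplicates()


# ---------------------------------------------------------------------------
# tau and enrichment
# ---------------------------------------------------------------------------

def tau_index(expression) -> float:
    """Yanai's tissue-specificity index.

    tau = sum_i (1 - x_i / x_max) / (n - 1), for a non-negative expression
    vector over n >= 2 tissues; 0 for uniform (housekeeping) expression, 1
    for single-tissue (tissue-specific) expression.  Invariant to scalar
    rescaling.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expression must be a vector over >= 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    m = x.max()
    if m == 0:
        raise UndefinedStatisticError("tau is undefined for an all-zero vector")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def enrichment_test(table) -> tuple[float, float]:
    """Fisher exact test (two-sided) for a 2x2 enrichment table.

    Rows: tissue-specific vs other isoforms; columns: from tissue-specific
    vs other genes.  Returns (odds_ratio, p); an empty margin gives p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    res = sps.fisher_exact(t, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# inverted-Alu flanking analysis
# ---------------------------------------------------------------------------

def alu_flank_classify(
    bsj: tuple[str, int, int],
    repeats: list[RepeatElement],
    window: int = 1000,
    family_prefix: str = "Alu",
) -> str:
    """Classify the inverted-repeat configuration flanking a BSJ.

    ``bsj`` is (chrom, start, end), 0-based half-open circle coordinates.
    The upstream flank is the `window` nt before the circle start, the
    downstream flank the `window` nt after its end (clipped at chromosome
    bounds by construction of the overlap test).  An inverted pair is one
    element in each flank on opposite strands; with the element strand as
    its pointing direction, a pair pointing toward the circle is convergent
    ('+' upstream with '-' downstream) and a pair pointing away is divergent.
    Returns 'convergent', 'divergent', 'both' or 'none'.
    """
    chrom, s, e = bsj
    up = (max(0, s - window), s)
    dn = (e, e + window)
    up_strands: set[str] = set()
    dn_strands: set[str] = set()
    for r in repeats:
        if r.chrom != chrom or not r.family.startswith(family_prefix):
            continue
        if r.start < up[1] and r.end > up[0]:
            up_strands.add(r.strand)
        if r.start < dn[1] and r.end > dn[0]:
            dn_strands.add(r.strand)
    convergent = "+" in up_strands and "-" in dn_strands
    divergent = "-" in up_strands and "+" in dn_strands
    if convergent and divergent:
        return "both"
    if convergent:
        return "convergent"
    if divergent:
        return "divergent"
    return "none"


def make_control_bsjs(
    donors: list[tuple[str, str, int]],
    acceptors: list[tuple[str, str, int]],
    n: int = 10000,
    rng: np.random.Generator | None = None,
    exclude_donors: set | None = None,
    exclude_acceptors: set | None = None,
    max_span: int = 100000,
) -> list[tuple[str, int, int, str]]:
    """Random negative-control BSJs from non-BSJ splice sites.

    Pairs a downstream 5' (donor) site with an upstream 3' (acceptor) site
    on the same chromosome and strand (back-splice geometry), excluding any
    site that participates in an observed or database BSJ.  Sampling is
    without replacement and seeded; if fewer than `n` valid pairs exist, the
    available ones are returned with a warning.  Returns (chrom, start, end,
    strand) circles, 0-based half-open.
    """
    rng = rng or np.random.default_rng(0)
    exclude_donors = exclude_donors or set()
    exclude_acceptors = exclude_acceptors or set()
    d_pool = sorted(set(donors) - exclude_donors)
    a_pool = sorted(set(acceptors) - exclude_acceptors)
    by_key_d: dict[tuple[str, str], list[int]] = {}
    by_key_a: dict[tuple[str, str], list[int]] = {}
    for c, st, p in d_pool:
        by_key_d.setdefault((c, st), []).append(p)
    for c, st, p in a_pool:
        by_key_a.setdefault((c, st), []).append(p)

    pairs: list[tuple[str, int, int, str]] = []
    for (c, st), dons in sorted(by_key_d.items()):
        accs = by_key_a.get((c, st), [])
        for d in dons:
            for a in accs:
                # back-splice geometry: donor downstream of acceptor in
                # transcript orientation
                if st == "-":
                    ok = d < a and a - d + 1 <= max_span
                    circle = (d - 1, a)
                else:
                    ok = d > a and d - a + 1 <= max_span
                    circle = (a - 1, d)
                if ok:
                    pairs.append((c, circle[0], circle[1], st))
    if len(pairs) < n:
        warnings.warn(
            f"only {len(pairs)} eligible control BSJ pairs (requested {n})", stacklevel=2
        )
        chosen = pairs
    else:
        idx = rng.choice(len(pairs), size=n, replace=False)
        chosen = [pairs[i] for i in sorted(idx)]
    return chosen


def normalized_bsj_count(bsj_count: int, total_reads: int) -> float:
    """BSJ count normalized by sequencing depth (BSJs per read)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if bsj_count < 0:
        raise ValueError("bsj_count must be non-negative")
    return bsj_count / total_reads
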