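"""Molar resource allocation to gene sets and its comparisons.

Allocation is the molar percentage of the transcriptome or proteome pool
dedicated to a gene set (a GO-slim biological process, a physiological
group, an isozyme set).  Built on top: enrichment of gene sets in sliding
windows of ranked abundance (Fisher's exact test with Benjamini-Hochberg
FDR), cross-condition allocation fold comparison, log-log regression of
proteome on transcriptome allocation, and isozyme differential-allocation
and switching analysis.

Replicates are averaged before any allocation is computed.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_sets",
    "compute_allocation",
    "sliding_window_enrichment",
    "compare_allocation",
    "allocation_regression",
    "isozyme_analysis",
    "fisher_two_sided",
]


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a term -> gene-set annotation table.

    Supports the SGD ``go_slim_mapping.tab`` dialect (>= 6 tab-separated
    columns: ORF, gene name, SGDID, GO aspect, GO-slim term, GOID, feature
    type) and generic 2- or 3-column TSVs (gene, term[, category]).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="!")
    if df.shape[1] >= 6:
        gene_col, term_col = 0, 4
    elif df.shape[1] in (2, 3):
        gene_col, term_col = 0, 1
    else:
        raise ValueError(f"unrecognized annotation format with {df.shape[1]} columns")
    sets: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        if pd.isna(gene) or pd.isna(term):
            continue
        sets.setdefault(term, set()).add(gene)
    return sets


def _condition_means(matrix) -> pd.DataFrame:
    if isinstance(matrix, OmicsMatrix):
        return matrix.condition_mean()
    return matrix


def compute_allocation(
    matrix,
    annotations: Mapping[str, Iterable[str]],
    normalize_gene_count: bool = False,
) -> pd.DataFrame:
    """Molar allocation (% mol mol^-1) per term and condition.

    ``allocation(term, cond) = 100 * sum_{g in term} a(g, cond) / sum_all``;
    genes in multiple terms count toward each.  With
    ``normalize_gene_count`` the percentage is divided by the number of
    matched genes in the term.  Unmatched genes are logged, terms with no
    matched gene skipped.
    """
    means = _condition_means(matrix)
    totals = means.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("total abundance is zero in at least one condition")
    rows = {}
    for term, genes in annotations.items():
        matched = means.index.intersection(pd.Index(list(genes)))
        missing = len(set(genes)) - len(matched)
        if missing:
            logger.debug("term %s: %d genes not in matrix", term, missing)
        if len(matched) == 0:
            logger.info("term %s skipped: no matched genes", term)
            continue
        frac = 100.0 * means.loc[matched].sum(axis=0) / totals
        if normalize_gene_count:
            frac = frac / len(matched)
        rows[term] = frac
    if not rows:
        raise ValueError("no term matched any gene")
    out = pd.DataFrame(rows).T
    out.index.name = "term"
    return out


@lru_cache(maxsize=262144)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]]."""
    return _fisher_cached(int(a), int(b), int(c), int(d))


def sliding_window_enrichment(
    abundance: pd.Series,
    annotations: Mapping[str, Iterable[str]],
    window: int = 200,
    step: int = 1,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene-set enrichment in sliding windows of ranked abundance.

    Genes are ranked by descending abundance; for each window position and
    term a 2x2 table (in-window & in-term, in-window & not, out-window &
    in-term, out-window & not) is tested by two-sided Fisher's exact test,
    with Benjamini-Hochberg FDR across all window x term tests jointly.
    The full table is returned with a ``significant`` column at
    ``fdr < fdr_threshold``; direction (over/under) comes from the odds
    ratio sign of the window versus the background proportion.
    """
    if window < 10:
        raise ValueError("window below 10 genes makes the test degenerate")
    n = len(abundance)
    if window > n:
        raise ValueError("window larger than the number of genes")
    if step < 1:
        raise ValueError("step must be >= 1")
    ranked = abundance.sort_values(ascending=False, kind="mergesort").index
    term_masks = {}
    for term, genes in annotations.items():
        mask = ranked.isin(set(genes))
        k = int(mask.sum())
        if k == 0:
            logger.info("term %s skipped: empty after matching", term)
            continue
        term_masks[term] = (np.cumsum(np.concatenate([[0], mask])), k)

    starts = list(range(0, n - window + 1, step))
    records = []
    for term, (csum, k_total) in term_masks.items():
        for s in starts:
            in_term = int(csum[s + window] - csum[s])
            a = in_term
            b = window - in_term
            c = k_total - in_term
            d = (n - window) - c
            p = fisher_two_sided(a, b, c, d)
            direction = "over" if a * (n - window) > c * window else "under"
            records.append((s + 1, term, direction, a, p))
    out = pd.DataFrame(
        records, columns=["window_start_rank", "term", "odds_direction", "in_window", "p_fisher"]
    )
    if len(out):
        out["fdr"] = multipletests(out["p_fisher"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < fdr_threshold
    else:
        out["fdr"] = []
        out["significant"] = []
    return out


def compare_allocation(
    alloc_a: pd.DataFrame | pd.Series,
    alloc_b: pd.DataFrame | pd.Series,
    log2_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-term log2 allocation fold b vs a, with |log2| > threshold outliers.

    Terms with zero allocation on either side are reported in a ``censored``
    category rather than as infinite folds.  Antisymmetric: swapping the
    arguments negates every finite log2 fold.
    """
    a = alloc_a.squeeze() if isinstance(alloc_a, pd.DataFrame) else alloc_a
    b = alloc_b.squeeze() if isinstance(alloc_b, pd.DataFrame) else alloc_b
    if not a.index.equals(b.index):
        shared = a.index.intersection(b.index)
        if len(shared) != len(a.index) or len(shared) != len(b.index):
            raise ValueError("allocation tables must share the same term universe")
        b = b.reindex(a.index)
    out = pd.DataFrame(index=a.index)
    censored = (a <= 0) | (b <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_fold"] = np.where(censored, np.nan, np.log2(b / a))
    out["censored"] = censored
    out["outlier"] = (~censored) & (np.abs(out["log2_fold"]) > log2_threshold)
    return out


def allocation_regression(
    transcript_alloc: pd.Series, protein_alloc: pd.Series
) -> tuple[float, float]:
    """Slope and Pearson r of log10 protein% on log10 transcript%.

    A slope above one means small allocation differences at the
    transcriptome level are amplified at the proteome level.
    """
    shared = transcript_alloc.index.intersection(protein_alloc.index)
    x = transcript_alloc.reindex(shared)
    y = protein_alloc.reindex(shared)
    keep = (x > 0) & (y > 0)
    if keep.sum() < 3:
        raise ValueError("need at least 3 terms with positive allocation in both layers")
    lx, ly = np.log10(x[keep].to_numpy(float)), np.log10(y[keep].to_numpy(float))
    res = stats.linregress(lx, ly)
    return float(res.slope), float(res.rvalue)


def isozyme_analysis(
    matrix,
    isozyme_sets: Mapping[str, Iterable[str]],
    condition_a=None,
    condition_b=None,
    log2_threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential allocation per isozyme and switching per reaction.

    Per gene: the allocation fold between two conditions (last vs first by
    default), flagged differential at |log2| > threshold.  Per reaction: the
    switching flag is true iff the majority (largest-share) isozyme differs
    between the two conditions.  Each isozyme set needs >= 2 genes.
    """
    means = _condition_means(matrix)
    conditions = list(means.columns)
    ca = conditions[0] if condition_a is None else condition_a
    cb = conditions[-1] if condition_b is None else condition_b
    alloc = means.div(means.sum(axis=0), axis=1) * 100.0

    gene_rows = []
    rxn_rows = []
    for rxn, genes in isozyme_sets.items():
        genes = list(genes)
        if len(genes) < 2:
            raise ValueError(f"isozyme set {rxn} needs at least 2 genes")
        matched = [g for g in genes if g in alloc.index]
        if len(matched) < 2:
            logger.info("reaction %s skipped: <2 matched isozymes", rxn)
            continue
        sub = alloc.loc[matched, [ca, cb]]
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(sub[cb] / sub[ca])
        shares_a = sub[ca] / sub[ca].sum()
        shares_b = sub[cb] / sub[cb].sum()
        for g in matched:
            gene_rows.append({
                "reaction": rxn, "gene": g,
                "alloc_a": sub.loc[g, ca], "alloc_b": sub.loc[g, cb],
                "log2_fold": lfc[g],
                "differential": bool(np.isfinite(lfc[g]) and abs(lfc[g]) > log2_threshold),
                "share_a": shares_a[g], "share_b": shares_b[g],
            })
        rxn_rows.append({
            "reaction": rxn,
            "major_a": shares_a.idxmax(),
            "major_b": shares_b.idxmax(),
            "switching": shares_a.idxmax() != shares_b.idxmax(),
        })
    return pd.DataFrame(gene_rows), pd.DataFrame(rxn_rows).set_index("reaction")
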