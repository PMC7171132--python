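"""Gene-specific translation efficiency and translational reserves.

At chemostat steady state the protein balance is
``k_sP * mRNA = (mu + k_deg) * protein``: synthesis balances dilution by
growth plus degradation.  The translation efficiency
``k_sP = protein * (mu + k_deg) / mRNA`` (protein mRNA^-1 h^-1) rises when
reserve translational capacity is put to use; grouping genes by the
nitrogen-reduction step at which k_sP first exceeds 2-fold of the
carbon-limited reference partitions the genome by when that reserve is
activated, and ``reserve = 1 - 1/fold`` converts an activation fold into a
reserve fraction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .allocation import fisher_two_sided
from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "compute_ksp",
    "compute_ksp_table",
    "group_by_activation",
    "reserve_from_fold",
    "group_enrichment",
    "group_summary",
]


def compute_ksp(protein, mrna, mu: float, k_deg=0.0):
    """k_sP = protein * (mu + k_deg) / mRNA (steady-state balance).

    Scalar or vectorized.  ``k_deg`` defaults to 0 when turnover data is
    unavailable (then k_sP is an apparent, dilution-only efficiency).
    """
    protein = np.asarray(protein, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    if np.any(mrna <= 0):
        raise ValueError("mRNA concentration must be positive")
    if mu < 0 or np.any(np.asarray(k_deg) < 0):
        raise ValueError("mu and k_deg must be non-negative")
    out = protein * (mu + np.asarray(k_deg)) / mrna
    return float(out) if out.ndim == 0 else out


def compute_ksp_table(
    proteome: OmicsMatrix | pd.DataFrame,
    transcriptome: OmicsMatrix | pd.DataFrame,
    mu: float,
    turnover: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene, per-condition k_sP from paired omics matrices.

    Replicates are averaged first.  Genes with zero mRNA in any condition
    are excluded (logged); without ``turnover``, k_deg = 0 is used for all
    genes and the fallback is logged.
    """
    prot = proteome.condition_mean() if isinstance(proteome, OmicsMatrix) else proteome
    mrna = transcriptome.condition_mean() if isinstance(transcriptome, OmicsMatrix) else transcriptome
    shared = prot.index.intersection(mrna.index)
    prot, mrna = prot.loc[shared], mrna.loc[shared, prot.columns]
    ok = (mrna > 0).all(axis=1)
    if (~ok).any():
        logger.info("compute_ksp_table: excluded %d genes with zero mRNA", int((~ok).sum()))
    prot, mrna = prot[ok], mrna[ok]
    if turnover is None:
        logger.info("compute_ksp_table: no turnover data, using k_deg = 0")
        kdeg = pd.Series(0.0, index=prot.index)
    else:
        kdeg = turnover.reindex(prot.index).fillna(0.0)
    return prot.mul(mu + kdeg, axis=0) / mrna


def group_by_activation(
    ksp: pd.DataFrame,
    condition_order: list | None = None,
    log2_threshold: float = 1.0,
    mode: str = "first",
) -> pd.Series:
    """Group genes by the nitrogen-reduction step activating their reserve.

    The first column (condition) is the reference.  Group ``g`` (1-based)
    is the first non-reference condition at which
    ``log2(k_sP / k_sP_ref) > log2_threshold``; genes never exceeding the
    threshold fall in the last group (group ``n_conditions``).  With
    ``mode="sustained"`` the fold must stay above threshold in all later
    conditions as well.
    """
    if mode not in ("first", "sustained"):
        raise ValueError("mode must be 'first' or 'sustained'")
    cols = list(ksp.columns) if condition_order is None else list(condition_order)
    mat = ksp[cols].to_numpy(float)
    ref = mat[:, 0]
    if np.any(ref <= 0):
        raise ValueError("reference k_sP must be positive for fold computation")
    with np.errstate(divide="ignore"):
        lfc = np.log2(mat[:, 1:] / ref[:, None])
    above = lfc > log2_threshold
    if mode == "sustained":
        above = np.flip(np.cumprod(np.flip(above, axis=1), axis=1), axis=1).astype(bool)
    n_steps = above.shape[1]
    first = np.where(above.any(axis=1), above.argmax(axis=1) + 1, n_steps + 1)
    return pd.Series(first, index=ksp.index, name="activation_group")


def reserve_from_fold(fold: float) -> float:
    """Reserve fraction implied by an activation fold: 1 - 1/fold.

    A 5.6-fold k_sP increase means 82% of the translational capacity was
    held in reserve; a 2-fold increase means 50%.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1 (no reserve defined below 1)")
    return 1.0 - 1.0 / fold


def group_summary(ksp: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Median k_sP fold versus reference per group and condition."""
    folds = ksp.div(ksp.iloc[:, 0], axis=0)
    out = folds.groupby(groups).median()
    out["n_genes"] = groups.value_counts().reindex(out.index)
    return out


def group_enrichment(
    groups: pd.Series,
    annotations: Mapping[str, Iterable[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per (group, term) two-sided Fisher enrichment with BH-FDR.

    The 2x2 table counts genes in/out of the group against genes in/out of
    the term, over the grouped gene universe.
    """
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    universe = set(groups.index)
    n = len(universe)
    records = []
    for term, genes in annotations.items():
        term_genes = set(genes) & universe
        if not term_genes:
            logger.info("term %s skipped: empty after matching", term)
            continue
        k = len(term_genes)
        for g in levels:
            members = set(groups.index[groups == g])
            a = len(members & term_genes)
            b = len(members) - a
            c = k - a
            d = n - len(members) - c
            p = fisher_two_sided(a, b, c, d)
            direction = "over" if a * (n - len(members)) > c * len(members) else "under"
            records.append((g, term, direction, a, p))
    out = pd.DataFrame(records, columns=["group", "term", "odds_direction", "in_group", "p_fisher"])
    if len(out):
        out["fdr"] = multipletests(out["p_fisher"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < fdr_threshold
    return out
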