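"""Ribosomal-protein stoichiometry, diversity and condition response.

Quantifies RP : rRNA stoichiometry per subunit, splits subunits into a
highly expressed "core" group and a sub-stoichiometric group (data-driven
1-D 2-means on log10 abundance), models the combinatorial diversity and
buildable abundance of ribosome complexes containing ``n`` RP subunits,
and calls subunits (and individual paralogs) selectively upregulated under
nitrogen limitation.

Diversity uses exact integer combinatorics: a complex carries all
``n_core`` core subunits plus an ``(n - n_core)``-subset of the ``n_sub``
sub-stoichiometric subunits, so ``D(n) = C(n_sub, n - n_core)``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .synthetic import RPProfile

__all__ = [
    "rp_rrna_ratios",
    "classify_core_sub",
    "diversity_curve",
    "capacity_curve",
    "upregulated_rps",
    "RPProfile",
]


def rp_rrna_ratios(profile: RPProfile) -> pd.DataFrame:
    """Per-subunit RP : rRNA ratio per condition, with sub-stoichiometric flag.

    The ratio is subunit abundance divided by the rRNA-derived ribosome
    count; ratios below 1 mark subunits present in fewer copies than
    assembled ribosomes.
    """
    rrna = profile.rrna_ribosomes.reindex(profile.abundance.columns)
    if (rrna <= 0).any():
        raise ValueError("ribosome count from rRNA must be positive")
    ratios = profile.abundance.div(rrna, axis=1)
    flags = ratios < 1.0
    flags.columns = [f"{c}_substoich" for c in flags.columns]
    return pd.concat([ratios, flags], axis=1)


def _two_means_1d(x: np.ndarray, tol: float = 1e-10, max_iter: int = 500):
    """Deterministic 1-D 2-means: centers initialized at the extremes."""
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < tol:
        return None
    c = np.array([lo, hi])
    for _ in range(max_iter):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        if len(np.unique(assign)) < 2:
            return None
        new = np.array([x[assign == 0].mean(), x[assign == 1].mean()])
        if np.allclose(new, c, atol=tol):
            break
        c = new
    return assign, c


def classify_core_sub(profile: RPProfile, reference_condition=None) -> pd.Series:
    """Split subunits into core / sub-stoichiometric by 2-means on log10 abundance.

    The higher cluster in the reference condition (first condition by
    default) is labelled ``core``.  If all abundances coincide, everything
    is labelled core with a warning.  Labels are invariant under a global
    rescaling of all abundances.
    """
    if len(profile.subunits) < 4:
        raise ValueError("need at least 4 subunits to classify")
    cond = profile.conditions[0] if reference_condition is None else reference_condition
    ab = profile.abundance[cond].to_numpy(float)
    if (ab <= 0).any():
        raise ValueError("abundances must be positive for log-scale clustering")
    res = _two_means_1d(np.log10(ab))
    if res is None:
        warnings.warn("single abundance population; labelling all subunits core")
        labels = pd.Series("core", index=profile.subunits, name="label")
    else:
        assign, centers = res
        core_cluster = int(np.argmax(centers))
        labels = pd.Series(
            np.where(assign == core_cluster, "core", "sub"),
            index=profile.subunits, name="label",
        )
    profile.labels = labels
    return labels


def diversity_curve(n_core: int = 54, n_sub: int = 22) -> pd.DataFrame:
    """Number of distinct ribosome compositions per complex size.

    ``D(n) = C(n_sub, n - n_core)`` for ``n_core <= n <= n_core + n_sub``,
    evaluated in exact integer arithmetic.  D is 1 at both ends, symmetric
    about ``n_core + n_sub / 2``, and sums to ``2**n_sub``.
    """
    if n_core < 0 or n_sub < 0:
        raise ValueError("subunit counts must be non-negative")
    ns = np.arange(n_core, n_core + n_sub + 1)
    D = [math.comb(n_sub, int(n) - n_core) for n in ns]
    return pd.DataFrame({"n": ns, "diversity": D})


def capacity_curve(
    profile: RPProfile,
    n_range: tuple[int, int] | None = None,
    condition=None,
) -> pd.DataFrame:
    """Maximum number of buildable ribosomes per complex size.

    Default capacity model: for ``n <= n_core`` the rRNA-derived ribosome
    count is the cap; beyond that,
    ``N(n) = min(ribosomes, floor(total sub-stoichiometric copies / (n - n_core)))``
    since each extra subunit slot consumes one sub-stoichiometric copy per
    ribosome.  Strictly non-increasing for ``n > n_core``.  The model is a
    documented choice and deliberately swappable.
    """
    if profile.labels is None:
        raise ValueError("classify_core_sub must be run first (labels unassigned)")
    cond = profile.conditions[0] if condition is None else condition
    n_core = int((profile.labels == "core").sum())
    n_sub = int((profile.labels == "sub").sum())
    sub_total = float(profile.abundance.loc[profile.labels == "sub", cond].sum())
    ribosomes = float(profile.rrna_ribosomes[cond])
    lo, hi = n_range if n_range is not None else (n_core, n_core + n_sub)
    rows = []
    for n in range(lo, hi + 1):
        if n <= n_core:
            cap = ribosomes
        else:
            cap = min(ribosomes, math.floor(sub_total / (n - n_core)))
        rows.append((n, cap))
    return pd.DataFrame(rows, columns=["n", "capacity"])


def upregulated_rps(
    profile: RPProfile,
    reference=None,
    log2_threshold: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Subunits selectively upregulated versus the reference condition.

    A subunit is flagged when the maximum over non-reference conditions of
    ``log2(abundance / reference)`` exceeds the threshold.  A
    paralog-specific call is emitted for subunits with two paralogs where
    exactly one paralog crosses the threshold while its sibling does not.
    """
    conds = profile.conditions
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    ref = conds[0] if reference is None else reference
    others = [c for c in conds if c != ref]

    def _crossers(table: pd.DataFrame) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(table[others].div(table[ref], axis=0))
        return lfc.max(axis=1) > log2_threshold

    flagged = set(profile.subunits[_crossers(profile.abundance)])

    paralog_specific: set[str] = set()
    if profile.paralog_abundance is not None:
        pcross = _crossers(profile.paralog_abundance)
        for subunit, paras in profile.paralogs.items():
            if len(paras) < 2:
                continue
            hits = [p for p in paras if pcross.get(p, False)]
            if 0 < len(hits) < len(paras):
                paralog_specific.add(subunit)
    return flagged, paralog_specific
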