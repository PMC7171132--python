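"""Independent oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) they are used to check: exact-rational hypergeometric
enumeration for Fisher's test, exhaustive basic-feasible-solution
enumeration for the small LPs, and an additive Pascal-triangle for
binomial coefficients.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def comb_exact(n: int, k: int) -> int:
    """Binomial coefficient via an additive Pascal triangle (no factorials)."""
    if k < 0 or k > n:
        return 0
    row = [1]
    for _ in range(n):
        row = [1] + [row[i] + row[i + 1] for i in range(len(row) - 1)] + [1]
    return row[k]


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by exact-rational enumeration.

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed table's (exact Fraction
    arithmetic; float conversion only at the end).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def table_weight(x: int) -> int:
        # un-normalized hypergeometric weight C(row1, x) * C(n-row1, col1-x)
        from math import comb

        return comb(row1, x) * comb(n - row1, col1 - x)

    total = sum(table_weight(x) for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1))
    obs = Fraction(table_weight(a), total)
    p = Fraction(0)
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        px = Fraction(table_weight(x), total)
        if px <= obs:
            p += px
    return float(min(p, Fraction(1)))


def enumerate_vertices(A_eq, b_eq, A_ub, b_ub, lb, ub, tol: float = 1e-9):
    """All basic feasible solutions of {A_eq x = b_eq, A_ub x <= b_ub, lb <= x <= ub}.

    Every inequality and finite bound is turned into a candidate active
    constraint; each full-rank combination of n active constraints
    (equalities always included) is solved and kept if feasible.  Only
    usable for tiny systems.
    """
    A_eq = np.atleast_2d(np.asarray(A_eq, float))
    b_eq = np.asarray(b_eq, float)
    n = A_eq.shape[1]
    rows = [(A_eq[i], b_eq[i]) for i in range(A_eq.shape[0])]
    cand = []
    if A_ub is not None and len(A_ub):
        A_ub = np.atleast_2d(np.asarray(A_ub, float))
        b_ub = np.asarray(b_ub, float)
        cand += [(A_ub[i], b_ub[i]) for i in range(A_ub.shape[0])]
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        if np.isfinite(lb[j]):
            cand.append((-e, -lb[j]))
        if np.isfinite(ub[j]):
            cand.append((e.copy(), ub[j]))

    n_eq = len(rows)
    need = n - n_eq
    vertices = []
    for combo in itertools.combinations(range(len(cand)), need):
        A = np.array([r[0] for r in rows] + [cand[i][0] for i in combo])
        b = np.array([r[1] for r in rows] + [cand[i][1] for i in combo])
        if np.linalg.matrix_rank(A) < n:
            continue
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ x - b)) > 1e-7:
            continue
        ok = np.all(x >= np.asarray(lb) - tol) and np.all(x <= np.asarray(ub) + tol)
        if ok and A_ub is not None and len(A_ub):
            ok = np.all(A_ub @ x <= b_ub + tol)
        if ok and np.max(np.abs(A_eq @ x - b_eq)) > 1e-7:
            ok = False
        if ok:
            vertices.append(x)
    if not vertices:
        return np.empty((0, n))
    V = np.array(vertices)
    # deduplicate
    keep = []
    for v in V:
        if not any(np.allclose(v, w, atol=1e-7) for w in keep):
            keep.append(v)
    return np.array(keep)


def ecmodel_vertices(model):
    """Vertex set of an EcModel's flux/usage polytope (pool bound required)."""
    from reservecalc.ecfba import _lp_parts

    A_eq, b_eq, A_ub, b_ub, bounds, rxns, enzs = _lp_parts(model)
    lb = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    ub = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
    V = enumerate_vertices(A_eq, b_eq, A_ub, b_ub, lb, ub)
    return V, rxns, enzs


def min_pool_by_enumeration(model) -> float:
    """Minimum enzyme-pool mass over all vertices (LP optimum is at a vertex)."""
    V, rxns, enzs = ecmodel_vertices(model)
    mw = np.array([model.enzymes[e].mw for e in enzs])
    pools = V[:, len(rxns):] @ mw
    return float(pools.min())


def fva_by_enumeration(model):
    """Per-reaction (min, max) flux over the enumerated vertex set."""
    import pandas as pd

    V, rxns, enzs = ecmodel_vertices(model)
    flux = V[:, : len(rxns)]
    return pd.DataFrame(
        {"minimum": flux.min(axis=0), "maximum": flux.max(axis=0)}, index=rxns
    )
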