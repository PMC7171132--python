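"""Enzyme-constrained flux balance analysis.

A small ec-FBA engine in the GECKO convention: each enzyme draws from a
shared enzyme pool (mass bound ``P_met``, g gDW^-1) through a usage
pseudo-flux (mmol gDW^-1), and every catalyzed reaction is capped by
``v_j <= kcat_ej * usage_e``.  Linear programs are assembled in-package and
solved through a narrow solver interface (scipy HiGHS); any LP solver
meeting a 1e-9 feasibility tolerance would do.

Provided analyses: biomass-composition rescaling, condition constraining,
minimum-enzyme-demand (sigma, the saturation coefficient), flux variability
analysis, random-sampling modal solutions, and superpathway usage/reserve
statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

__all__ = [
    "Enzyme",
    "BiomassComposition",
    "EcModel",
    "FluxSolution",
    "InfeasibleModelError",
    "scale_biomass",
    "constrain",
    "minimize_enzyme_pool",
    "saturation_sigma",
    "SaturationResult",
    "fva",
    "sample_optimal",
    "pathway_usage",
    "pathway_usage_fold",
    "UsageFold",
]

FEASIBILITY_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    """Raised when a constrained model admits no feasible flux distribution."""


@dataclass
class Enzyme:
    """An enzyme with molecular weight (g mmol^-1) and kcat links (h^-1)."""

    mw: float
    links: dict[str, float]  # reaction id -> kcat

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular weight must be positive")
        for rxn, kcat in self.links.items():
            if kcat <= 0:
                raise ValueError(f"kcat for {rxn} must be positive")


@dataclass
class BiomassComposition:
    """Mass coefficients of the biomass pseudo-reaction (g gDW^-1) plus GAM.

    GAM (growth-associated maintenance, mmol ATP gDW^-1) is a configured
    constant; it is carried but never recalculated here.
    """

    protein: float
    rna: float
    carbohydrate: float
    gam: float = 30.0

    @property
    def total_mass(self) -> float:
        return self.protein + self.rna + self.carbohydrate


@dataclass
class EcModel:
    """Stoichiometric network with enzyme/kcat links and a shared pool bound."""

    S: pd.DataFrame  # metabolites x reactions
    lb: pd.Series
    ub: pd.Series
    enzymes: dict[str, Enzyme] = field(default_factory=dict)
    pool_bound: float | None = None  # P_met, g gDW^-1
    biomass: BiomassComposition | None = None
    biomass_reaction: str | None = None
    reference_flux: pd.Series | None = None
    name: str = "ecmodel"

    def __post_init__(self) -> None:
        rxns = self.S.columns
        if not (self.lb.index.equals(rxns) and self.ub.index.equals(rxns)):
            self.lb = self.lb.reindex(rxns)
            self.ub = self.ub.reindex(rxns)
        if self.lb.isna().any() or self.ub.isna().any():
            raise ValueError("bounds must be given for every reaction")
        for enz, e in self.enzymes.items():
            for rxn in e.links:
                if rxn not in rxns:
                    raise ValueError(f"enzyme {enz} links unknown reaction {rxn}")
                if self.lb[rxn] < 0:
                    raise ValueError(
                        f"catalyzed reaction {rxn} must be irreversible (lb >= 0)"
                    )
        if self.pool_bound is not None and self.pool_bound < 0:
            raise ValueError("P_met must be non-negative")

    @property
    def reactions(self) -> list[str]:
        return list(self.S.columns)

    @property
    def metabolites(self) -> list[str]:
        return list(self.S.index)

    def copy(self) -> "EcModel":
        return replace(
            self,
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            enzymes={k: Enzyme(v.mw, dict(v.links)) for k, v in self.enzymes.items()},
            reference_flux=None if self.reference_flux is None else self.reference_flux.copy(),
        )


@dataclass
class FluxSolution:
    """One flux distribution with its enzyme usage and pool consumption."""

    fluxes: pd.Series
    enzyme_usage: pd.Series  # mmol gDW^-1
    pool_used: float  # g gDW^-1
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    spread: pd.DataFrame | None = None  # per-reaction dispersion (sampling only)
    sample_pools: np.ndarray | None = None  # pool_used of each sampled LP solution


# ---------------------------------------------------------------------------
# LP assembly (narrow solver interface)
# ---------------------------------------------------------------------------


def _lp_parts(model: EcModel):
    """Assemble equality/inequality matrices over variables [fluxes, usages]."""
    rxns = model.reactions
    enzs = list(model.enzymes)
    n_v, n_u = len(rxns), len(enzs)
    n = n_v + n_u
    rxn_pos = {r: i for i, r in enumerate(rxns)}

    A_eq = np.hstack([model.S.to_numpy(float), np.zeros((len(model.metabolites), n_u))])
    b_eq = np.zeros(len(model.metabolites))

    rows = []
    for ui, enz in enumerate(enzs):
        for rxn, kcat in model.enzymes[enz].links.items():
            row = np.zeros(n)
            row[rxn_pos[rxn]] = 1.0
            row[n_v + ui] = -kcat
            rows.append(row)
    if model.pool_bound is not None and n_u:
        row = np.zeros(n)
        for ui, enz in enumerate(enzs):
            row[n_v + ui] = model.enzymes[enz].mw
        rows.append(row)
    A_ub = np.vstack(rows) if rows else np.zeros((0, n))
    b_ub = np.zeros(A_ub.shape[0])
    if model.pool_bound is not None and n_u:
        b_ub[-1] = model.pool_bound

    bounds = [(model.lb[r], model.ub[r]) for r in rxns] + [(0.0, None)] * n_u
    return A_eq, b_eq, A_ub, b_ub, bounds, rxns, enzs


def _solve(model: EcModel, c: np.ndarray, sense: int = 1) -> FluxSolution:
    """Solve min (sense=1) or max (sense=-1) of c^T x over the ec-FBA polytope."""
    A_eq, b_eq, A_ub, b_ub, bounds, rxns, enzs = _lp_parts(model)
    res = linprog(
        sense * c,
        A_ub=A_ub if A_ub.size else None,
        b_ub=b_ub if b_ub.size else None,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return FluxSolution(
            fluxes=pd.Series(np.nan, index=rxns),
            enzyme_usage=pd.Series(np.nan, index=enzs),
            pool_used=math.nan,
            objective_value=math.nan,
            status="infeasible",
        )
    if res.status == 3:
        return FluxSolution(
            fluxes=pd.Series(np.nan, index=rxns),
            enzyme_usage=pd.Series(np.nan, index=enzs),
            pool_used=math.nan,
            objective_value=math.inf * -sense,
            status="unbounded",
        )
    x = res.x
    n_v = len(rxns)
    fluxes = pd.Series(x[:n_v], index=rxns)
    usage = pd.Series(x[n_v:], index=enzs)
    pool = float(sum(model.enzymes[e].mw * usage[e] for e in enzs))
    return FluxSolution(
        fluxes=fluxes,
        enzyme_usage=usage,
        pool_used=pool,
        objective_value=float(sense * res.fun),
        status="optimal",
    )


def _objective(model: EcModel, flux_weights: Mapping[str, float] | None = None,
               usage_weights: Mapping[str, float] | None = None) -> np.ndarray:
    rxns, enzs = model.reactions, list(model.enzymes)
    c = np.zeros(len(rxns) + len(enzs))
    for r, w in (flux_weights or {}).items():
        c[rxns.index(r)] = w
    for e, w in (usage_weights or {}).items():
        c[len(rxns) + enzs.index(e)] = w
    return c


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------


def scale_biomass(model: EcModel, protein_content: float, rna_content: float) -> EcModel:
    """Rescale biomass composition to measured protein and RNA content.

    The carbohydrate coefficient absorbs the difference so that the biomass
    component masses still sum to 1 g gDW^-1.  GAM is left unchanged.
    """
    if model.biomass is None:
        raise ValueError("model carries no biomass composition")
    if protein_content <= 0 or rna_content <= 0:
        raise ValueError("contents must be positive")
    if protein_content + rna_content >= 1:
        raise ValueError("protein + RNA content exceeds total biomass mass")
    out = model.copy()
    out.biomass = BiomassComposition(
        protein=protein_content,
        rna=rna_content,
        carbohydrate=1.0 - protein_content - rna_content,
        gam=model.biomass.gam,
    )
    return out


def constrain(
    model: EcModel,
    P_met: float,
    exchange_fluxes: Mapping[str, float] | None = None,
    growth_rate: float | None = None,
    exchange_tol: float = 0.05,
) -> EcModel:
    """Apply condition constraints: pool bound, growth rate, measured exchanges.

    Measured exchange fluxes are clamped to value +/- ``exchange_tol``
    (relative), not hard equalities; the biomass/demand flux is fixed to the
    growth rate exactly.  Raises :class:`InfeasibleModelError` listing the
    applied constraints if the result is infeasible.
    """
    if P_met < 0:
        raise ValueError("P_met must be non-negative")
    out = model.copy()
    out.pool_bound = P_met
    applied = [f"P_met={P_met}"]
    if growth_rate is not None:
        if out.biomass_reaction is None:
            raise ValueError("model has no biomass reaction to fix growth rate on")
        out.lb[out.biomass_reaction] = growth_rate
        out.ub[out.biomass_reaction] = growth_rate
        applied.append(f"{out.biomass_reaction}={growth_rate}")
    for rxn, value in (exchange_fluxes or {}).items():
        if rxn not in out.S.columns:
            raise ValueError(f"unknown exchange reaction {rxn}")
        lo, hi = sorted((value * (1 - exchange_tol), value * (1 + exchange_tol)))
        out.lb[rxn], out.ub[rxn] = lo, hi
        applied.append(f"{rxn}={value}+/-{exchange_tol:.0%}")
    probe = _solve(out, np.zeros(len(out.reactions) + len(out.enzymes)))
    if probe.status == "infeasible":
        raise InfeasibleModelError(
            "model infeasible under constraints: " + "; ".join(applied)
        )
    return out


def minimize_enzyme_pool(model: EcModel) -> tuple[float, FluxSolution]:
    """Minimum total enzyme demand P_min (g gDW^-1) and its flux solution.

    Solves min sum_e MW_e * usage_e subject to mass balance, bounds and kcat
    coupling; this is the in-silico minimum enzyme demand whose ratio to the
    measured enzyme pool is the saturation coefficient sigma.
    """
    if not model.enzymes:
        raise ValueError("model has no enzymes")
    c = _objective(model, usage_weights={e: model.enzymes[e].mw for e in model.enzymes})
    sol = _solve(model, c, sense=1)
    if sol.status != "optimal":
        raise InfeasibleModelError(f"enzyme pool minimization ended with status {sol.status}")
    return sol.objective_value, sol


class SaturationResult(NamedTuple):
    sigma: float
    reserve: float


def saturation_sigma(P_min: float, P_measured: float) -> SaturationResult:
    """Enzyme saturation coefficient sigma = P_min / P_measured.

    The complement ``reserve = 1 - sigma`` is the fraction of the measured
    enzyme pool held in reserve.
    """
    if P_measured <= 0:
        raise ValueError("measured enzyme pool must be positive")
    sigma = P_min / P_measured
    return SaturationResult(sigma=sigma, reserve=1.0 - sigma)


def fva(model: EcModel, reactions: Iterable[str] | None = None) -> pd.DataFrame:
    """Flux variability analysis: per-reaction (min, max) flux.

    Two LPs per reaction.  Unbounded directions are reported as +/-inf.
    """
    rxns = list(reactions) if reactions is not None else model.reactions
    rows = {}
    for rxn in rxns:
        c = _objective(model, flux_weights={rxn: 1.0})
        lo = _solve(model, c, sense=1)
        hi = _solve(model, c, sense=-1)
        if lo.status == "infeasible" or hi.status == "infeasible":
            raise InfeasibleModelError("FVA on infeasible model")
        vmin = -math.inf if lo.status == "unbounded" else lo.objective_value
        vmax = math.inf if hi.status == "unbounded" else hi.objective_value
        rows[rxn] = (vmin, vmax)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["minimum", "maximum"])
    return out.loc[rxns]


def _fd_mode(samples: np.ndarray, lo: float, hi: float) -> float:
    """Histogram mode with Freedman-Diaconis bins inside the FVA interval.

    Ties between equally tall bins break toward the bin containing the
    sample median.
    """
    if hi - lo <= FEASIBILITY_TOL * max(1.0, abs(hi)):
        return 0.5 * (lo + hi)
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    width = 2 * iqr / len(samples) ** (1 / 3) if iqr > 0 else 0.0
    n_bins = int(np.ceil((hi - lo) / width)) if width > 0 else 10
    n_bins = min(max(n_bins, 1), 1000)
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if len(candidates) > 1:
        med = np.median(samples)
        med_bin = min(np.searchsorted(edges, med, side="right") - 1, n_bins - 1)
        idx = candidates[np.argmin(np.abs(candidates - med_bin))]
    else:
        idx = candidates[0]
    return float(0.5 * (edges[idx] + edges[idx + 1]))


def sample_optimal(
    model: EcModel,
    n_samples: int = 1000,
    seed: int | None = None,
    pair_mode: str = "single",
    fva_bounds: pd.DataFrame | None = None,
) -> FluxSolution:
    """Modal flux distribution from randomly weighted objective sampling.

    Per sample a non-negative weight vector over a random half of the
    reactions is drawn and the weighted flux sum is both maximized and
    minimized (the "pair"); with ``pair_mode="independent"`` the two
    directions use independent weight vectors.  The per-reaction mode over
    all collected solutions, estimated by histogram binning between the FVA
    bounds, is reported as the optimal solution.
    """
    if pair_mode not in ("single", "independent"):
        raise ValueError("pair_mode must be 'single' or 'independent'")
    rng = np.random.default_rng(seed)
    rxns = model.reactions
    n_v = len(rxns)
    bounds = fva(model) if fva_bounds is None else fva_bounds
    if not np.isfinite(bounds.to_numpy()).all():
        raise InfeasibleModelError("sampling requires bounded FVA intervals")

    k = max(1, math.ceil(n_v / 2))
    collected = []
    pools = []
    for _ in range(n_samples):
        subset = rng.choice(n_v, size=k, replace=False)
        w = np.zeros(n_v + len(model.enzymes))
        w[subset] = 1.0 - rng.random(k)  # uniform(0, 1]
        sol_max = _solve(model, w, sense=-1)
        if pair_mode == "independent":
            subset = rng.choice(n_v, size=k, replace=False)
            w = np.zeros(n_v + len(model.enzymes))
            w[subset] = 1.0 - rng.random(k)
        sol_min = _solve(model, w, sense=1)
        for sol in (sol_max, sol_min):
            if sol.status == "optimal":
                collected.append(sol.fluxes.to_numpy())
                pools.append(sol.pool_used)
    if not collected:
        raise InfeasibleModelError("all random-objective samples were infeasible")
    mat = np.asarray(collected)

    modal = np.empty(n_v)
    for j, rxn in enumerate(rxns):
        modal[j] = _fd_mode(mat[:, j], bounds.loc[rxn, "minimum"], bounds.loc[rxn, "maximum"])
    fluxes = pd.Series(modal, index=rxns)

    # Enzyme usage implied by the modal fluxes (GECKO coupling, binding kcat).
    usage = {}
    for enz, e in model.enzymes.items():
        usage[enz] = max((fluxes[r] / kc for r, kc in e.links.items()), default=0.0)
    usage = pd.Series(usage, dtype=float)
    pool = float(sum(model.enzymes[e].mw * usage[e] for e in usage.index))
    spread = pd.DataFrame(
        {"std": mat.std(axis=0), "q25": np.percentile(mat, 25, axis=0),
         "q75": np.percentile(mat, 75, axis=0)},
        index=rxns,
    )
    return FluxSolution(
        fluxes=fluxes,
        enzyme_usage=usage,
        pool_used=pool,
        objective_value=math.nan,
        status="optimal",
        spread=spread,
        sample_pools=np.asarray(pools),
    )


def pathway_usage(
    solution: FluxSolution,
    measured_enzymes: pd.Series,
    pathways: Mapping[str, Iterable[str]],
    min_genes: int = 5,
) -> pd.DataFrame:
    """Superpathway usage and reserve from simulated demand vs measurement.

    usage_p = sum of simulated enzyme demand over the pathway's enzymes
    divided by the sum of their measured abundance; reserve = 1 - usage.
    Pathways with fewer than ``min_genes`` matched enzymes or zero simulated
    demand are excluded (logged).
    """
    rows = {}
    for pw, enzymes in pathways.items():
        matched = [e for e in enzymes if e in measured_enzymes.index and e in solution.enzyme_usage.index]
        if len(matched) < min_genes:
            logger.info("pathway %s excluded: %d matched enzymes < %d", pw, len(matched), min_genes)
            continue
        demand = float(solution.enzyme_usage[matched].sum())
        if demand <= 0:
            logger.info("pathway %s excluded: zero simulated flux", pw)
            continue
        measured = float(measured_enzymes[matched].sum())
        if measured <= 0:
            raise ValueError(f"pathway {pw} has zero measured abundance")
        usage = demand / measured
        rows[pw] = {
            "simulated_demand": demand,
            "measured_abundance": measured,
            "usage": usage,
            "reserve": 1.0 - usage,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


class UsageFold(NamedTuple):
    flux_fold: float
    usage_fold: float
    reference_usage: float
    reference_reserve: float


def pathway_usage_fold(
    flux_ref: float, enzyme_ref: float, flux_alt: float, enzyme_alt: float
) -> UsageFold:
    """Relative pathway usage between two conditions from flux and enzyme sums.

    Usage scales as flux / enzyme abundance, so the usage fold between the
    alternative and reference condition is
    ``(flux_alt / enzyme_alt) / (flux_ref / enzyme_ref)``.  When the
    alternative condition runs the pathway at full (saturated) usage, the
    reference condition's usage is the reciprocal of this fold, with its
    reserve complement.
    """
    if min(flux_ref, enzyme_ref, flux_alt, enzyme_alt) <= 0:
        raise ValueError("fluxes and enzyme abundances must be positive")
    flux_fold = flux_alt / flux_ref
    usage_fold = (flux_alt / enzyme_alt) / (flux_ref / enzyme_ref)
    return UsageFold(
        flux_fold=flux_fold,
        usage_fold=usage_fold,
        reference_usage=1.0 / usage_fold,
        reference_reserve=1.0 - 1.0 / usage_fold,
    )
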