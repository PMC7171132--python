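"""Synthetic chemostat multi-omics with known ground truth.

Emulates the study conditions of nitrogen-limited steady-state chemostats:
four conditions ordered carbon-limited -> most nitrogen-limited at a fixed
dilution rate of 0.2 h^-1, with total protein declining to 50% and total
mRNA to 25% of the carbon-limited reference, per-process molar allocation
held constant across conditions, lognormal gene abundances with
multiplicative lognormal measurement noise, spike-in calibrators spanning
the dynamic range, a toy fermentation/respiration network with known
minimal enzyme demand, and a bimodal (core / sub-stoichiometric) ribosomal
protein profile.

Every random draw flows through one seeded generator, so a fixed seed gives
bit-identical datasets; with ``noise_cv=0`` the stored truth reproduces the
dataset exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, make_columns, lognormal_noise
from .ecfba import BiomassComposition, EcModel, Enzyme

__all__ = [
    "SynthConfig",
    "SyntheticDataset",
    "generate_chemostat_omics",
    "generate_spikein_standards",
    "generate_toy_model",
    "generate_rp_profile",
    "media_cn_ratio",
    "biomass_cn_ratio",
    "DEFAULT_ALLOCATION",
]

# Molar masses (g/mol): glucose C6H12O6, ammonium sulfate (NH4)2SO4
# (standard atomic weights).
GLUCOSE_MW = 180.16
AMMONIUM_SULFATE_MW = 132.14

# Default per-process molar allocation, one entry per functional category.
# Metabolism dominates (the measured proteome is ~half metabolic enzymes by
# mass); translation is the second-largest consumer.  The remainder of the
# molar pool is carried by an explicit "unassigned" pool at generation time.
DEFAULT_ALLOCATION: dict[str, float] = {
    "metabolism": 0.45,
    "translation": 0.12,
    "protein_processing": 0.10,
    "transcription": 0.08,
    "stress_response": 0.05,
    "cell_cycle_organelle": 0.05,
    "dna_maintenance": 0.03,
}

_UNASSIGNED = "unassigned"


@dataclass
class SynthConfig:
    """Ground-truth parameters of the synthetic chemostat experiment.

    Defaults are the study conditions: 4 conditions (C-limited reference,
    then media C/N 30, 50, 115), biological duplicates, a 2x total-protein
    and 4x total-mRNA reduction between the first and last condition, and
    20% CV multiplicative lognormal measurement noise.
    """

    n_genes: int = 3000
    n_conditions: int = 4
    n_replicates: int = 2
    protein_reduction: float = 0.5
    mrna_reduction: float = 0.25
    noise_cv: float = 0.2
    seed: int = 0
    allocation_profile: dict[str, float | list[float]] = field(
        default_factory=lambda: dict(DEFAULT_ALLOCATION)
    )
    rp_core_mean: float = 3e5  # copies/cell, core RP group
    rp_sub_mean: float = 3e4  # copies/cell, sub-stoichiometric group
    dilution_rate: float = 0.2  # h^-1
    # log10 standard deviations of base gene abundance; protein spans a
    # larger range than mRNA (translation amplifies transcription signals).
    mrna_log10_sd: float = 1.0
    protein_log10_sd: float = 1.5
    # Target k_sP fold once a gene's translational reserve is activated
    # (realized folds stay > 2 but may deviate to close the per-process
    # protein-mass balance exactly; see generate_chemostat_omics).
    activated_fold: float = 2.5
    # Reference-condition total molar content (mmol gDW^-1).
    base_mrna_total: float = 1.5e-4
    base_protein_total: float = 8e-3
    kdeg_median: float = 0.04  # h^-1, protein degradation
    kdeg_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        for name, frac in (
            ("protein_reduction", self.protein_reduction),
            ("mrna_reduction", self.mrna_reduction),
        ):
            if not 0 < frac <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        totals = np.zeros(self.n_conditions)
        for proc, frac in self.allocation_profile.items():
            arr = self._per_condition(frac)
            if (arr < 0).any():
                raise ValueError(f"allocation for {proc} must be non-negative")
            totals += arr
        if (totals > 1 + 1e-12).any():
            raise ValueError("allocation fractions must sum to <= 1 per condition")

    def _per_condition(self, frac: float | list[float]) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(frac, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, self.n_conditions)
        if arr.size != self.n_conditions:
            raise ValueError("per-condition allocation must have n_conditions entries")
        return arr

    @property
    def condition_names(self) -> list[str]:
        if self.n_conditions == 4:
            return ["Clim", "CN30", "CN50", "CN115"]
        return ["Clim"] + [f"Nlim{i}" for i in range(1, self.n_conditions)]


@dataclass
class SyntheticDataset:
    """A generated multi-omics dataset plus the truth that produced it."""

    transcriptome: OmicsMatrix
    proteome: OmicsMatrix
    turnover: pd.Series  # per-gene k_deg, h^-1
    annotations: dict[str, set[str]]  # process -> gene set
    truth: dict

    def write(self, outdir) -> None:
        """Write TSV matrices, turnover TSV and a YAML truth sidecar."""
        import pathlib

        import yaml

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.transcriptome.to_tsv(outdir / "transcriptome.tsv")
        self.proteome.to_tsv(outdir / "proteome.tsv")
        self.turnover.rename("k_deg").to_csv(outdir / "turnover.tsv", sep="\t")
        ann = pd.DataFrame(
            [(g, p) for p, genes in self.annotations.items() for g in sorted(genes)],
            columns=["gene", "term"],
        )
        ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        truth = {
            k: (v.to_dict() if isinstance(v, (pd.Series, pd.DataFrame)) else v)
            for k, v in self.truth.items()
        }
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(_to_plain(truth), fh)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    return obj


def _geometric_trajectory(ratio: float, n: int) -> np.ndarray:
    """Total-content multipliers declining geometrically from 1 to ``ratio``."""
    return ratio ** (np.arange(n) / (n - 1))


def generate_chemostat_omics(config: SynthConfig) -> SyntheticDataset:
    """Generate paired absolute transcriptome/proteome matrices with truth.

    Construction guarantees, exactly at ``noise_cv=0``:

    * total mRNA and protein content decline geometrically to
      ``mrna_reduction`` and ``protein_reduction`` of the reference;
    * per-process molar allocation equals the configured profile in every
      condition (within each process, genes whose translational reserve is
      not yet activated absorb a solved compensation factor so process
      totals close exactly);
    * each gene's k_sP activation group is recoverable from its realized
      k_sP trajectory with a 2-fold threshold.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nC, nG = cfg.n_conditions, cfg.n_genes
    conditions = cfg.condition_names
    genes = pd.Index([f"g{i:05d}" for i in range(nG)], name="gene")

    # --- process assignment (gene counts proportional to molar fractions) --
    procs = list(cfg.allocation_profile)
    alloc = {p: cfg._per_condition(cfg.allocation_profile[p]) for p in procs}
    rest = 1.0 - np.sum([alloc[p] for p in procs], axis=0)
    if (rest > 1e-12).any():
        alloc[_UNASSIGNED] = rest
        procs = procs + [_UNASSIGNED]
    probs = np.array([max(alloc[p][0], 1e-9) for p in procs])
    probs = probs / probs.sum()
    proc_of_gene = rng.choice(len(procs), size=nG, p=probs)
    # guarantee one gene per activation group per process
    min_per_proc = max(4, nC)
    for pi in range(len(procs)):
        short = min_per_proc - int((proc_of_gene == pi).sum())
        if short > 0:
            pool = np.flatnonzero(
                np.bincount(proc_of_gene, minlength=len(procs))[proc_of_gene]
                > min_per_proc
            )
            proc_of_gene[rng.choice(pool, size=short, replace=False)] = pi

    # --- base abundances -------------------------------------------------
    mrna_w = 10 ** rng.normal(0.0, cfg.mrna_log10_sd, nG)
    prot_w = 10 ** rng.normal(0.0, cfg.protein_log10_sd, nG)
    r_m = _geometric_trajectory(cfg.mrna_reduction, nC)
    r_p = _geometric_trajectory(cfg.protein_reduction, nC)

    mrna0 = np.empty(nG)
    prot0 = np.empty(nG)
    for pi, p in enumerate(procs):
        mask = proc_of_gene == pi
        mrna0[mask] = mrna_w[mask] / mrna_w[mask].sum() * alloc[p][0] * cfg.base_mrna_total
        prot0[mask] = prot_w[mask] / prot_w[mask].sum() * alloc[p][0] * cfg.base_protein_total

    # --- k_sP activation groups ------------------------------------------
    # Groups 1..nC-1 activate (cross 2-fold) at condition step 1..nC-1;
    # group nC never activates.  Within each process, genes are assigned to
    # groups by greedy mass balancing so every group carries ~1/nC of the
    # process's protein mass (required for the exact compensation solve).
    # The heaviest gene of each process goes to the never-activated group
    # (mirroring the highly abundant translation-machinery proteins that do
    # not modulate k_sP); the rest are greedily mass-balanced across all
    # groups.  This bounds any activating group's protein-mass share at 1/2,
    # which keeps the per-process fold solve below feasible.
    group = np.empty(nG, dtype=int)
    for pi in range(len(procs)):
        idx = np.flatnonzero(proc_of_gene == pi)
        idx = idx[np.argsort(-prot0[idx])]
        load = np.zeros(nC)
        order = rng.permutation(nC)  # randomize tie-breaking across processes
        group[idx[0]] = nC
        load[nC - 1] += prot0[idx[0]]
        for g in idx[1:]:
            tgt = order[np.argmin(load[order])]
            group[g] = tgt + 1
            load[tgt] += prot0[g]

    # --- per-gene k_sP fold trajectories ----------------------------------
    # At each step the activated genes of a process share one fold F > 2 and
    # the not-yet-activated genes one fold u < 2, solved jointly from the
    # process protein-mass balance so the process total closes exactly:
    #   F * s + u * (1 - s) = T(c),   s = activated mass share,
    #   T(c) = r_p(c) / r_m(c)  (protein vs mRNA total trajectory).
    # u is targeted at (T - activated_fold * s) / (1 - s), clipped into
    # [0.2, 1.8] so activation is always separated from the 2-fold line.
    fold = np.ones((nG, nC))
    T = r_p / r_m
    for pi, p in enumerate(procs):
        mask = proc_of_gene == pi
        pm = prot0[mask].sum()
        for c in range(1, nC):
            crossed = mask & (group <= c)
            uncrossed = mask & (group > c)
            s = prot0[crossed].sum() / pm
            if not 0 < s < 1:
                raise RuntimeError(f"process {p} needs genes in every activation group")
            u = float(np.clip((T[c] - cfg.activated_fold * s) / (1 - s), 0.2, 1.8))
            F = (T[c] - u * (1 - s)) / s
            if F <= 2.02:
                raise RuntimeError(
                    f"activated fold {F:.3f} for {p} step {c} too close to the "
                    "2-fold threshold; the configured reductions are outside the "
                    "supported regime (mRNA must be reduced at least as much as protein)"
                )
            fold[crossed, c] = F
            fold[uncrossed, c] = u

    # --- assemble noise-free matrices -------------------------------------
    mrna = np.empty((nG, nC))
    prot = np.empty((nG, nC))
    for pi, p in enumerate(procs):
        mask = proc_of_gene == pi
        for c in range(nC):
            mr = (alloc[p][c] / alloc[p][0]) * r_m[c]
            mrna[mask, c] = mrna0[mask] * mr
            prot[mask, c] = prot0[mask] * fold[mask, c] * mr

    kdeg = pd.Series(
        np.exp(rng.normal(math.log(cfg.kdeg_median), cfg.kdeg_log_sd, nG)),
        index=genes, name="k_deg",
    )
    ksp_base = prot0 * (cfg.dilution_rate + kdeg.to_numpy()) / mrna0

    # --- replicate expansion with measurement noise -----------------------
    cols = make_columns(conditions, cfg.n_replicates)
    vm = np.repeat(mrna, cfg.n_replicates, axis=1) * lognormal_noise(
        rng, cfg.noise_cv, (nG, nC * cfg.n_replicates))
    vp = np.repeat(prot, cfg.n_replicates, axis=1) * lognormal_noise(
        rng, cfg.noise_cv, (nG, nC * cfg.n_replicates))

    meta = {
        "dilution_rate": cfg.dilution_rate,
        "condition_order": conditions,
        "media_cn_ratio": [3.5, 30, 50, 115][:nC] if nC <= 4 else None,
    }
    transcriptome = OmicsMatrix(
        values=pd.DataFrame(vm, index=genes, columns=cols),
        layer="mRNA",
        total_content=pd.Series(cfg.base_mrna_total * r_m, index=conditions),
        meta=dict(meta),
    )
    proteome = OmicsMatrix(
        values=pd.DataFrame(vp, index=genes, columns=cols),
        layer="protein",
        total_content=pd.Series(cfg.base_protein_total * r_p, index=conditions),
        meta=dict(meta),
    )
    annotations = {
        p: set(genes[proc_of_gene == pi])
        for pi, p in enumerate(procs) if p != _UNASSIGNED
    }
    truth = {
        "config": asdict(cfg),
        "process_of_gene": pd.Series([procs[i] for i in proc_of_gene], index=genes),
        "allocation": pd.DataFrame(
            {p: alloc[p] for p in procs}, index=conditions).T,
        "mrna_total": pd.Series(cfg.base_mrna_total * r_m, index=conditions),
        "protein_total": pd.Series(cfg.base_protein_total * r_p, index=conditions),
        "protein_reduction": cfg.protein_reduction,
        "mrna_reduction": cfg.mrna_reduction,
        "ksp_fold": pd.DataFrame(fold, index=genes, columns=conditions),
        "ksp_base": pd.Series(ksp_base, index=genes),
        "activation_group": pd.Series(group, index=genes),
        "noise_free_mrna": pd.DataFrame(mrna, index=genes, columns=conditions),
        "noise_free_protein": pd.DataFrame(prot, index=genes, columns=conditions),
    }
    return SyntheticDataset(
        transcriptome=transcriptome,
        proteome=proteome,
        turnover=kdeg,
        annotations=annotations,
        truth=truth,
    )


def generate_spikein_standards(
    n_standards: int,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spike-in calibrators spanning >= 3 orders of magnitude.

    Known concentrations are log-spaced over 4 decades and signals follow
    ``log10(signal) = slope*log10(conc) + intercept + noise``.
    """
    if n_standards < 3:
        raise ValueError("need at least 3 standards (regression underdetermined)")
    rng = np.random.default_rng(seed)
    conc = np.logspace(-1.5, 2.5, n_standards)
    log_noise = (
        np.log10(lognormal_noise(rng, noise_cv, n_standards)) if noise_cv > 0
        else np.zeros(n_standards)
    )
    signal = 10 ** (slope * np.log10(conc) + intercept + log_noise)
    return pd.DataFrame({"known_concentration": conc, "signal": signal})


def generate_toy_model(variant: str = "branched-fermentation") -> EcModel:
    """A toy enzyme-constrained network with known minimal enzyme demand.

    ``linear``: a 3-reaction chain (uptake -> catalyzed conversion -> demand)
    with one enzyme.  ``branched-fermentation``: glucose uptake splitting
    into a high-yield respiration-like branch (cheap per mole of glucose,
    expensive per unit flux) and a low-yield / high-rate fermentation-like
    branch, both producing ATP for a demand reaction; ethanol leaves through
    an exchange.  A mass-balanced reference flux is attached.
    """
    if variant == "linear":
        mets = ["A", "B"]
        rxns = ["R_in", "R1", "R_out"]
        S = pd.DataFrame(0.0, index=mets, columns=rxns)
        S.loc["A", "R_in"] = 1.0
        S.loc["A", "R1"] = -1.0
        S.loc["B", "R1"] = 1.0
        S.loc["B", "R_out"] = -1.0
        lb = pd.Series({"R_in": 0.0, "R1": 0.0, "R_out": 1.0})
        ub = pd.Series({"R_in": 1000.0, "R1": 1000.0, "R_out": 1.0})
        enzymes = {"E1": Enzyme(mw=50.0, links={"R1": 100.0})}
        ref = pd.Series({"R_in": 1.0, "R1": 1.0, "R_out": 1.0})
        return EcModel(
            S=S, lb=lb, ub=ub, enzymes=enzymes,
            biomass=BiomassComposition(protein=0.45, rna=0.10, carbohydrate=0.45),
            biomass_reaction="R_out", reference_flux=ref, name="toy-linear",
        )
    if variant == "branched-fermentation":
        mets = ["glc", "atp", "eth"]
        rxns = ["GLC_up", "RESP", "FERM", "ETH_ex", "ATP_demand"]
        S = pd.DataFrame(0.0, index=mets, columns=rxns)
        S.loc["glc", "GLC_up"] = 1.0
        S.loc["glc", "RESP"] = -1.0
        S.loc["atp", "RESP"] = 10.0
        S.loc["glc", "FERM"] = -1.0
        S.loc["atp", "FERM"] = 2.0
        S.loc["eth", "FERM"] = 2.0
        S.loc["eth", "ETH_ex"] = -1.0
        S.loc["atp", "ATP_demand"] = -1.0
        lb = pd.Series({r: 0.0 for r in rxns})
        ub = pd.Series({r: 1000.0 for r in rxns})
        lb["ATP_demand"] = ub["ATP_demand"] = 20.0
        lb["GLC_up"] = 0.0
        ub["GLC_up"] = 10.0
        enzymes = {
            # respiration: high ATP yield per glucose, slow and heavy enzyme
            "E_resp": Enzyme(mw=60.0, links={"RESP": 50.0}),
            # fermentation: low yield, fast and light enzyme
            "E_ferm": Enzyme(mw=40.0, links={"FERM": 600.0}),
        }
        # reference: all ATP demand met by respiration
        ref = pd.Series({"GLC_up": 2.0, "RESP": 2.0, "FERM": 0.0,
                         "ETH_ex": 0.0, "ATP_demand": 20.0})
        return EcModel(
            S=S, lb=lb, ub=ub, enzymes=enzymes,
            biomass=BiomassComposition(protein=0.45, rna=0.10, carbohydrate=0.45),
            biomass_reaction="ATP_demand", reference_flux=ref,
            name="toy-branched-fermentation",
        )
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class RPProfile:
    """Per-subunit ribosomal protein abundances and rRNA-derived ribosomes.

    ``abundance`` is paralog-summed (shared peptides counted once);
    ``paralog_abundance`` keeps paralogs separate where a subunit has two.
    """

    abundance: pd.DataFrame  # subunit x condition, copies/cell
    paralogs: dict[str, list[str]]
    paralog_abundance: pd.DataFrame | None
    rrna_ribosomes: pd.Series  # ribosome count per condition from rRNA
    labels: pd.Series | None = None  # core | sub
    truth: dict = field(default_factory=dict)

    @property
    def subunits(self) -> pd.Index:
        return self.abundance.index

    @property
    def conditions(self) -> list:
        return list(self.abundance.columns)

    def to_tsv(self, path) -> None:
        long = self.abundance.reset_index().melt(
            id_vars="subunit", var_name="condition", value_name="abundance")
        long.to_csv(path, sep="\t", index=False)


def generate_rp_profile(
    n_core: int = 54,
    n_sub: int = 22,
    config: SynthConfig | None = None,
    n_upregulated: int = 17,
    n_paralog_specific: int = 3,
) -> RPProfile:
    """Generate a bimodal core/sub-stoichiometric RP abundance profile.

    Core subunits are drawn around ``rp_core_mean`` (geometric mean) and
    sub-stoichiometric subunits an order of magnitude lower around
    ``rp_sub_mean``.  ``n_upregulated`` subunits are selectively shifted
    >2-fold in the most N-limited condition, ``n_paralog_specific`` of them
    through only one of two paralogs.  Ribosome counts from rRNA track the
    total-RNA reduction across conditions.
    """
    if n_core + n_sub < 2:
        raise ValueError("need at least 2 RP subunits")
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed + 77003)
    nC = cfg.n_conditions
    conditions = cfg.condition_names

    names = [f"RPC{i + 1:02d}" for i in range(n_core)] + [
        f"RPS{i + 1:02d}" for i in range(n_sub)]
    is_sub = np.array([False] * n_core + [True] * n_sub)
    log_sd = 0.25 if cfg.noise_cv > 0 else 0.0
    base = np.where(is_sub, cfg.rp_sub_mean, cfg.rp_core_mean) * (
        10 ** rng.normal(0.0, log_sd, n_core + n_sub))

    # ribosome count tracks total RNA (80% rRNA) across conditions
    r_m = _geometric_trajectory(cfg.mrna_reduction, nC)
    rrna = pd.Series(cfg.rp_core_mean * r_m, index=conditions)

    # RP totals follow total protein across conditions
    r_p = _geometric_trajectory(cfg.protein_reduction, nC)
    ab = np.outer(base, r_p)

    n_up = min(n_upregulated, n_core + n_sub)
    up_idx = rng.choice(n_core + n_sub, size=n_up, replace=False)
    up_fold = 2.5
    ab[up_idx, -1] *= up_fold / r_p[-1]  # >2-fold over reference in last condition

    noise = lognormal_noise(rng, cfg.noise_cv, ab.shape)
    abundance = pd.DataFrame(ab * noise, index=pd.Index(names, name="subunit"),
                             columns=conditions)

    # paralog structure: first 5 upregulated + paralog-specific responders
    # get two paralogs; everything else has one
    paralogs: dict[str, list[str]] = {s: [f"{s}a"] for s in names}
    two_paralog = list(np.array(names)[up_idx[: min(5, n_up)]])
    spec_idx = [i for i in range(n_core + n_sub) if i not in up_idx][:n_paralog_specific]
    paralog_specific = [names[i] for i in spec_idx]
    for s in two_paralog + paralog_specific:
        paralogs[s] = [f"{s}a", f"{s}b"]

    rows = {}
    for s in names:
        total = abundance.loc[s].to_numpy()
        if len(paralogs[s]) == 1:
            rows[f"{s}a"] = total
        else:
            rows[f"{s}a"] = 0.6 * total
            rows[f"{s}b"] = 0.4 * total
    for s in paralog_specific:
        # one paralog rises 4x over reference in the last condition while the
        # sibling follows the global decline; the subunit-level sum stays
        # below the 2-fold threshold
        a = rows[f"{s}a"].copy()
        b = rows[f"{s}b"].copy()
        b[-1] = b[0] * 4.0
        a[-1] = a[0] * r_p[-1]
        rows[f"{s}a"], rows[f"{s}b"] = a, b
        abundance.loc[s] = a + b
    paralog_abundance = pd.DataFrame(rows, index=conditions).T
    paralog_abundance.index.name = "paralog"

    truth = {
        "labels": pd.Series(np.where(is_sub, "sub", "core"), index=abundance.index),
        "upregulated": sorted(np.array(names)[up_idx]),
        "paralog_specific": sorted(paralog_specific),
        "rp_core_mean": cfg.rp_core_mean,
        "rp_sub_mean": cfg.rp_sub_mean,
    }
    return RPProfile(
        abundance=abundance,
        paralogs=paralogs,
        paralog_abundance=paralog_abundance,
        rrna_ribosomes=rrna,
        labels=None,
        truth=truth,
    )


def media_cn_ratio(glucose_gL: float, ammonium_sulfate_gL: float) -> float:
    """Molar C/N ratio of a glucose / ammonium sulfate medium.

    Six carbons per glucose, two nitrogens per ammonium sulfate.
    """
    if glucose_gL <= 0 or ammonium_sulfate_gL <= 0:
        raise ValueError("concentrations must be positive")
    carbon = 6 * glucose_gL / GLUCOSE_MW
    nitrogen = 2 * ammonium_sulfate_gL / AMMONIUM_SULFATE_MW
    return carbon / nitrogen


def biomass_cn_ratio(carbon_frac: float, nitrogen_frac: float) -> float:
    """Elemental C/N mass ratio of dry biomass."""
    if not (0 < carbon_frac < 1) or not (0 < nitrogen_frac < 1):
        raise ValueError("elemental fractions must be in (0, 1)")
    return carbon_frac / nitrogen_frac
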