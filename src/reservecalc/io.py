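"""Serialization of enzyme-constrained models and condition constraints.

The core stoichiometric network travels as SBML Level 3 (through cobra's
reader/writer) or as a documented 3-file TSV set; the enzyme layer (enzyme,
reaction, kcat, molecular weight) always travels as a separate TSV since
SBML core has no native slot for it.  Condition constraints (growth rate,
exchange fluxes, P_met, protein/RNA content) are YAML.
"""

from __future__ import annotations

import pathlib

import pandas as pd
import yaml

from .ecfba import BiomassComposition, EcModel, Enzyme

__all__ = [
    "write_model_tsv",
    "read_model_tsv",
    "write_model_sbml",
    "read_model_sbml",
    "write_enzyme_tsv",
    "read_enzyme_tsv",
    "read_constraints_yaml",
]

_BIG = 1000.0  # default bound magnitude used when SBML carries infinities


def write_enzyme_tsv(model: EcModel, path) -> None:
    rows = [
        {"enzyme": enz, "reaction": rxn, "kcat": kcat, "mw": e.mw}
        for enz, e in model.enzymes.items()
        for rxn, kcat in e.links.items()
    ]
    pd.DataFrame(rows, columns=["enzyme", "reaction", "kcat", "mw"]).to_csv(
        path, sep="\t", index=False)


def read_enzyme_tsv(path) -> dict[str, Enzyme]:
    df = pd.read_csv(path, sep="\t")
    enzymes: dict[str, Enzyme] = {}
    for enz, grp in df.groupby("enzyme"):
        mw = float(grp["mw"].iloc[0])
        enzymes[enz] = Enzyme(mw=mw, links=dict(zip(grp["reaction"], grp["kcat"].astype(float))))
    return enzymes


def write_model_tsv(model: EcModel, outdir) -> None:
    """Write the 3-file TSV set: reactions, stoichiometry, enzyme links."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rxns = pd.DataFrame({
        "reaction": model.reactions,
        "lb": [model.lb[r] for r in model.reactions],
        "ub": [model.ub[r] for r in model.reactions],
    })
    rxns.to_csv(outdir / "reactions.tsv", sep="\t", index=False)
    stoich = model.S.stack()
    stoich = stoich[stoich != 0].rename("coefficient").reset_index()
    stoich.columns = ["metabolite", "reaction", "coefficient"]
    stoich.to_csv(outdir / "metabolites.tsv", sep="\t", index=False)
    write_enzyme_tsv(model, outdir / "enzymes.tsv")
    meta = {
        "name": model.name,
        "pool_bound": model.pool_bound,
        "biomass_reaction": model.biomass_reaction,
        "biomass": None if model.biomass is None else {
            "protein": model.biomass.protein, "rna": model.biomass.rna,
            "carbohydrate": model.biomass.carbohydrate, "gam": model.biomass.gam,
        },
    }
    with open(outdir / "model.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_model_tsv(outdir) -> EcModel:
    outdir = pathlib.Path(outdir)
    rxns = pd.read_csv(outdir / "reactions.tsv", sep="\t")
    stoich = pd.read_csv(outdir / "metabolites.tsv", sep="\t")
    S = stoich.pivot_table(
        index="metabolite", columns="reaction", values="coefficient", fill_value=0.0
    ).reindex(columns=rxns["reaction"], fill_value=0.0)
    S.columns.name = None
    S.index.name = None
    meta_path = outdir / "model.yaml"
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    biomass = meta.get("biomass")
    return EcModel(
        S=S,
        lb=pd.Series(rxns["lb"].to_numpy(float), index=rxns["reaction"]),
        ub=pd.Series(rxns["ub"].to_numpy(float), index=rxns["reaction"]),
        enzymes=read_enzyme_tsv(outdir / "enzymes.tsv"),
        pool_bound=meta.get("pool_bound"),
        biomass=None if biomass is None else BiomassComposition(**biomass),
        biomass_reaction=meta.get("biomass_reaction"),
        name=meta.get("name", "ecmodel"),
    )


def _to_cobra(model: EcModel):
    import cobra

    m = cobra.Model(model.name)
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolites}
    for rid in model.reactions:
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lb[rid])
        rxn.upper_bound = float(model.ub[rid])
        coeffs = model.S[rid]
        rxn.add_metabolites({mets[mid]: float(c) for mid, c in coeffs.items() if c != 0})
        m.add_reactions([rxn])
    return m


def write_model_sbml(model: EcModel, sbml_path, enzyme_tsv_path=None) -> None:
    """Write the core network as SBML Level 3 plus the enzyme-link TSV."""
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(sbml_path))
    if enzyme_tsv_path is not None:
        write_enzyme_tsv(model, enzyme_tsv_path)


def read_model_sbml(sbml_path, enzyme_tsv_path=None, **kwargs) -> EcModel:
    from cobra.io import read_sbml_model

    m = read_sbml_model(str(sbml_path))
    mets = [met.id for met in m.metabolites]
    rxns = [rxn.id for rxn in m.reactions]
    S = pd.DataFrame(0.0, index=mets, columns=rxns)
    lb, ub = {}, {}
    for rxn in m.reactions:
        for met, coeff in rxn.metabolites.items():
            S.loc[met.id, rxn.id] = float(coeff)
        lb[rxn.id] = max(float(rxn.lower_bound), -_BIG)
        ub[rxn.id] = min(float(rxn.upper_bound), _BIG)
    enzymes = read_enzyme_tsv(enzyme_tsv_path) if enzyme_tsv_path is not None else {}
    return EcModel(
        S=S,
        lb=pd.Series(lb).reindex(rxns),
        ub=pd.Series(ub).reindex(rxns),
        enzymes=enzymes,
        name=m.id or "ecmodel",
        **kwargs,
    )


def read_constraints_yaml(path) -> dict:
    """Condition constraints: growth_rate, exchange_fluxes, P_met, contents."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("constraints YAML must be a mapping")
    return data
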