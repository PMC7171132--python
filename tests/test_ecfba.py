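"""ec-FBA engine checked against exhaustive basic-feasible-solution
enumeration on the toy networks, plus the closed-form and benchmark
arithmetic of saturation and pathway usage."""

import numpy as np
import pandas as pd
import pytest

from reservecalc import ecfba as ec
from reservecalc import synthetic as sy

from oracles import fva_by_enumeration, min_pool_by_enumeration


@pytest.fixture()
def constrained_branched(branched_model):
    return ec.constrain(branched_model, P_met=2.0)


class TestScaleBiomass:
    def test_fixed_point(self, branched_model):
        b = branched_model.biomass
        out = ec.scale_biomass(branched_model, b.protein, b.rna)
        assert out.biomass.protein == b.protein
        assert out.biomass.carbohydrate == pytest.approx(b.carbohydrate)

    def test_mass_conservation(self, branched_model):
        out = ec.scale_biomass(branched_model, 0.25, 0.10)
        # protein dropped 0.45 -> 0.25; carbohydrate absorbs exactly 0.20
        assert out.biomass.carbohydrate == pytest.approx(
            branched_model.biomass.carbohydrate + 0.20)
        assert out.biomass.total_mass == pytest.approx(1.0, abs=1e-12)

    def test_gam_unchanged(self, branched_model):
        out = ec.scale_biomass(branched_model, 0.3, 0.05)
        assert out.biomass.gam == branched_model.biomass.gam

    def test_excessive_contents_rejected(self, branched_model):
        with pytest.raises(ValueError):
            ec.scale_biomass(branched_model, 0.7, 0.4)


class TestConstrain:
    def test_zero_pool_infeasible(self, branched_model):
        with pytest.raises(ec.InfeasibleModelError):
            ec.constrain(branched_model, P_met=0.0)

    def test_generous_pool_feasible(self, branched_model):
        m = ec.constrain(branched_model, P_met=10.0)
        p_min, sol = ec.minimize_enzyme_pool(m)
        assert sol.status == "optimal"

    def test_pool_below_minimum_infeasible(self, branched_model):
        p_min, _ = ec.minimize_enzyme_pool(ec.constrain(branched_model, P_met=100.0))
        with pytest.raises(ec.InfeasibleModelError):
            ec.constrain(branched_model, P_met=0.5 * p_min)

    def test_exchange_clamping(self, branched_model):
        m = ec.constrain(branched_model, P_met=5.0, exchange_fluxes={"GLC_up": 4.0})
        assert m.lb["GLC_up"] == pytest.approx(3.8)
        assert m.ub["GLC_up"] == pytest.approx(4.2)


class TestMinimizeEnzymePool:
    def test_linear_chain_closed_form(self, linear_model):
        """Single enzyme, demand v, kcat 100/h, MW 50 g/mmol: P = v/kcat*MW."""
        m = linear_model.copy()
        m.lb["R_out"] = m.ub["R_out"] = 2.0
        p_min, sol = ec.minimize_enzyme_pool(m)
        assert p_min == pytest.approx(2.0 / 100.0 * 50.0, abs=1e-9)
        assert sol.enzyme_usage["E1"] == pytest.approx(0.02, abs=1e-10)

    def test_matches_vertex_enumeration(self, constrained_branched):
        p_min, _ = ec.minimize_enzyme_pool(constrained_branched)
        assert p_min == pytest.approx(
            min_pool_by_enumeration(constrained_branched), abs=1e-8)

    def test_doubling_kcats_halves_pool(self, branched_model):
        p1, _ = ec.minimize_enzyme_pool(branched_model)
        fast = branched_model.copy()
        for e in fast.enzymes.values():
            e.links = {r: 2 * k for r, k in e.links.items()}
        p2, _ = ec.minimize_enzyme_pool(fast)
        assert p2 == pytest.approx(p1 / 2, rel=1e-9)

    def test_solution_satisfies_invariants(self, constrained_branched):
        _, sol = ec.minimize_enzyme_pool(constrained_branched)
        S = constrained_branched.S.to_numpy()
        v = sol.fluxes[constrained_branched.reactions].to_numpy()
        assert np.abs(S @ v).max() <= 1e-8
        for enz, e in constrained_branched.enzymes.items():
            for rxn, kcat in e.links.items():
                assert sol.fluxes[rxn] <= kcat * sol.enzyme_usage[enz] + 1e-8
        assert sol.pool_used <= constrained_branched.pool_bound + 1e-8


class TestSaturation:
    def test_headline_arithmetic(self):
        sat = ec.saturation_sigma(0.71, 1.0)
        assert sat.reserve == pytest.approx(0.29, abs=1e-12)

    def test_saturated_regime(self):
        sat = ec.saturation_sigma(0.2, 0.2)
        assert sat.sigma == 1.0
        assert sat.reserve == 0.0

    def test_zero_demand(self):
        assert ec.saturation_sigma(0.0, 1.0).sigma == 0.0

    def test_sigma_monotone_in_demand(self, branched_model):
        """Raising the ATP demand raises sigma against a fixed measured pool."""
        sigmas = []
        for demand in (5.0, 10.0, 20.0):
            m = branched_model.copy()
            m.lb["ATP_demand"] = m.ub["ATP_demand"] = demand
            p_min, _ = ec.minimize_enzyme_pool(m)
            sigmas.append(ec.saturation_sigma(p_min, 2.0).sigma)
        assert sigmas == sorted(sigmas)
        assert sigmas[0] < sigmas[-1]


class TestFVA:
    def test_fixed_flux_is_point(self, constrained_branched):
        iv = ec.fva(constrained_branched)
        assert iv.loc["ATP_demand", "minimum"] == pytest.approx(
            iv.loc["ATP_demand", "maximum"], abs=1e-9)

    def test_matches_vertex_enumeration(self, constrained_branched):
        got = ec.fva(constrained_branched)
        oracle = fva_by_enumeration(constrained_branched)
        np.testing.assert_allclose(
            got.to_numpy(), oracle.loc[got.index].to_numpy(), atol=1e-8)

    def test_monotone_nesting_under_pool_tightening(self, branched_model, rng):
        p_min, _ = ec.minimize_enzyme_pool(ec.constrain(branched_model, P_met=100.0))
        pools = np.sort(p_min * (1 + 9 * rng.random(10)))[::-1]
        prev = None
        for pool in pools:
            iv = ec.fva(ec.constrain(branched_model, P_met=float(pool)))
            if prev is not None:
                assert (iv["minimum"] >= prev["minimum"] - 1e-8).all()
                assert (iv["maximum"] <= prev["maximum"] + 1e-8).all()
            prev = iv


class TestSampling:
    def test_point_solution_space(self, linear_model):
        m = ec.constrain(linear_model, P_met=1.0)
        sol = ec.sample_optimal(m, n_samples=20, seed=9)
        np.testing.assert_allclose(
            sol.fluxes, linear_model.reference_flux[m.reactions], atol=1e-6)

    def test_deterministic_under_seed(self, constrained_branched):
        a = ec.sample_optimal(constrained_branched, n_samples=40, seed=5)
        b = ec.sample_optimal(constrained_branched, n_samples=40, seed=5)
        pd.testing.assert_series_equal(a.fluxes, b.fluxes)

    def test_modal_flux_within_fva_bounds(self, constrained_branched):
        iv = ec.fva(constrained_branched)
        sol = ec.sample_optimal(constrained_branched, n_samples=60, seed=2)
        assert (sol.fluxes >= iv["minimum"] - 1e-8).all()
        assert (sol.fluxes <= iv["maximum"] + 1e-8).all()

    def test_pool_minimum_lower_bounds_samples(self, constrained_branched):
        p_min, _ = ec.minimize_enzyme_pool(constrained_branched)
        sol = ec.sample_optimal(constrained_branched, n_samples=60, seed=2)
        assert (sol.sample_pools >= p_min - 1e-8).all()

    def test_independent_pair_mode_runs(self, constrained_branched):
        sol = ec.sample_optimal(constrained_branched, n_samples=20, seed=1,
                                pair_mode="independent")
        assert sol.status == "optimal"


class TestPathwayUsage:
    def test_full_usage(self):
        sol = ec.FluxSolution(
            fluxes=pd.Series(dtype=float),
            enzyme_usage=pd.Series({f"e{i}": 1.0 for i in range(5)}),
            pool_used=5.0, objective_value=5.0, status="optimal")
        measured = pd.Series({f"e{i}": 1.0 for i in range(5)})
        out = ec.pathway_usage(sol, measured, {"pw": [f"e{i}" for i in range(5)]})
        assert out.loc["pw", "usage"] == pytest.approx(1.0)
        assert out.loc["pw", "reserve"] == pytest.approx(0.0)

    def test_small_pathways_excluded(self):
        sol = ec.FluxSolution(
            fluxes=pd.Series(dtype=float),
            enzyme_usage=pd.Series({"e0": 1.0, "e1": 1.0}),
            pool_used=2.0, objective_value=2.0, status="optimal")
        measured = pd.Series({"e0": 2.0, "e1": 2.0})
        out = ec.pathway_usage(sol, measured, {"tiny": ["e0", "e1"]}, min_genes=5)
        assert len(out) == 0

    def test_fermentation_benchmark(self):
        """Glucose flux 2.4 -> 6.0 with enzymes halved: fivefold usage rise,
        20% usage in the reference condition."""
        res = ec.pathway_usage_fold(
            flux_ref=2.4, enzyme_ref=1.0, flux_alt=6.0, enzyme_alt=0.5)
        assert res.flux_fold == pytest.approx(2.5, abs=1e-12)
        assert res.usage_fold == pytest.approx(5.0, abs=1e-12)
        assert res.reference_usage == pytest.approx(0.20, abs=1e-12)
        assert res.reference_reserve == pytest.approx(0.80, abs=1e-12)


class TestModelIO:
    def test_tsv_roundtrip(self, branched_model, tmp_path):
        from reservecalc import io as mio

        mio.write_model_tsv(branched_model, tmp_path)
        back = mio.read_model_tsv(tmp_path)
        pd.testing.assert_frame_equal(
            back.S.loc[branched_model.metabolites, branched_model.reactions],
            branched_model.S)
        assert back.enzymes["E_ferm"].links == branched_model.enzymes["E_ferm"].links
        p1, _ = ec.minimize_enzyme_pool(branched_model)
        p2, _ = ec.minimize_enzyme_pool(back)
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_sbml_roundtrip(self, branched_model, tmp_path):
        from reservecalc import io as mio

        sbml = tmp_path / "model.xml"
        enz = tmp_path / "enzymes.tsv"
        mio.write_model_sbml(branched_model, sbml, enz)
        back = mio.read_model_sbml(sbml, enz)
        assert set(back.reactions) == set(branched_model.reactions)
        p1, _ = ec.minimize_enzyme_pool(branched_model)
        p2, _ = ec.minimize_enzyme_pool(back)
        assert p2 == pytest.approx(p1, rel=1e-9)
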