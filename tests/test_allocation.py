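"""Molar allocation, sliding-window Fisher enrichment (against an exact
hypergeometric oracle), fold comparison, regression and isozyme analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reservecalc import allocation as al
from reservecalc import synthetic as sy

from oracles import fisher_two_sided_exact


def _matrix(values: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(values)


class TestComputeAllocation:
    def test_all_genes_single_term_is_100(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(20, 2)), columns=["a", "b"],
                         index=[f"g{i}" for i in range(20)])
        out = al.compute_allocation(m, {"all": set(m.index)})
        np.testing.assert_allclose(out.loc["all"], [100.0, 100.0], rtol=1e-12)

    def test_disjoint_halves(self):
        m = pd.DataFrame({"c": [1.0, 1.0, 2.0, 0.0]}, index=list("wxyz"))
        out = al.compute_allocation(m, {"t1": {"w", "x"}, "t2": {"y", "z"}})
        assert out.loc["t1", "c"] == pytest.approx(50.0)
        assert out.loc["t2", "c"] == pytest.approx(50.0)

    def test_partition_sums_to_100(self, clean_dataset):
        ann = dict(clean_dataset.annotations)
        assigned = set().union(*ann.values())
        ann["rest"] = set(clean_dataset.proteome.genes) - assigned
        out = al.compute_allocation(clean_dataset.proteome, ann)
        np.testing.assert_allclose(out.sum(axis=0), 100.0, rtol=1e-9)

    def test_truth_allocation_recovered_exactly(self, clean_dataset):
        out = al.compute_allocation(clean_dataset.proteome, clean_dataset.annotations)
        assert out.loc["translation", "Clim"] == pytest.approx(12.0, rel=1e-9)
        truth = clean_dataset.truth["allocation"]
        for term in out.index:
            np.testing.assert_allclose(
                out.loc[term], 100 * truth.loc[term].astype(float), rtol=1e-9)

    def test_gene_count_normalization(self):
        m = pd.DataFrame({"c": [3.0, 3.0, 4.0]}, index=list("abc"))
        out = al.compute_allocation(m, {"t": {"a", "b"}}, normalize_gene_count=True)
        assert out.loc["t", "c"] == pytest.approx(30.0)  # 60% / 2 genes

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            al.compute_allocation(pd.DataFrame({"c": [0.0]}), {"t": {"0"}})


class TestSlidingWindow:
    def test_top_window_matches_hypergeometric_oracle(self, rng):
        """All 30 term genes in the top 200 ranks of 3000 genes."""
        n, k, window = 3000, 30, 200
        genes = [f"g{i}" for i in range(n)]
        abundance = pd.Series(np.sort(rng.lognormal(size=n))[::-1], index=genes)
        term = set(genes[:k])  # all term genes in the top window
        res = al.sliding_window_enrichment(abundance, {"t": term},
                                           window=window, step=200)
        top = res[res["window_start_rank"] == 1].iloc[0]
        oracle = fisher_two_sided_exact(k, window - k, 0, n - window)
        assert top["p_fisher"] == pytest.approx(oracle, abs=1e-10)
        assert top["odds_direction"] == "over"

    def test_all_tested_tables_match_oracle(self, rng):
        n = 400
        genes = [f"g{i}" for i in range(n)]
        abundance = pd.Series(rng.lognormal(size=n), index=genes)
        ann = {f"t{j}": set(rng.choice(genes, size=40, replace=False)) for j in range(3)}
        res = al.sliding_window_enrichment(abundance, ann, window=100, step=50)
        k_tot = {t: len(g) for t, g in ann.items()}
        for _, row in res.iterrows():
            a = int(row["in_window"])
            b = 100 - a
            c = k_tot[row["term"]] - a
            d = (n - 100) - c
            assert row["p_fisher"] == pytest.approx(
                fisher_two_sided_exact(a, b, c, d), abs=1e-10)

    def test_null_type_one_error_controlled(self, rng):
        """Uniformly interleaved term genes: family-wise FDR discoveries
        occur in at most 0.05 + 2*MC-error of 500 null replicates."""
        n, window, step = 600, 200, 100
        genes = np.array([f"g{i}" for i in range(n)])
        ann_sizes = [30, 60, 90]
        hits = 0
        reps = 500
        for _ in range(reps):
            perm = rng.permutation(n)
            abundance = pd.Series(np.arange(n, 0, -1, dtype=float)[perm], index=genes)
            ann = {}
            offset = 0
            for j, size in enumerate(ann_sizes):
                ann[f"t{j}"] = set(rng.choice(genes, size=size, replace=False))
            res = al.sliding_window_enrichment(abundance, ann, window=window, step=step)
            hits += int(res["significant"].any())
        mc = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 2 * mc

    def test_empty_term_skipped(self, rng, caplog):
        abundance = pd.Series(rng.lognormal(size=50), index=[f"g{i}" for i in range(50)])
        res = al.sliding_window_enrichment(abundance, {"none": {"zz"}}, window=20, step=10)
        assert len(res) == 0

    def test_degenerate_window_rejected(self, rng):
        abundance = pd.Series(rng.lognormal(size=50))
        with pytest.raises(ValueError):
            al.sliding_window_enrichment(abundance, {"t": {0}}, window=5)


class TestCompareAllocation:
    def test_identical_tables_no_outliers(self):
        a = pd.Series({"t1": 10.0, "t2": 5.0})
        out = al.compare_allocation(a, a)
        assert not out["outlier"].any()
        np.testing.assert_allclose(out["log2_fold"], 0.0)

    def test_single_fourfold_outlier(self):
        a = pd.Series({"t1": 10.0, "t2": 5.0, "t3": 1.0})
        b = pd.Series({"t1": 10.0, "t2": 20.0, "t3": 1.0})
        out = al.compare_allocation(a, b)
        assert out["outlier"].sum() == 1
        assert out.loc["t2", "outlier"]

    def test_97_of_99_processes_within_band(self):
        """Constructed 99-process profile with 2 shifted terms."""
        profile = {f"p{i:02d}": 0.008 for i in range(97)}
        profile["p97"] = [0.008, 0.012, 0.02, 0.033]  # rises ~4x
        profile["p98"] = [0.033, 0.02, 0.012, 0.008]  # falls ~4x
        ds = sy.generate_chemostat_omics(sy.SynthConfig(
            n_genes=3000, noise_cv=0.0, seed=2, allocation_profile=profile))
        alloc = al.compute_allocation(ds.proteome, ds.annotations)
        out = al.compare_allocation(alloc.iloc[:, 0], alloc.iloc[:, -1])
        assert len(out) == 99
        assert (~out["outlier"]).sum() == 97
        assert out["outlier"].sum() == 2

    def test_zero_allocation_censored_not_infinite(self):
        a = pd.Series({"t1": 1.0, "t2": 0.0})
        out = al.compare_allocation(a, pd.Series({"t1": 2.0, "t2": 3.0}))
        assert out.loc["t2", "censored"]
        assert not out.loc["t2", "outlier"]
        assert np.isfinite(out["log2_fold"].dropna()).all()

    @given(st.lists(st.floats(0.1, 50), min_size=3, max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry(self, vals):
        a = pd.Series(vals, index=[f"t{i}" for i in range(len(vals))])
        b = a.iloc[::-1].set_axis(a.index)
        ab = al.compare_allocation(a, b)["log2_fold"]
        ba = al.compare_allocation(b, a)["log2_fold"]
        np.testing.assert_allclose(ab, -ba, atol=1e-12)


class TestAllocationRegression:
    def test_identity(self):
        a = pd.Series({"t1": 1.0, "t2": 5.0, "t3": 20.0})
        slope, r = al.allocation_regression(a, a)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_power_law_amplification(self):
        t = pd.Series({"t1": 0.5, "t2": 2.0, "t3": 8.0, "t4": 30.0})
        p = 0.7 * t**1.5
        slope, r = al.allocation_regression(t, p)
        assert slope == pytest.approx(1.5, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_sign(self):
        t = pd.Series({"t1": 1.0, "t2": 4.0, "t3": 16.0})
        p = pd.Series({"t1": 16.0, "t2": 4.0, "t3": 1.0})
        _, r = al.allocation_regression(t, p)
        assert r < 0


class TestIsozymes:
    def _matrix(self):
        # minor isozyme rises 3.6x but stays <1% of the pair; a second
        # reaction switches majority 60/40 -> 40/60
        idx = ["gdh1", "gdh3", "r2a", "r2b", "bg"]
        return pd.DataFrame(
            {"Clim": [99.0, 0.25, 60.0, 40.0, 800.0],
             "Nlim": [99.0, 0.90, 40.0, 60.0, 800.0]}, index=idx)

    def test_differential_without_switching(self):
        genes, rxns = al.isozyme_analysis(
            self._matrix(), {"GDH": ["gdh1", "gdh3"]})
        minor = genes.set_index("gene").loc["gdh3"]
        assert minor["differential"]
        assert minor["share_b"] < 0.01
        assert not rxns.loc["GDH", "switching"]

    def test_switching_on_majority_change(self):
        _, rxns = al.isozyme_analysis(self._matrix(), {"R2": ["r2a", "r2b"]})
        assert rxns.loc["R2", "switching"]

    def test_identical_conditions_no_flags(self):
        m = self._matrix()
        m["Nlim"] = m["Clim"]
        genes, rxns = al.isozyme_analysis(
            m, {"GDH": ["gdh1", "gdh3"], "R2": ["r2a", "r2b"]})
        assert not genes["differential"].any()
        assert not rxns["switching"].any()

    def test_small_set_rejected(self):
        with pytest.raises(ValueError):
            al.isozyme_analysis(self._matrix(), {"solo": ["gdh1"]})


def test_read_gene_sets_dialects(tmp_path):
    generic = tmp_path / "sets.tsv"
    generic.write_text("g1\ttermA\ng2\ttermA\ng3\ttermB\n")
    sets = al.read_gene_sets(generic)
    assert sets == {"termA": {"g1", "g2"}, "termB": {"g3"}}

    sgd = tmp_path / "go_slim_mapping.tab"
    sgd.write_text(
        "YAL001C\tTFC3\tS000000001\tP\ttranscription\tGO:0006351\tORF\n"
        "YAL002W\tVPS8\tS000000002\tP\ttransport\tGO:0006810\tORF\n"
        "YAL003W\tEFB1\tS000000003\tP\ttranslation\tGO:0006412\tORF\n")
    sets = al.read_gene_sets(sgd)
    assert sets["translation"] == {"YAL003W"}
    assert sets["transport"] == {"YAL002W"}
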