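"""Categorical investment, yield weighting, top genes and over-representation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import atlasdecon as ad
from oracles import hypergeom_tail, hypergeom_tail_enumerated


def _profiles(table, genes):
    return {
        name: ad.ConditionProfile(
            values=pd.Series(vals, index=genes, dtype=float), compartment=name
        )
        for name, vals in table.items()
    }


class TestCumulativeInvestment:
    def test_full_universe_category_sums_to_a_million(self, noiseless_profiles):
        profiles, _, _ = noiseless_profiles
        one = next(iter(profiles.values()))
        cmap = ad.CategoryMap({"everything": set(one.values.index)})
        inv = ad.cumulative_investment(profiles, cmap)
        assert np.allclose(inv.table["everything"], 1e6, rtol=1e-9)

    def test_toy_sums_match_hand_computation(self):
        genes = ["g1", "g2", "g3"]
        profiles = _profiles(
            {"r1": [10.0, 20.0, 30.0], "r2": [5.0, 5.0, 40.0]}, genes
        )
        cmap = ad.CategoryMap({"ab": {"g1", "g2"}, "c": {"g3"}})
        inv = ad.cumulative_investment(profiles, cmap)
        assert inv.table.loc["r1", "ab"] == 30.0
        assert inv.table.loc["r2", "ab"] == 10.0
        assert inv.table.loc["r1", "c"] == 30.0
        assert inv.table.loc["r2", "c"] == 40.0

    def test_missing_category_genes_counted_as_zero_and_reported(self):
        genes = ["g1"]
        profiles = _profiles({"r1": [10.0]}, genes)
        cmap = ad.CategoryMap({"cat": {"g1", "ghost"}})
        inv = ad.cumulative_investment(profiles, cmap)
        assert inv.table.loc["r1", "cat"] == 10.0
        assert inv.missing_genes == {"cat": ["ghost"]}

    def test_percent_of_max_marks_top_region_100(self):
        genes = ["g1"]
        profiles = _profiles({"r1": [20.0], "r2": [40.0], "r3": [10.0]}, genes)
        inv = ad.cumulative_investment(profiles, ad.CategoryMap({"cat": {"g1"}}))
        scaled, zero = inv.percent_of_max()
        assert zero == []
        assert np.allclose(scaled["cat"], [50.0, 100.0, 25.0])


class TestScaleToMax:
    def test_closed_form(self):
        scaled, flag = ad.scale_to_max(pd.Series([20.0, 40.0, 10.0]))
        assert np.allclose(scaled, [50.0, 100.0, 25.0])
        assert flag is None

    def test_all_zero_flagged(self):
        scaled, flag = ad.scale_to_max(pd.Series([0.0, 0.0, 0.0]))
        assert (scaled == 0).all()
        assert flag == "all_zero"

    def test_sub_tpm_rows_suppressed(self):
        scaled, flag = ad.scale_to_max(pd.Series([0.4, 0.9, 0.1]))
        assert (scaled == 0).all()
        assert flag == "low_expression"

    def test_idempotent_and_scale_invariant(self):
        values = pd.Series([3.0, 9.0, 6.0])
        once, _ = ad.scale_to_max(values)
        twice, _ = ad.scale_to_max(once)
        tenfold, _ = ad.scale_to_max(values * 10)
        assert np.allclose(once, twice)
        assert np.allclose(once, tenfold)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ad.scale_to_max(pd.Series([-1.0, 2.0]))


class TestYieldAndOutput:
    def test_yield_arithmetic(self):
        yt = ad.rna_yield([ad.YieldMeasurement("gut", 12.0, 30.0, 20, 1)])
        assert yt.mean_ng["gut"] == 18.0  # 12 ng/µl × 30 µl / 20 organs

    def test_yield_replicates_averaged_and_volume_linear(self):
        yt = ad.rna_yield(
            [
                ad.YieldMeasurement("gut", 10.0, 10.0, 10, 1),
                ad.YieldMeasurement("gut", 20.0, 10.0, 10, 2),
            ]
        )
        assert yt.mean_ng["gut"] == 15.0
        doubled = ad.rna_yield([ad.YieldMeasurement("gut", 10.0, 20.0, 10, 1)])
        assert doubled.mean_ng["gut"] == 2 * 10.0 * 10.0 / 10

    def test_equal_yields_preserve_investment_shares(self):
        inv = ad.InvestmentTable(
            pd.DataFrame({"cat": [100.0, 300.0]}, index=["r1", "r2"])
        )
        yt = ad.YieldTable(
            mean_ng=pd.Series({"r1": 2.0, "r2": 2.0}), replicates=pd.DataFrame()
        )
        out = ad.weight_by_yield(inv, yt)
        assert np.allclose(out.shares["cat"], [25.0, 75.0])

    def test_unequal_yields_shift_shares(self):
        inv = ad.InvestmentTable(
            pd.DataFrame({"cat": [100.0, 100.0]}, index=["r1", "r2"])
        )
        yt = ad.YieldTable(
            mean_ng=pd.Series({"r1": 1.0, "r2": 3.0}), replicates=pd.DataFrame()
        )
        out = ad.weight_by_yield(inv, yt)
        assert np.allclose(out.shares["cat"], [25.0, 75.0])

    def test_toy_output_matches_hand_computation(self):
        inv = ad.InvestmentTable(
            pd.DataFrame(
                {"pep": [100.0, 50.0, 10.0], "lip": [5.0, 20.0, 40.0]},
                index=["pv", "am", "pm"],
            )
        )
        yt = ad.YieldTable(
            mean_ng=pd.Series({"pv": 2.0, "am": 4.0, "pm": 10.0}),
            replicates=pd.DataFrame(),
        )
        out = ad.weight_by_yield(inv, yt)
        pep = np.array([200.0, 200.0, 100.0])
        assert np.allclose(out.output["pep"], pep)
        assert np.allclose(out.shares["pep"], pep / pep.sum() * 100)
        assert np.allclose(out.shares.sum(axis=0), 100.0)

    def test_missing_yield_names_compartment(self):
        inv = ad.InvestmentTable(pd.DataFrame({"cat": [1.0]}, index=["gut"]))
        yt = ad.YieldTable(
            mean_ng=pd.Series({"head": 1.0}), replicates=pd.DataFrame()
        )
        with pytest.raises(ValueError, match="gut"):
            ad.weight_by_yield(inv, yt)


class TestTopExpressed:
    def _profile(self, values, genes):
        return ad.ConditionProfile(
            values=pd.Series(values, index=genes, dtype=float), compartment="gut"
        )

    def test_n_larger_than_gene_count_returns_all(self):
        prof = self._profile([5e5, 3e5, 2e5], ["g1", "g2", "g3"])
        top = ad.top_expressed(prof, n=10)
        assert list(top["gene_id"]) == ["g1", "g2", "g3"]
        assert np.isclose(top["cumulative_percent"].iloc[-1], 100.0)

    def test_ties_break_lexicographically(self):
        prof = self._profile([10.0, 10.0, 999_980.0], ["gb", "ga", "gz"])
        top = ad.top_expressed(prof, n=3)
        assert list(top["gene_id"]) == ["gz", "ga", "gb"]

    def test_categories_annotated(self):
        prof = self._profile([6e5, 4e5], ["g1", "g2"])
        cmap = ad.CategoryMap({"pep": {"g1"}, "lip": {"g1"}})
        top = ad.top_expressed(prof, n=2, category_map=cmap)
        assert top.loc[0, "category"] == "lip;pep"
        assert top.loc[1, "category"] == ""


class TestCategoryEnrichment:
    def test_matches_closed_form_and_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        category = set(universe[:6])
        selected = set(universe[2:10])  # overlap with category = 4
        cmap = ad.CategoryMap({"cat": category})
        result = ad.category_enrichment(selected, set(universe), cmap)
        overlap = int(result.loc[0, "overlap"])
        expected = hypergeom_tail(overlap, 20, 6, 8)
        assert np.isclose(result.loc[0, "p"], expected, rtol=1e-12)
        enumerated = hypergeom_tail_enumerated(overlap, universe, category, 8)
        assert np.isclose(expected, enumerated, rtol=1e-12)

    def test_zero_overlap_is_never_flagged(self):
        universe = {f"g{i}" for i in range(30)}
        cmap = ad.CategoryMap({"cat": {f"g{i}" for i in range(10)}})
        selected = {f"g{i}" for i in range(10, 25)}
        result = ad.category_enrichment(selected, universe, cmap)
        assert result.loc[0, "overlap"] == 0
        assert result.loc[0, "p"] >= 0.5

    def test_selecting_whole_universe_is_degenerate(self):
        universe = {f"g{i}" for i in range(12)}
        cmap = ad.CategoryMap({"cat": {f"g{i}" for i in range(5)}})
        result = ad.category_enrichment(universe, universe, cmap)
        assert result.loc[0, "overlap"] == 5
        assert result.loc[0, "p"] == 1.0

    def test_selection_outside_universe_rejected(self):
        cmap = ad.CategoryMap({"cat": {"g1"}})
        with pytest.raises(ValueError, match="ghost"):
            ad.category_enrichment({"ghost"}, {"g1"}, cmap)

    def test_matches_monte_carlo_within_three_standard_errors(self):
        rng = np.random.default_rng(42)
        n_draw, n_sel, overlap_min = 100_000, 15, 6
        # vectorized draws without replacement: random ranks over 40 genes,
        # the first 12 indices are the category
        picks = rng.random((n_draw, 40)).argsort(axis=1)[:, :n_sel]
        mc = ((picks < 12).sum(axis=1) >= overlap_min).mean()
        p = float(stats.hypergeom.sf(overlap_min - 1, 40, 12, n_sel))
        se = np.sqrt(p * (1 - p) / n_draw)
        assert abs(p - mc) < 3 * se
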