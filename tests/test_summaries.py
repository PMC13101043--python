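"""Descriptive statistics and gap analysis against hand-computed values."""

import numpy as np
import pandas as pd
import pytest

import n2kgap as g


def _classified(rows):
    """rows: (site_code, habitat_code, cover_ha, habitat_class, group, nutrient, region)"""
    return pd.DataFrame(
        rows,
        columns=[
            "site_code",
            "habitat_code",
            "cover_ha",
            "habitat_class",
            "freshwater_group",
            "nutrient",
            "region",
        ],
    )


class TestClassCoverage:
    def test_single_fully_covered_freshwater_site(self):
        sites = pd.DataFrame(
            {"site_code": ["S1"], "site_type": ["HD_ONLY"], "total_area_ha": [100.0]}
        )
        entries = _classified(
            [("S1", "3150", 100.0, "FRESHWATER", "STANDING", "EUTROPHIC", "")]
        )
        cov = g.class_coverage(sites, entries)
        assert cov.mapped_percent == 100.0
        assert cov.unmapped_percent == 0.0
        assert cov.class_percent["FRESHWATER"] == 100.0

    def test_two_sites_partial_terrestrial_cover(self):
        # two 100-ha sites, one 30-ha terrestrial habitat -> mapped 15%
        sites = pd.DataFrame(
            {
                "site_code": ["S1", "S2"],
                "site_type": ["HD_ONLY", "HD_ONLY"],
                "total_area_ha": [100.0, 100.0],
            }
        )
        entries = _classified([("S1", "9110", 30.0, "TERRESTRIAL", "", "", "")])
        cov = g.class_coverage(sites, entries)
        assert cov.mapped_percent == 15.0
        assert cov.class_percent["TERRESTRIAL"] == 15.0
        assert cov.class_percent["FRESHWATER"] == 0.0

    def test_zero_total_area_is_an_error(self):
        sites = pd.DataFrame(
            {"site_code": ["S1"], "site_type": ["HD_ONLY"], "total_area_ha": [0.0]}
        )
        with pytest.raises(ValueError):
            g.class_coverage(sites, _classified([]))

    def test_bd_only_area_enters_network_denominator_only(self):
        sites = pd.DataFrame(
            {"site_code": ["S1"], "site_type": ["HD_ONLY"], "total_area_ha": [100.0]}
        )
        entries = _classified(
            [("S1", "3150", 50.0, "FRESHWATER", "STANDING", "EUTROPHIC", "")]
        )
        cov = g.class_coverage(sites, entries, dropped_bd_only_area_ha=100.0)
        assert cov.class_percent["FRESHWATER"] == 50.0  # of HD area
        assert cov.freshwater_percent_of_network == 25.0  # of HD + BD-only area


class TestGroupShares:
    def test_equal_areas_give_equal_shares(self):
        rows = [
            ("S1", "3260", 10.0, "FRESHWATER", "RUNNING", "MESOTROPHIC", ""),
            ("S1", "3150", 10.0, "FRESHWATER", "STANDING", "EUTROPHIC", ""),
            ("S1", "7110", 10.0, "FRESHWATER", "PEATLAND", "OLIGOTROPHIC", ""),
            ("S1", "91E0", 10.0, "FRESHWATER", "FOREST", "EUTROPHIC", ""),
            ("S1", "6430", 10.0, "FRESHWATER", "GRASS_HEATH_COASTAL", "EUTROPHIC", ""),
        ]
        shares = g.group_shares(_classified(rows))
        assert np.allclose(shares["percent_of_freshwater_area"], 20.0)

    def test_planted_shares(self):
        rows = [
            ("S1", "3260", 50.0, "FRESHWATER", "RUNNING", "MESOTROPHIC", ""),
            ("S1", "3150", 30.0, "FRESHWATER", "STANDING", "EUTROPHIC", ""),
            ("S1", "7110", 20.0, "FRESHWATER", "PEATLAND", "OLIGOTROPHIC", ""),
        ]
        shares = g.group_shares(_classified(rows)).set_index("freshwater_group")
        got = shares["percent_of_freshwater_area"]
        assert got["RUNNING"] == 50.0 and got["STANDING"] == 30.0
        assert got["PEATLAND"] == 20.0 and got["FOREST"] == 0.0

    def test_shares_sum_to_100(self, worked_bundle):
        total = worked_bundle.group_shares["percent_of_freshwater_area"].sum()
        assert abs(total - 100.0) < 0.1


class TestNutrientSummary:
    def test_single_site_single_habitat(self):
        rows = [("S1", "3150", 5.0, "FRESHWATER", "STANDING", "EUTROPHIC", "")]
        out = g.nutrient_summary(_classified(rows)).set_index("nutrient")
        assert out.loc["EUTROPHIC", "n_sites"] == 1
        assert out.loc["OLIGOTROPHIC", "n_sites"] == 0

    def test_site_with_two_nutrient_classes_counts_in_both(self):
        rows = [
            ("S1", "3110", 5.0, "FRESHWATER", "STANDING", "OLIGOTROPHIC", ""),
            ("S1", "3150", 5.0, "FRESHWATER", "STANDING", "EUTROPHIC", ""),
        ]
        out = g.nutrient_summary(_classified(rows)).set_index("nutrient")
        assert out.loc["EUTROPHIC", "n_sites"] == 1
        assert out.loc["OLIGOTROPHIC", "n_sites"] == 1


class TestSizeDistribution:
    def test_boundary_convention_half_open(self):
        # 49.99 -> [0,50); 50 -> [50,500); 500 -> >=500
        out = g.size_distribution(pd.Series([49.99, 50.0, 500.0]))
        assert list(out["n_sites"]) == [1, 1, 1]

    def test_planted_counts(self):
        areas = pd.Series([1, 10, 49, 60, 70, 499, 500, 600, 5000, 10000], dtype=float)
        out = g.size_distribution(areas)
        assert list(out["n_sites"]) == [3, 3, 4]
        assert out["n_sites"].sum() == len(areas)
        assert abs(out["percent"].sum() - 100.0) < 1e-9


class TestHabitatStats:
    def test_single_habitat_three_sites(self):
        rows = [
            (f"S{i}", "3260", 10.0, "FRESHWATER", "RUNNING", "MESOTROPHIC", "")
            for i in range(3)
        ]
        stats = g.habitat_stats(_classified(rows))
        assert len(stats) == 1
        row = stats.iloc[0]
        assert row["total_area_ha"] == 30.0
        assert row["percent_of_freshwater_area"] == 100.0
        assert row["n_sites"] == 3

    def test_removing_one_code_leaves_other_areas_unchanged(self):
        rows = [
            ("S1", "3260", 10.0, "FRESHWATER", "RUNNING", "MESOTROPHIC", ""),
            ("S2", "7310", 40.0, "FRESHWATER", "PEATLAND", "OLIGOTROPHIC", ""),
        ]
        full = g.habitat_stats(_classified(rows)).set_index("habitat_code")
        reduced = g.habitat_stats(_classified(rows[1:])).set_index("habitat_code")
        assert len(full) - len(reduced) == 1
        # area invariance (percent does change)
        assert reduced.loc["7310", "total_area_ha"] == full.loc["7310", "total_area_ha"]
        assert reduced.loc["7310", "percent_of_freshwater_area"] != pytest.approx(
            full.loc["7310", "percent_of_freshwater_area"]
        )

    def test_permutation_invariance(self):
        res = g.generate(g.SynthConfig(n_sites=80, seed=11))
        ds = g.curate(res.sites, res.habitats)
        entries, _ = g.attach_classifications(ds.entries, g.load_taxonomy())
        entries["region"] = ""
        a = g.habitat_stats(entries)
        b = g.habitat_stats(entries.sample(frac=1, random_state=1).reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)


class TestSitesWithFreshwater:
    def test_no_freshwater_entries(self):
        n, per_site, share = g.sites_with_freshwater(
            _classified([("S1", "9110", 1.0, "TERRESTRIAL", "", "", "")])
        )
        assert n == 0 and per_site.empty

    def test_counts_and_1_to_4_share(self):
        rows = [("S1", c, 1.0, "FRESHWATER", "STANDING", "EUTROPHIC", "")
                for c in ["3110", "3120", "3130", "3140", "3150"]]
        rows += [("S2", "3150", 1.0, "FRESHWATER", "STANDING", "EUTROPHIC", "")]
        n, per_site, share = g.sites_with_freshwater(_classified(rows))
        assert n == 2
        assert per_site["S1"] == 5 and per_site["S2"] == 1
        assert share == 50.0  # only S2 hosts one-to-four types


class TestGapAnalysis:
    def test_full_representation(self):
        rows = [
            ("S1", "3150", 1.0, "FRESHWATER", "STANDING", "EUTROPHIC", "Alpine"),
            ("S2", "3150", 1.0, "FRESHWATER", "STANDING", "EUTROPHIC", "Boreal"),
            ("S3", "3150", 1.0, "FRESHWATER", "STANDING", "EUTROPHIC", "Atlantic"),
        ]
        natural = {"3150": frozenset({"Alpine", "Boreal", "Atlantic"})}
        gap, tally, excluded = g.gap_analysis(_classified(rows), natural)
        row = gap.iloc[0]
        assert row["proportion"] == 1.0 and bool(row["fully_represented"])
        assert excluded == []

    def test_half_representation(self):
        rows = [
            ("S1", "7110", 1.0, "FRESHWATER", "PEATLAND", "OLIGOTROPHIC", "Alpine"),
            ("S2", "7110", 1.0, "FRESHWATER", "PEATLAND", "OLIGOTROPHIC", "Boreal"),
        ]
        natural = {"7110": frozenset({"Alpine", "Boreal", "Atlantic", "Continental"})}
        gap, _, _ = g.gap_analysis(_classified(rows), natural)
        assert gap.iloc[0]["proportion"] == 0.5
        assert not gap.iloc[0]["fully_represented"]

    def test_na_entries_excluded_from_observed(self):
        rows = [
            ("S1", "7310", 1.0, "FRESHWATER", "PEATLAND", "OLIGOTROPHIC", ""),
        ]
        natural = {"7310": frozenset({"Boreal"})}
        gap, _, _ = g.gap_analysis(_classified(rows), natural)
        assert gap.iloc[0]["proportion"] == 0.0
        assert gap.iloc[0]["observed_regions"] == ""

    def test_code_without_natural_range_is_excluded_and_reported(self):
        rows = [("S1", "3150", 1.0, "FRESHWATER", "STANDING", "EUTROPHIC", "Alpine")]
        gap, tally, excluded = g.gap_analysis(_classified(rows), {})
        assert gap.empty and excluded == ["3150"]

    @pytest.mark.parametrize("seed", range(5))
    def test_proportion_bounds_and_subset_iff_full(self, seed):
        res = g.generate(g.SynthConfig(n_sites=200, seed=seed))
        bundle = g.run_pipeline(sites=res.sites, habitats=res.habitats,
                                bioregions=res.bioregions)
        gap = bundle.gap
        assert ((gap["proportion"] >= 0) & (gap["proportion"] <= 1)).all()
        for row in gap.itertuples():
            assert row.fully_represented == (row.proportion == 1.0)


class TestWorkedFixtureSummaries:
    """Every summary reproduces the fixture's hand-computed expectations."""

    def test_coverage(self, worked, worked_bundle):
        exp = worked["expected"]
        cov = worked_bundle.coverage
        assert cov.total_hd_area_ha == exp["total_hd_area_ha"]
        assert cov.network_area_ha == exp["network_area_ha"]
        assert cov.mapped_percent == pytest.approx(exp["mapped_percent"])
        assert cov.unmapped_percent == pytest.approx(exp["unmapped_percent"])
        for cls, pct in exp["class_percent"].items():
            assert cov.class_percent[cls] == pytest.approx(pct)
        assert cov.freshwater_percent_of_network == pytest.approx(
            exp["freshwater_percent_of_network"]
        )
        assert cov.mapped_percent + cov.unmapped_percent == pytest.approx(100.0)

    def test_group_shares(self, worked, worked_bundle):
        exp = worked["expected"]
        shares = worked_bundle.group_shares.set_index("freshwater_group")
        for group, area in exp["group_area_ha"].items():
            assert shares.loc[group, "area_ha"] == area
        for group, pct in exp["group_percent"].items():
            assert shares.loc[group, "percent_of_freshwater_area"] == pytest.approx(pct)

    def test_nutrients(self, worked, worked_bundle):
        exp = worked["expected"]
        nut = worked_bundle.nutrient.set_index("nutrient")
        for level, area in exp["nutrient_area_ha"].items():
            assert nut.loc[level, "area_ha"] == area
        for level, n in exp["nutrient_sites"].items():
            assert nut.loc[level, "n_sites"] == n

    def test_size_classes(self, worked, worked_bundle):
        exp = worked["expected"]
        sizes = worked_bundle.size_classes["ALL"].set_index("size_class")
        for cls, n in exp["size_counts"].items():
            assert sizes.loc[cls, "n_sites"] == n

    def test_freshwater_site_counts(self, worked, worked_bundle):
        exp = worked["expected"]
        assert worked_bundle.n_sites_with_freshwater == exp["sites_with_freshwater"]
        assert worked_bundle.share_sites_1_to_4_types == exp["share_sites_1_to_4_types"]

    def test_gap_proportions(self, worked, worked_bundle):
        exp = worked["expected"]
        gap = worked_bundle.gap.set_index("habitat_code")
        for code, prop in exp["gap_proportion"].items():
            assert gap.loc[code, "proportion"] == pytest.approx(prop), code
        for code, full in exp["fully_represented"].items():
            assert bool(gap.loc[code, "fully_represented"]) is full
        assert gap["proportion"].mean() == pytest.approx(exp["mean_gap_proportion"])
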