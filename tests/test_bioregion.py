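"""Region corrections and per-site assignment rules."""

import pandas as pd
import pytest

import n2kgap as g
from conftest import canonical_bioregions


def _bio(*rows):
    return canonical_bioregions(list(rows))


class TestCorrectZeroPercents:
    def test_sole_region_zero_corrected_to_100(self):
        df, n, log = g.correct_zero_percents(_bio(("BE2200037", "Atlantic", 0.0)))
        assert n == 1
        assert df.loc[0, "percent_of_site"] == 100.0
        assert log.loc[0, "rule"] == "CORRECTED_0_TO_100"

    def test_multi_region_zero_left_untouched(self):
        df, n, _ = g.correct_zero_percents(
            _bio(("S1", "Alpine", 0.0), ("S1", "Continental", 60.0))
        )
        assert n == 0
        assert df.loc[0, "percent_of_site"] == 0.0  # ambiguous, not sole-region

    def test_override_takes_precedence(self):
        overrides = pd.DataFrame(
            {"site_code": ["BE2200036"], "region": ["Atlantic"], "percent": [79.0]}
        )
        df, n, log = g.correct_zero_percents(
            _bio(("BE2200036", "Atlantic", 0.0)), overrides
        )
        assert n == 1
        assert df.loc[0, "percent_of_site"] == 79.0
        assert log.loc[0, "rule"] == "OVERRIDE"

    def test_shipped_overrides_contain_the_known_case(self):
        overrides = g.load_overrides()
        row = overrides[overrides["site_code"] == "BE2200036"]
        assert row.iloc[0]["region"] == "Atlantic"
        assert row.iloc[0]["percent"] == 79.0


class TestAssignRegion:
    def test_ge70_rule(self):
        a = g.assign_region(_bio(("S1", "Atlantic", 79.0), ("S1", "Continental", 21.0)))
        assert a.region == "Atlantic"
        assert a.rule_used == "GE70"

    def test_fifty_fifty_is_na(self):
        a = g.assign_region(_bio(("S1", "Alpine", 50.0), ("S1", "Continental", 50.0)))
        assert a.region is None
        assert a.rule_used == "NA_UNRESOLVED"

    def test_single_region_100(self):
        a = g.assign_region(_bio(("S1", "Boreal", 100.0)))
        assert a.region == "Boreal"

    def test_marine_majority_never_qualifies(self):
        a = g.assign_region(
            _bio(("S1", "MarineBaltic", 80.0), ("S1", "Boreal", 20.0))
        )
        assert a.region is None  # 80% Marine Baltic resolves to NA

    def test_minor_terrestrial_region_never_qualifies(self):
        a = g.assign_region(_bio(("S1", "Steppic", 100.0)))
        assert a.region is None

    def test_two_regions_both_100_is_data_error_na(self):
        a = g.assign_region(_bio(("S1", "Alpine", 100.0), ("S1", "Boreal", 100.0)))
        assert a.region is None

    def test_duplicate_rows_summed_before_evaluation(self):
        a = g.assign_region(_bio(("S1", "Alpine", 40.0), ("S1", "Alpine", 35.0)))
        assert a.region == "Alpine"  # 75 >= 70 after summing

    def test_max100_is_threshold_independent(self):
        # a region recorded at exactly 100 stays assigned even when the
        # fraction threshold is raised past 100
        a = g.assign_region(_bio(("S1", "Boreal", 100.0)), min_fraction=120.0)
        assert a.region == "Boreal"
        assert a.rule_used == "MAX100"

    def test_extended_mode_admits_marine_regions(self):
        df = _bio(("S1", "MarineBaltic", 100.0))
        ext = g.assign_regions(df, terrestrial_only=False)
        assert ext.loc[0, "region"] == "MarineBaltic"


class TestAssignmentProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_order_invariance(self, seed):
        res = g.generate(g.SynthConfig(n_sites=150, seed=seed))
        base = g.assign_regions(res.bioregions)
        shuffled = res.bioregions.sample(frac=1, random_state=seed).reset_index(drop=True)
        other = g.assign_regions(shuffled)
        pd.testing.assert_frame_equal(
            base.sort_values("site_code", ignore_index=True),
            other.sort_values("site_code", ignore_index=True),
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        """Raising min_fraction can only turn assignments into NA, never
        switch one region for another (MAX100 cases are threshold-free)."""
        res = g.generate(g.SynthConfig(n_sites=150, seed=seed))
        corrected, _, _ = g.correct_zero_percents(res.bioregions)
        low = g.assign_regions(corrected, min_fraction=70.0).set_index("site_code")
        high = g.assign_regions(corrected, min_fraction=90.0).set_index("site_code")
        for site in low.index:
            lo, hi = low.loc[site, "region"], high.loc[site, "region"]
            assert hi == lo or hi is None


class TestAttachRegions:
    def test_na_sites_yield_na_entries(self, worked, worked_bundle):
        exp = worked["expected"]
        entries = worked_bundle.entries_classified
        fw = entries[entries["habitat_class"] == "FRESHWATER"]
        assert (fw["region"] == "").sum() == exp["na_freshwater_entries"]
        assignments = worked_bundle.assignments.set_index("site_code")["region"]
        for site, region in exp["assignments"].items():
            assert assignments.get(site) == region

    def test_all_sites_resolved_means_no_na(self):
        entries = pd.DataFrame(
            {
                "site_code": ["S1", "S2"],
                "habitat_code": ["3150", "7110"],
                "cover_ha": [1.0, 2.0],
                "habitat_class": ["FRESHWATER", "FRESHWATER"],
            }
        )
        assignments = pd.DataFrame(
            {"site_code": ["S1", "S2"], "region": ["Alpine", "Boreal"],
             "rule_used": ["GE70", "GE70"]}
        )
        out = g.attach_regions(entries, assignments)
        assert (out["region"] != "").all()

    def test_unresolved_site_count_from_fixture(self):
        # 2 of 5 sites unresolved, 3 entries each -> 6 NA entries
        entries = pd.DataFrame(
            {
                "site_code": [f"S{i}" for i in range(1, 6) for _ in range(3)],
                "habitat_code": ["3150"] * 15,
                "cover_ha": [1.0] * 15,
                "habitat_class": ["FRESHWATER"] * 15,
            }
        )
        assignments = pd.DataFrame(
            {
                "site_code": [f"S{i}" for i in range(1, 6)],
                "region": ["Alpine", "Alpine", "Alpine", None, None],
                "rule_used": ["GE70"] * 3 + ["NA_UNRESOLVED"] * 2,
            }
        )
        out = g.attach_regions(entries, assignments)
        assert (out["region"] == "").sum() == 6
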