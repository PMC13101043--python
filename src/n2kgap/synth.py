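"""Synthetic Natura 2000-shaped tables with planted ground truth.

The generator emulates the three-table schema of the 2021 database
export — sites with codes/types/areas, habitat entries with per-site
cover, bioregion rows with per-site region percentages — including the
anomaly classes the curation pipeline must handle: missing and tiny site
areas, missing and tiny habitat covers, sites whose habitat covers sum
past 100.01% of site area, Birds-Directive-only sites, sole-region rows
recorded at 0%, and sites split across regions below the 70% threshold.

Anomalies are planted disjointly (at most one site-level anomaly class
per site; entry-level anomalies only on anomaly-free sites), so every
expected post-curation count in :class:`GroundTruth` follows by direct
construction and the pipeline can be checked against it exactly.

Default parameters mirror the scale and anomaly frequencies of the 2021
database: ~27k sites, ~5.7 habitat entries per site, stage-1 site drops
near 0.4%, cover drops near 5%, and ~1.4% of sites carrying the
sole-region-0% recording error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemas import HabitatClass, Region, TERRESTRIAL_SIX
from .taxonomy import load_taxonomy


def _default_site_type_mix() -> dict[str, float]:
    return {"BD_ONLY": 0.17, "HD_ONLY": 0.60, "BOTH": 0.23}


def _default_region_mix() -> dict[str, float]:
    return {
        Region.ALPINE.value: 0.08,
        Region.ATLANTIC.value: 0.18,
        Region.BOREAL.value: 0.14,
        Region.CONTINENTAL.value: 0.30,
        Region.MEDITERRANEAN.value: 0.18,
        Region.PANNONIAN.value: 0.05,
        Region.STEPPIC.value: 0.01,
        Region.BLACK_SEA.value: 0.005,
        Region.MACARONESIAN.value: 0.005,
        Region.MARINE_ATLANTIC.value: 0.02,
        Region.MARINE_BALTIC.value: 0.02,
        Region.MARINE_MEDITERRANEAN.value: 0.01,
    }


@dataclass
class SynthConfig:
    """Generator parameters; probabilities must sum to 1, rates lie in [0, 1]."""

    n_sites: int = 27031
    site_type_mix: dict[str, float] = field(default_factory=_default_site_type_mix)
    log_area_mean: float = 5.0  # log-hectares; exp(5) ≈ 148 ha median
    log_area_sd: float = 2.5
    habitats_per_site_mean: float = 5.65
    fill_fraction_range: tuple[float, float] = (0.2, 0.9)
    overfill_fraction_range: tuple[float, float] = (1.2, 1.8)
    region_mix: dict[str, float] = field(default_factory=_default_region_mix)
    missing_site_area: float = 0.003
    tiny_site_area: float = 0.001
    missing_cover: float = 0.045
    tiny_cover: float = 0.004
    overfilled_site: float = 0.01
    zero_percent_region: float = 0.0138
    multi_region_site: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "missing_site_area",
            "tiny_site_area",
            "missing_cover",
            "tiny_cover",
            "overfilled_site",
            "zero_percent_region",
            "multi_region_site",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        for mix_name in ("site_type_mix", "region_mix"):
            total = sum(getattr(self, mix_name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} probabilities sum to {total}, not 1")
        site_rate = (
            self.missing_site_area
            + self.tiny_site_area
            + self.overfilled_site
            + self.zero_percent_region
            + self.multi_region_site
        )
        if site_rate > 1.0:
            raise ValueError("site-level anomaly rates sum past 1; cannot plant disjointly")
        if self.missing_cover + self.tiny_cover > 1.0:
            raise ValueError("entry-level anomaly rates sum past 1")
        if self.overfilled_site > 0 and self.habitats_per_site_mean <= 0:
            raise ValueError("overfilled sites require habitats; habitats_per_site_mean is 0")


@dataclass
class GroundTruth:
    """Expected pipeline outcomes, derived at generation time by construction."""

    n_sites_raw: int
    n_entries_raw: int
    n_sites_after_filter: int
    n_entries_after_filter: int
    n_overfilled_dropped: int
    n_bd_only_dropped: int
    n_sites_final: int
    n_entries_final: int
    n_zero_percent_corrected: int
    n_na_sites_final: int
    n_na_freshwater_entries: int
    class_area_ha: dict[str, float]
    per_habitat_site_counts: dict[str, int]
    gap_proportion: dict[str, float]

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class SynthResult:
    sites: pd.DataFrame
    habitats: pd.DataFrame
    bioregions: pd.DataFrame
    truth: GroundTruth


_COUNTRIES = ("AT", "BE", "DE", "DK", "ES", "FI", "FR", "IT", "LV", "PL", "SE")


def generate(config: SynthConfig | None = None) -> SynthResult:
    """Generate the three tables plus ground truth; same config ⇒ same bytes."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    country = rng.choice(_COUNTRIES, size=n)
    site_code = np.array([f"{c}{i:07d}" for i, c in enumerate(country)])
    types = list(config.site_type_mix)
    site_type = rng.choice(types, size=n, p=[config.site_type_mix[t] for t in types])
    true_area = np.exp(rng.normal(config.log_area_mean, config.log_area_sd, size=n))
    true_area = np.maximum(true_area, 0.01)  # keep legit sites clear of the 1e-4 floor

    # --- disjoint site-level anomaly planting: one categorical draw per
    # site, so each anomaly count is Binomial(n, rate) across seeds ---
    site_categories = (
        "missing_site_area",
        "tiny_site_area",
        "overfilled_site",
        "zero_percent_region",
        "multi_region_site",
    )
    site_rates = [getattr(config, c) for c in site_categories]
    anomaly = rng.choice(
        [*site_categories, "none"], size=n, p=[*site_rates, 1.0 - sum(site_rates)]
    ).astype(object)
    planted = {name: np.flatnonzero(anomaly == name) for name in site_categories}

    reported_area = true_area.copy()
    reported_area[planted["missing_site_area"]] = np.nan
    reported_area[planted["tiny_site_area"]] = rng.uniform(
        1e-6, 5e-5, size=len(planted["tiny_site_area"])
    )
    # tiny sites keep a workable true area for cover allocation
    sites = pd.DataFrame(
        {
            "site_code": site_code,
            "site_type": site_type,
            "total_area_ha": reported_area,
            "country": country,
        }
    )

    # --- habitat entries ---
    taxonomy = load_taxonomy()
    code_pool = np.array(taxonomy.codes)
    n_habs = rng.poisson(config.habitats_per_site_mean, size=n)
    n_habs[planted["overfilled_site"]] = np.maximum(n_habs[planted["overfilled_site"]], 1)

    site_idx = np.repeat(np.arange(n), n_habs)
    codes = rng.choice(code_pool, size=len(site_idx))
    entries = pd.DataFrame({"_site_idx": site_idx, "habitat_code": codes})
    entries = entries.drop_duplicates(["_site_idx", "habitat_code"]).reset_index(drop=True)

    lo, hi = config.fill_fraction_range
    fill = rng.uniform(lo, hi, size=n)
    olo, ohi = config.overfill_fraction_range
    fill[planted["overfilled_site"]] = rng.uniform(
        olo, ohi, size=len(planted["overfilled_site"])
    )
    weights = rng.exponential(1.0, size=len(entries))
    wsum = pd.Series(weights).groupby(entries["_site_idx"]).transform("sum").to_numpy()
    cover = weights / wsum * fill[entries["_site_idx"]] * true_area[entries["_site_idx"]]

    entries["site_code"] = site_code[entries["_site_idx"]]
    entries["priority"] = False
    entries["cover_ha"] = cover

    # entry-level anomalies only on sites without a site-level anomaly,
    # again as independent categorical draws per eligible entry
    clean_entry = anomaly[entries["_site_idx"].to_numpy()] == "none"
    eligible_idx = np.flatnonzero(clean_entry)
    entry_rates = [config.missing_cover, config.tiny_cover]
    entry_kind = rng.choice(
        ["missing_cover", "tiny_cover", "none"],
        size=len(eligible_idx),
        p=[*entry_rates, 1.0 - sum(entry_rates)],
    )
    missing_entries = eligible_idx[entry_kind == "missing_cover"]
    tiny_entries = eligible_idx[entry_kind == "tiny_cover"]
    entries.loc[missing_entries, "cover_ha"] = np.nan
    entries.loc[tiny_entries, "cover_ha"] = rng.uniform(1e-6, 5e-5, size=len(tiny_entries))

    # --- bioregions ---
    regions = list(config.region_mix)
    primary = rng.choice(regions, size=n, p=[config.region_mix[r] for r in regions])
    bio_rows = {"site_code": [], "region": [], "percent_of_site": []}
    second_choices = rng.choice(regions, size=n)
    for i in range(n):
        if anomaly[i] == "zero_percent_region":
            bio_rows["site_code"].append(site_code[i])
            bio_rows["region"].append(primary[i])
            bio_rows["percent_of_site"].append(0.0)
        elif anomaly[i] == "multi_region_site":
            other = second_choices[i]
            if other == primary[i]:
                other = regions[(regions.index(other) + 1) % len(regions)]
            bio_rows["site_code"].extend([site_code[i], site_code[i]])
            bio_rows["region"].extend([primary[i], other])
            bio_rows["percent_of_site"].extend([55.0, 45.0])
        else:
            bio_rows["site_code"].append(site_code[i])
            bio_rows["region"].append(primary[i])
            bio_rows["percent_of_site"].append(100.0)
    bioregions = pd.DataFrame(bio_rows)

    truth = _ground_truth(
        config, anomaly, site_type, primary, entries, taxonomy, site_code
    )
    entries = entries.drop(columns="_site_idx")[
        ["site_code", "habitat_code", "priority", "cover_ha"]
    ]
    return SynthResult(sites=sites, habitats=entries, bioregions=bioregions, truth=truth)


def _ground_truth(config, anomaly, site_type, primary, entries, taxonomy, site_code):
    """Derive expected pipeline outcomes from the planted flags alone."""
    n = len(anomaly)
    terrestrial_six = {r.value for r in TERRESTRIAL_SIX}

    site_dropped_stage1 = np.isin(anomaly, ("missing_site_area", "tiny_site_area"))
    n_after_filter = int(n - site_dropped_stage1.sum())

    entry_bad = entries["cover_ha"].isna() | (entries["cover_ha"] < 1e-4)
    n_entries_after = int(len(entries) - entry_bad.sum())

    overfilled = anomaly == "overfilled_site"
    bd_only = (site_type == "BD_ONLY") & ~site_dropped_stage1 & ~overfilled
    site_final = ~site_dropped_stage1 & ~overfilled & ~bd_only

    entry_site_final = site_final[entries["_site_idx"].to_numpy()]
    entry_final = entry_site_final & ~entry_bad.to_numpy()
    n_entries_final = int(entry_final.sum())

    # region resolution: zero-percent sites are corrected then assigned;
    # multi-region splits (55/45) and non-six primaries resolve to NA
    primary_in_six = np.isin(primary, list(terrestrial_six))
    site_na = (anomaly == "multi_region_site") | ~primary_in_six
    n_na_sites_final = int((site_na & site_final).sum())

    classes = {
        code: taxonomy.frame.at[code, "habitat_class"] for code in taxonomy.codes
    }
    entry_class = entries["habitat_code"].map(classes).to_numpy()
    fw = entry_class == HabitatClass.FRESHWATER.value
    entry_na = site_na[entries["_site_idx"].to_numpy()]
    n_na_fw_entries = int((entry_final & fw & entry_na).sum())

    final_entries = entries.loc[entry_final]
    class_area = (
        final_entries.assign(_class=entry_class[entry_final])
        .groupby("_class")["cover_ha"]
        .sum()
        .to_dict()
    )
    per_habitat_sites = (
        final_entries.groupby("habitat_code")["site_code"].nunique().to_dict()
    )

    gap_proportion = _brute_force_gap(
        final_entries, entry_class[entry_final], entry_na[entry_final], primary
    )

    return GroundTruth(
        n_sites_raw=n,
        n_entries_raw=int(len(entries)),
        n_sites_after_filter=n_after_filter,
        n_entries_after_filter=n_entries_after,
        n_overfilled_dropped=int(overfilled.sum()),
        n_bd_only_dropped=int(bd_only.sum()),
        n_sites_final=int(site_final.sum()),
        n_entries_final=n_entries_final,
        n_zero_percent_corrected=int((anomaly == "zero_percent_region").sum()),
        n_na_sites_final=n_na_sites_final,
        n_na_freshwater_entries=n_na_fw_entries,
        class_area_ha={k: float(v) for k, v in class_area.items()},
        per_habitat_site_counts={k: int(v) for k, v in per_habitat_sites.items()},
        gap_proportion=gap_proportion,
    )


def _brute_force_gap(final_entries, entry_class_final, entry_na_final, primary):
    """Expected gap proportions via a plain row-by-row crosswalk union.

    Independent of the range-inference module: reads the shipped crosswalk
    CSVs directly, unions linked region sets (UNSPECIFIED means all six),
    and adds the Baltic {Boreal, Continental} rule for 1650 by hand.
    """
    from .redlist import default_crosswalk_path, default_rl_regions_path

    six = {r.value for r in TERRESTRIAL_SIX}
    links = pd.read_csv(default_crosswalk_path(), dtype=str, keep_default_na=False)
    regs = pd.read_csv(default_rl_regions_path(), dtype=str, keep_default_na=False)
    reg_map = dict(zip(regs["rl_code"], regs["regions"]))

    natural: dict[str, set[str]] = {}
    for row in links.itertuples():
        spec = reg_map.get(row.rl_code, "UNSPECIFIED")
        members = set(six) if spec == "UNSPECIFIED" else set(spec.split(";"))
        natural.setdefault(row.annex_code, set()).update(members)
    if "1650" in natural:
        natural["1650"] |= {Region.BOREAL.value, Region.CONTINENTAL.value}

    fw_mask = entry_class_final == HabitatClass.FRESHWATER.value
    fw = final_entries.loc[fw_mask]
    fw_na = entry_na_final[fw_mask]
    observed: dict[str, set[str]] = {code: set() for code in fw["habitat_code"].unique()}
    resolved = fw.loc[~fw_na]
    resolved_regions = pd.Series(
        primary[resolved["_site_idx"].to_numpy()], index=resolved.index
    )
    for code, region_values in resolved_regions.groupby(resolved["habitat_code"]):
        observed[code] = set(region_values)

    out: dict[str, float] = {}
    for code, obs in observed.items():
        nat = natural.get(code)
        if nat:
            out[code] = len(obs & nat) / len(nat)
    return out


def make_worked_fixture() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Miniature six-site dataset exercising every curation rule once.

    Sites: a multi-habitat freshwater site (DE0001), a sole-region-0%
    site (FR0002), a Birds-Directive-only site (BE0003), an overfilled
    site (PL0004, covers sum to 140% of area), an unresolvable-region
    site (SE0005, 60/40 split), and a site with a tiny-cover entry
    (IT0006). Expected summaries are hand-computed and returned alongside.
    """
    sites = pd.DataFrame(
        {
            "site_code": ["DE0001", "FR0002", "BE0003", "PL0004", "SE0005", "IT0006"],
            "site_type": ["BOTH", "HD_ONLY", "BD_ONLY", "HD_ONLY", "HD_ONLY", "HD_ONLY"],
            "total_area_ha": [100.0, 200.0, 50.0, 10.0, 1000.0, 100.0],
            "country": ["DE", "FR", "BE", "PL", "SE", "IT"],
        }
    )
    habitats = pd.DataFrame(
        {
            "site_code": [
                "DE0001", "DE0001", "DE0001", "DE0001",
                "FR0002", "FR0002",
                "BE0003",
                "PL0004", "PL0004",
                "SE0005",
                "IT0006", "IT0006",
            ],
            "habitat_code": [
                "3260", "7110", "91E0", "9110",
                "3150", "1110",
                "6430",
                "3160", "7140",
                "7310",
                "92D0", "3270",
            ],
            "priority": [
                False, True, True, False,
                False, False,
                False,
                False, False,
                True,
                False, False,
            ],
            "cover_ha": [10.0, 20.0, 10.0, 20.0, 50.0, 50.0, 5.0, 8.0, 6.0, 600.0, 30.0, 0.00005],
        }
    )
    bioregions = pd.DataFrame(
        {
            "site_code": [
                "DE0001", "FR0002", "BE0003", "PL0004", "SE0005", "SE0005", "IT0006",
            ],
            "region": [
                "Continental", "Atlantic", "Atlantic", "Continental",
                "Boreal", "Continental", "Mediterranean",
            ],
            "percent_of_site": [100.0, 0.0, 100.0, 100.0, 60.0, 40.0, 100.0],
        }
    )
    expected = {
        "sites_after_filter": 6,
        "entries_after_filter": 11,
        "sites_final": 4,
        "entries_final": 8,
        "dropped_bd_only_area_ha": 50.0,
        "total_hd_area_ha": 1400.0,
        "network_area_ha": 1450.0,
        "mapped_percent": 100.0 * 790.0 / 1400.0,
        "unmapped_percent": 100.0 * 610.0 / 1400.0,
        "class_percent": {
            "FRESHWATER": 100.0 * 720.0 / 1400.0,
            "MARINE_COASTAL": 100.0 * 50.0 / 1400.0,
            "TERRESTRIAL": 100.0 * 20.0 / 1400.0,
        },
        "freshwater_percent_of_network": 100.0 * 720.0 / 1450.0,
        "group_area_ha": {
            "RUNNING": 10.0,
            "STANDING": 50.0,
            "PEATLAND": 620.0,
            "FOREST": 40.0,
            "GRASS_HEATH_COASTAL": 0.0,
        },
        "group_percent": {
            "RUNNING": 100.0 * 10.0 / 720.0,
            "STANDING": 100.0 * 50.0 / 720.0,
            "PEATLAND": 100.0 * 620.0 / 720.0,
            "FOREST": 100.0 * 40.0 / 720.0,
            "GRASS_HEATH_COASTAL": 0.0,
        },
        "nutrient_area_ha": {"OLIGOTROPHIC": 620.0, "MESOTROPHIC": 40.0, "EUTROPHIC": 60.0},
        "nutrient_sites": {"OLIGOTROPHIC": 2, "MESOTROPHIC": 2, "EUTROPHIC": 2},
        "size_counts": {"[0, 50)": 0, "[50, 500)": 3, ">= 500": 1},
        "sites_with_freshwater": 4,
        "share_sites_1_to_4_types": 100.0,
        "zero_percent_corrections": 1,
        "na_sites": 1,
        "na_freshwater_entries": 1,
        "assignments": {
            "DE0001": "Continental",
            "FR0002": "Atlantic",
            "SE0005": None,
            "IT0006": "Mediterranean",
        },
        "gap_proportion": {
            "3260": 1.0 / 6.0,
            "7110": 1.0 / 4.0,
            "91E0": 1.0 / 6.0,
            "3150": 1.0 / 6.0,
            "7310": 0.0,
            "92D0": 1.0,
        },
        "fully_represented": {"92D0": True},
        "mean_gap_proportion": (1.0 / 6.0 + 0.25 + 1.0 / 6.0 + 1.0 / 6.0 + 0.0 + 1.0) / 6.0,
    }
    return sites, habitats, bioregions, expected
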