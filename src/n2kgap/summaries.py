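"""Descriptive statistics and the biogeographic representation-gap analysis.

All percentages are computed at full precision; rendering to one decimal
is left to the caller. Every summary documents its denominator in the
returned object, because the two natural denominators differ: per-class
coverage uses the total area of sites designated under the Habitats
Directive (HD-only + both-directive sites), while whole-network figures
additionally include the area of Birds-Directive-only sites removed
during curation.

Two region-counting modes exist and are deliberately separate outputs:
the gap analysis compares terrestrial-only observed regions against the
inferred natural range, while descriptive per-habitat region counts may
use the extended region list including marine regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemas import FreshwaterGroup, HabitatClass, Nutrient


@dataclass
class CoverageSummary:
    total_hd_area_ha: float
    network_area_ha: float  # HD-designated + dropped BD-only area
    mapped_percent: float
    unmapped_percent: float
    class_percent: dict[str, float]  # of HD-designated area
    freshwater_percent_of_network: float

    def to_dict(self) -> dict:
        return {
            "total_hd_area_ha": self.total_hd_area_ha,
            "network_area_ha": self.network_area_ha,
            "mapped_percent": self.mapped_percent,
            "unmapped_percent": self.unmapped_percent,
            "class_percent": dict(self.class_percent),
            "freshwater_percent_of_network": self.freshwater_percent_of_network,
        }


def class_coverage(
    sites: pd.DataFrame,
    entries: pd.DataFrame,
    dropped_bd_only_area_ha: float = 0.0,
) -> CoverageSummary:
    """Mapped/unmapped split and per-class share of the HD-designated area."""
    hd_area = float(sites["total_area_ha"].sum())
    if hd_area <= 0:
        raise ValueError("total HD-designated area is zero; nothing to summarize")
    network_area = hd_area + float(dropped_bd_only_area_ha)

    mapped_area = float(entries["cover_ha"].sum())
    class_area = entries.groupby("habitat_class")["cover_ha"].sum()
    class_percent = {
        cls.value: float(100.0 * class_area.get(cls.value, 0.0) / hd_area)
        for cls in HabitatClass
    }
    fw_area = float(class_area.get(HabitatClass.FRESHWATER.value, 0.0))
    return CoverageSummary(
        total_hd_area_ha=hd_area,
        network_area_ha=network_area,
        mapped_percent=100.0 * mapped_area / hd_area,
        unmapped_percent=100.0 * (hd_area - mapped_area) / hd_area,
        class_percent=class_percent,
        freshwater_percent_of_network=100.0 * fw_area / network_area,
    )


def _freshwater(entries: pd.DataFrame) -> pd.DataFrame:
    return entries[entries["habitat_class"] == HabitatClass.FRESHWATER.value]


def group_shares(entries: pd.DataFrame) -> pd.DataFrame:
    """Area, percent-of-freshwater-area and site count per freshwater group."""
    fw = _freshwater(entries)
    total = fw["cover_ha"].sum()
    rows = []
    for group in FreshwaterGroup:
        sub = fw[fw["freshwater_group"] == group.value]
        area = float(sub["cover_ha"].sum())
        rows.append(
            {
                "freshwater_group": group.value,
                "area_ha": area,
                "percent_of_freshwater_area": 100.0 * area / total if total else 0.0,
                "n_sites": int(sub["site_code"].nunique()),
            }
        )
    return pd.DataFrame(rows)


def nutrient_summary(entries: pd.DataFrame) -> pd.DataFrame:
    """Site counts and area shares per nutrient level.

    Site counts record (site, nutrient) presence: a site hosting habitats
    of two nutrient classes contributes to both counters.
    """
    fw = _freshwater(entries)
    total = fw["cover_ha"].sum()
    rows = []
    for nut in Nutrient:
        sub = fw[fw["nutrient"] == nut.value]
        area = float(sub["cover_ha"].sum())
        rows.append(
            {
                "nutrient": nut.value,
                "n_sites": int(sub["site_code"].nunique()),
                "area_ha": area,
                "percent_of_freshwater_area": 100.0 * area / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def size_distribution(
    areas: pd.Series, breaks: tuple[float, ...] = (50.0, 500.0)
) -> pd.DataFrame:
    """Counts and percents of sites per half-open size class [lo, hi) in ha."""
    edges = [0.0, *breaks, np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f">= {lo:g}")
    cut = pd.cut(areas, bins=edges, labels=labels, right=False, include_lowest=True)
    counts = cut.value_counts().reindex(labels, fill_value=0)
    n = len(areas)
    return pd.DataFrame(
        {
            "size_class": labels,
            "n_sites": counts.values,
            "percent": 100.0 * counts.values / n if n else 0.0,
        }
    )


def size_distribution_by_class(
    sites: pd.DataFrame, entries: pd.DataFrame, breaks: tuple[float, ...] = (50.0, 500.0)
) -> dict[str, pd.DataFrame]:
    """Size distribution of all HD sites and of sites hosting each class."""
    out = {"ALL": size_distribution(sites["total_area_ha"], breaks)}
    areas = sites.set_index("site_code")["total_area_ha"]
    for cls in HabitatClass:
        hosting = entries.loc[entries["habitat_class"] == cls.value, "site_code"].unique()
        out[cls.value] = size_distribution(areas.loc[areas.index.intersection(hosting)], breaks)
    return out


def habitat_stats(entries: pd.DataFrame) -> pd.DataFrame:
    """Per freshwater habitat code: total area, share of freshwater area,
    distinct-site count, group and nutrient."""
    fw = _freshwater(entries)
    total = fw["cover_ha"].sum()
    grouped = fw.groupby("habitat_code").agg(
        total_area_ha=("cover_ha", "sum"),
        n_sites=("site_code", "nunique"),
        freshwater_group=("freshwater_group", "first"),
        nutrient=("nutrient", "first"),
    )
    grouped["percent_of_freshwater_area"] = (
        100.0 * grouped["total_area_ha"] / total if total else 0.0
    )
    return grouped.reset_index()[
        [
            "habitat_code",
            "total_area_ha",
            "percent_of_freshwater_area",
            "n_sites",
            "freshwater_group",
            "nutrient",
        ]
    ].sort_values("total_area_ha", ascending=False, ignore_index=True)


def sites_with_freshwater(entries: pd.DataFrame) -> tuple[int, pd.Series, float]:
    """(number of sites with >=1 freshwater habitat, per-site habitat-type
    counts, share of those sites hosting one to four types)."""
    fw = _freshwater(entries)
    per_site = fw.groupby("site_code")["habitat_code"].nunique()
    n = int(len(per_site))
    share_1_to_4 = float(100.0 * per_site.between(1, 4).mean()) if n else 0.0
    return n, per_site, share_1_to_4


@dataclass
class GapResult:
    habitat_code: str
    freshwater_group: str
    observed_regions: frozenset[str]
    natural_range: frozenset[str]
    n_observed_extended: int
    fully_represented: bool
    proportion: float


def observed_regions_by_habitat(entries: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Terrestrial regions in which each freshwater habitat is designated.

    Entries with an unresolved (NA) region carry an empty string and are
    excluded here, though they remain in area/count summaries.
    """
    fw = _freshwater(entries)
    resolved = fw[fw["region"] != ""]
    return {
        code: frozenset(grp["region"])
        for code, grp in resolved.groupby("habitat_code")
    }


def gap_analysis(
    entries: pd.DataFrame,
    natural_ranges: dict[str, frozenset[str]],
    extended_counts: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Compare observed network regions with inferred natural ranges.

    Returns (per-habitat gap table, per-group full-representation tally,
    codes excluded for lack of a usable natural range). The proportion is
    |observed ∩ natural| / |natural|; it equals 1 exactly when the natural
    range is a subset of the observed regions.
    """
    fw = _freshwater(entries)
    observed = observed_regions_by_habitat(entries)
    groups = fw.drop_duplicates("habitat_code").set_index("habitat_code")["freshwater_group"]

    rows, excluded = [], []
    for code in sorted(fw["habitat_code"].unique()):
        natural = natural_ranges.get(code)
        if not natural:
            excluded.append(code)
            continue
        obs = observed.get(code, frozenset())
        inter = obs & natural
        proportion = len(inter) / len(natural)
        rows.append(
            {
                "habitat_code": code,
                "freshwater_group": groups.get(code, ""),
                "observed_regions": ";".join(sorted(obs)),
                "natural_range": ";".join(sorted(natural)),
                "n_observed": len(obs),
                "n_natural": len(natural),
                "n_observed_extended": (extended_counts or {}).get(code, len(obs)),
                "fully_represented": natural <= obs,
                "proportion": proportion,
            }
        )
    gap = pd.DataFrame(
        rows,
        columns=[
            "habitat_code",
            "freshwater_group",
            "observed_regions",
            "natural_range",
            "n_observed",
            "n_natural",
            "n_observed_extended",
            "fully_represented",
            "proportion",
        ],
    )
    if gap.empty:
        tally = pd.DataFrame(
            columns=["freshwater_group", "n_habitats", "n_fully_represented"]
        )
    else:
        tally = (
            gap.groupby("freshwater_group")
            .agg(n_habitats=("habitat_code", "size"), n_fully_represented=("fully_represented", "sum"))
            .reset_index()
        )
    return gap, tally, excluded


def extended_region_counts(
    entries: pd.DataFrame, extended_assignments: pd.DataFrame
) -> dict[str, int]:
    """Descriptive per-habitat region counts over the extended region list.

    Uses a site→region assignment computed with ``terrestrial_only=False``
    so marine and minor terrestrial regions are countable.
    """
    fw = _freshwater(entries)
    lookup = extended_assignments.set_index("site_code")["region"]
    regions = fw["site_code"].map(lookup)
    counted = fw.assign(ext_region=regions).dropna(subset=["ext_region"])
    return {
        code: int(grp["ext_region"].nunique())
        for code, grp in counted.groupby("habitat_code")
    }
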