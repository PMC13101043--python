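"""Biogeographic region cleaning and per-site assignment.

A site is assigned at most one of the six main terrestrial regions:
the region holding at least ``min_fraction`` percent of the site's area,
or — failing that — the region whose reported percentage equals 100
(a pattern produced by sites recorded as a single region). Marine and
minor terrestrial regions never qualify a site for assignment; sites
that cannot be resolved get NA and their habitat entries are excluded
from per-region tallies (but stay in area and count totals).

Sites recorded as exactly one region with 0% (a known data error in the
source table) are corrected to 100% deterministically; an overrides file
handles the cases where the correct value is not 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .schemas import Region, TERRESTRIAL_SIX


class AssignmentRule:
    GE70 = "GE70"
    MAX100 = "MAX100"
    CORRECTED_0_TO_100 = "CORRECTED_0_TO_100"
    OVERRIDE = "OVERRIDE"
    NA_UNRESOLVED = "NA_UNRESOLVED"


@dataclass(frozen=True)
class RegionAssignment:
    site_code: str
    region: str | None  # one of the six terrestrial region values, or None
    rule_used: str


def default_overrides_path() -> Path:
    return Path(str(resources.files("n2kgap").joinpath("data/region_overrides.csv")))


def load_overrides(path: str | Path | None = None) -> pd.DataFrame:
    """Overrides CSV: site_code,region,percent with percents in (0, 100]."""
    path = Path(path) if path is not None else default_overrides_path()
    df = pd.read_csv(path, dtype={"site_code": str, "region": str, "percent": float})
    bad = df[(df["percent"] <= 0) | (df["percent"] > 100)]
    if not bad.empty:
        raise ValueError(f"override percents must lie in (0, 100]: {bad['site_code'].tolist()}")
    return df


def correct_zero_percents(
    bioregions: pd.DataFrame, overrides: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, int, pd.DataFrame]:
    """Fix sole-region-0% records and apply explicit overrides.

    A site whose region records consist of exactly one region reported at
    0% has that percent set to 100 (rule CORRECTED_0_TO_100) unless an
    override row specifies a different value. Sites with several regions,
    one of them 0%, are ambiguous and left untouched.

    Returns (corrected table, number of sites corrected, correction log).
    """
    df = bioregions.copy()
    per_site = df.groupby("site_code")["percent_of_site"]
    sole = per_site.transform("size") == 1
    zero = df["percent_of_site"] == 0
    target = sole & zero

    override_map: dict[str, tuple[str, float]] = {}
    if overrides is not None:
        override_map = {
            r.site_code: (r.region, float(r.percent)) for r in overrides.itertuples()
        }

    log_rows = []
    corrected_sites: set[str] = set()
    for idx in df.index[target]:
        site = df.at[idx, "site_code"]
        if site in override_map:
            region, pct = override_map[site]
            df.at[idx, "region"] = region
            df.at[idx, "percent_of_site"] = pct
            rule = AssignmentRule.OVERRIDE
        else:
            pct = 100.0
            df.at[idx, "percent_of_site"] = pct
            rule = AssignmentRule.CORRECTED_0_TO_100
        corrected_sites.add(site)
        log_rows.append({"site_code": site, "new_percent": pct, "rule": rule})

    # overrides may also target sites outside the sole-zero pattern
    for site, (region, pct) in override_map.items():
        if site in corrected_sites:
            continue
        mask = (df["site_code"] == site) & (df["region"] == region)
        if mask.any():
            df.loc[mask, "percent_of_site"] = pct
            corrected_sites.add(site)
            log_rows.append({"site_code": site, "new_percent": pct, "rule": AssignmentRule.OVERRIDE})

    log = pd.DataFrame(log_rows, columns=["site_code", "new_percent", "rule"])
    return df, len(corrected_sites), log


_TERRESTRIAL_VALUES = {r.value for r in TERRESTRIAL_SIX}


def assign_regions(
    bioregions: pd.DataFrame,
    min_fraction: float = 70.0,
    corrected_sites: set[str] | None = None,
    override_sites: set[str] | None = None,
    terrestrial_only: bool = True,
) -> pd.DataFrame:
    """Assign at most one region per site.

    Duplicate (site, region) rows are summed before evaluation. With
    ``terrestrial_only`` (the analysis mode) only the six main terrestrial
    regions can be assigned; the extended mode (descriptive counts) admits
    every known region. Ties where two regions both report 100% are data
    errors and resolve to NA.

    Returns a frame with columns site_code, region (None for NA), rule_used.
    """
    corrected_sites = corrected_sites or set()
    override_sites = override_sites or set()
    candidates = _TERRESTRIAL_VALUES if terrestrial_only else {
        r.value for r in Region if r is not Region.UNKNOWN
    }

    summed = (
        bioregions.groupby(["site_code", "region"], as_index=False)["percent_of_site"].sum()
    )
    rows = []
    for site, grp in summed.groupby("site_code", sort=True):
        eligible = grp[grp["region"].isin(candidates)]
        region = None
        rule = AssignmentRule.NA_UNRESOLVED
        if not eligible.empty:
            at_100 = eligible[eligible["percent_of_site"] == 100.0]
            top = eligible.loc[eligible["percent_of_site"].idxmax()]
            if len(at_100) >= 2:
                pass  # two regions both reported at 100%: data error, NA
            elif top["percent_of_site"] >= min_fraction:
                region, rule = top["region"], AssignmentRule.GE70
            elif len(at_100) == 1:
                region, rule = at_100.iloc[0]["region"], AssignmentRule.MAX100
        if region is not None:
            if site in override_sites:
                rule = AssignmentRule.OVERRIDE
            elif site in corrected_sites:
                rule = AssignmentRule.CORRECTED_0_TO_100
        rows.append({"site_code": site, "region": region, "rule_used": rule})
    return pd.DataFrame(rows, columns=["site_code", "region", "rule_used"])


def assign_region(
    site_entries: pd.DataFrame, min_fraction: float = 70.0, **kwargs
) -> RegionAssignment:
    """Single-site convenience wrapper around :func:`assign_regions`."""
    codes = site_entries["site_code"].unique()
    if len(codes) != 1:
        raise ValueError("assign_region expects the records of exactly one site")
    row = assign_regions(site_entries, min_fraction=min_fraction, **kwargs).iloc[0]
    return RegionAssignment(
        site_code=codes[0],
        region=None if row["region"] is None else row["region"],
        rule_used=row["rule_used"],
    )


def attach_regions(entries: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Annotate habitat entries with their site's assigned region (or NA).

    NA entries keep an empty-string region; downstream per-region tallies
    skip them while area/count totals retain them.
    """
    lookup = assignments.set_index("site_code")["region"]
    out = entries.copy()
    out["region"] = entries["site_code"].map(lookup).fillna("")
    out["region"] = out["region"].replace({None: ""})
    return out
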