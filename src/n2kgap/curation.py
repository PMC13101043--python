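"""Stepwise exclusion rules producing the analysis dataset.

The curation order is fixed: (1) drop sites with missing or sub-threshold
total area, (2) drop habitat entries with missing or sub-threshold cover,
(3) join on site code, drop orphaned entries, drop sites whose summed
habitat cover exceeds the tolerance above 100% of site area, drop sites
designated only under the Birds Directive. Applying the join/prune stage
before the entry filter could change the >100.01% verdict for sites with
tiny entries, so the order is part of the contract.

Every stage appends to a ``CurationAudit`` whose counts always satisfy
``records_out = records_in - records_dropped``; the per-record drop
reasons partition the dropped set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .schemas import SiteType

#: Decimal places used when comparing summed habitat cover (in percent of
#: site area) against the >100.01% threshold, to keep binary representation
#: noise away from the boundary.
PERCENT_DECIMALS = 6


@dataclass
class CurationConfig:
    """Thresholds for the exclusion rules.

    min_area_ha: sites/entries with area strictly below this (or missing)
        are dropped; equality keeps the record.
    max_habitat_sum_percent: sites whose habitat covers sum to strictly
        more than this percentage of site area are dropped.
    drop_bd_only: remove sites designated only under the Birds Directive
        (their Annex I habitats were not part of the designation).
    """

    min_area_ha: float = 0.0001
    max_habitat_sum_percent: float = 100.01
    drop_bd_only: bool = True

    def __post_init__(self) -> None:
        if self.min_area_ha <= 0:
            raise ValueError("min_area_ha must be > 0")
        if self.max_habitat_sum_percent < 100:
            raise ValueError("max_habitat_sum_percent must be >= 100")


@dataclass
class AuditStage:
    name: str
    n_in: int
    n_dropped: int
    n_out: int
    reasons: pd.DataFrame  # columns: record_id, reason

    def __post_init__(self) -> None:
        assert self.n_out == self.n_in - self.n_dropped, self.name


@dataclass
class CurationAudit:
    stages: list[AuditStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, reasons: pd.DataFrame) -> AuditStage:
        stage = AuditStage(
            name=name,
            n_in=n_in,
            n_dropped=len(reasons),
            n_out=n_in - len(reasons),
            reasons=reasons.reset_index(drop=True),
        )
        self.stages.append(stage)
        return stage

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "records_in": s.n_in,
                    "records_dropped": s.n_dropped,
                    "records_out": s.n_out,
                }
                for s in self.stages
            ]
        )

    def reasons_frame(self) -> pd.DataFrame:
        if not self.stages:
            return pd.DataFrame(columns=["stage", "record_id", "reason"])
        frames = [s.reasons.assign(stage=s.name) for s in self.stages]
        return pd.concat(frames, ignore_index=True)[["stage", "record_id", "reason"]]


@dataclass
class CuratedDataset:
    """Analysis-ready sites and habitat entries plus the audit trail.

    ``dropped_bd_only_area_ha`` keeps the total area of the removed
    BD-only sites: whole-network denominators (freshwater share of the
    entire network, not just the HD-designated part) need it even though
    the sites themselves leave the dataset.
    Sites with zero habitat entries are retained — their unmapped area is
    part of the mapped/unmapped split.
    """

    sites: pd.DataFrame
    entries: pd.DataFrame
    audit: CurationAudit
    dropped_bd_only_area_ha: float = 0.0


def _reasons(ids: pd.Series, reason: str) -> pd.DataFrame:
    return pd.DataFrame({"record_id": ids.astype(str), "reason": reason})


def filter_sites(
    sites: pd.DataFrame, config: CurationConfig, audit: CurationAudit | None = None
) -> tuple[pd.DataFrame, AuditStage]:
    """Drop sites whose total area is missing or strictly below the minimum."""
    audit = audit if audit is not None else CurationAudit()
    area = sites["total_area_ha"]
    missing = area.isna()
    tiny = area < config.min_area_ha  # NaN compares False, disjoint from `missing`
    reasons = pd.concat(
        [
            _reasons(sites.loc[missing, "site_code"], "site_area_missing"),
            _reasons(sites.loc[tiny, "site_code"], "site_area_below_min"),
        ],
        ignore_index=True,
    )
    stage = audit.add("filter_sites", len(sites), reasons)
    return sites.loc[~(missing | tiny)].reset_index(drop=True), stage


def filter_habitat_entries(
    entries: pd.DataFrame, config: CurationConfig, audit: CurationAudit | None = None
) -> tuple[pd.DataFrame, AuditStage]:
    """Drop habitat entries whose cover is missing or strictly below the minimum."""
    audit = audit if audit is not None else CurationAudit()
    cover = entries["cover_ha"]
    missing = cover.isna()
    tiny = cover < config.min_area_ha
    entry_id = entries["site_code"].astype(str) + ":" + entries["habitat_code"].astype(str)
    reasons = pd.concat(
        [
            _reasons(entry_id[missing], "cover_missing"),
            _reasons(entry_id[tiny], "cover_below_min"),
        ],
        ignore_index=True,
    )
    stage = audit.add("filter_habitat_entries", len(entries), reasons)
    return entries.loc[~(missing | tiny)].reset_index(drop=True), stage


def join_and_prune(
    sites: pd.DataFrame,
    entries: pd.DataFrame,
    config: CurationConfig,
    audit: CurationAudit | None = None,
) -> CuratedDataset:
    """Join filtered tables on site code and apply the site-level prunes.

    Order within this stage: orphaned entries, zero-area defensive drop,
    habitat-sum >100.01% of site area, BD-only designation. Sites are
    removed together with all their entries; sites without entries stay.
    """
    audit = audit if audit is not None else CurationAudit()

    known = entries["site_code"].isin(set(sites["site_code"]))
    orphans = entries.loc[~known]
    orphan_ids = orphans["site_code"].astype(str) + ":" + orphans["habitat_code"].astype(str)
    audit.add("drop_orphan_entries", len(entries), _reasons(orphan_ids, "site_not_retained"))
    entries = entries.loc[known]

    n_sites_in = len(sites)
    area = sites["total_area_ha"].astype(float)
    zero_area = area == 0
    sums = entries.groupby("site_code")["cover_ha"].sum()
    site_sum = sites["site_code"].map(sums).fillna(0.0).astype(float)
    pct = (100.0 * site_sum / area).round(PERCENT_DECIMALS)
    overfilled = ~zero_area & (pct > config.max_habitat_sum_percent)
    bd_only = (
        (sites["site_type"] == SiteType.BD_ONLY.value) & ~zero_area & ~overfilled
        if config.drop_bd_only
        else pd.Series(False, index=sites.index)
    )
    reasons = pd.concat(
        [
            _reasons(sites.loc[zero_area, "site_code"], "site_area_zero"),
            _reasons(sites.loc[overfilled, "site_code"], "habitat_sum_over_max"),
            _reasons(sites.loc[bd_only, "site_code"], "bd_only_designation"),
        ],
        ignore_index=True,
    )
    audit.add("prune_sites", n_sites_in, reasons)

    dropped_bd_area = float(sites.loc[bd_only, "total_area_ha"].sum())
    keep = ~(zero_area | overfilled | bd_only)
    sites_out = sites.loc[keep].reset_index(drop=True)

    n_entries_in = len(entries)
    entry_keep = entries["site_code"].isin(set(sites_out["site_code"]))
    dropped = entries.loc[~entry_keep]
    audit.add(
        "drop_entries_of_pruned_sites",
        n_entries_in,
        _reasons(
            dropped["site_code"].astype(str) + ":" + dropped["habitat_code"].astype(str),
            "site_pruned",
        ),
    )
    entries_out = entries.loc[entry_keep].reset_index(drop=True)

    return CuratedDataset(
        sites=sites_out,
        entries=entries_out,
        audit=audit,
        dropped_bd_only_area_ha=dropped_bd_area,
    )


def curate(
    sites: pd.DataFrame, entries: pd.DataFrame, config: CurationConfig | None = None
) -> CuratedDataset:
    """Run the full curation pipeline in the fixed order."""
    config = config or CurationConfig()
    audit = CurationAudit()
    sites_f, _ = filter_sites(sites, config, audit)
    entries_f, _ = filter_habitat_entries(entries, config, audit)
    return join_and_prune(sites_f, entries_f, config, audit)
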