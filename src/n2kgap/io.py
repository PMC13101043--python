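"""Readers and writers for the three Natura 2000 tables.

Loading never filters: every data row becomes a record, anomalies
(missing areas, duplicate site codes, unknown region strings) are counted
in the ``LoadReport`` and resolved downstream by the curation and
bioregion modules, so the audit trail stays complete.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .schemas import (
    DEFAULT_SITE_TYPE_ALIASES,
    LoadReport,
    Region,
    SchemaError,
    SiteType,
    TableSchema,
    parse_region,
)

SITES_SCHEMA = TableSchema(
    table_name="NATURA2000SITES",
    columns={
        "site_code": "SITECODE",
        "site_type": "SITETYPE",
        "total_area_ha": "AREAHA",
        "country": "COUNTRY_CODE",
    },
    required=("site_code", "site_type", "total_area_ha"),
)

HABITATS_SCHEMA = TableSchema(
    table_name="HABITATS",
    columns={
        "site_code": "SITECODE",
        "habitat_code": "HABITATCODE",
        "cover_ha": "COVER_HA",
    },
    required=("site_code", "habitat_code", "cover_ha"),
)

BIOREGION_SCHEMA = TableSchema(
    table_name="BIOREGION",
    columns={
        "site_code": "SITECODE",
        "region": "BIOGEFRAPHICREG",  # sic: the official export header
        "percent_of_site": "PERCENTAGE",
    },
    required=("site_code", "region", "percent_of_site"),
)

SITE_COLUMNS = ["site_code", "site_type", "total_area_ha", "country"]
HABITAT_COLUMNS = ["site_code", "habitat_code", "priority", "cover_ha"]
BIOREGION_COLUMNS = ["site_code", "region", "percent_of_site"]


def _read_csv(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema.validate(df)
    df = schema.rename(df)
    return df


def _to_float(series: pd.Series) -> pd.Series:
    """Parse numbers leniently; blanks and non-numeric strings become NaN."""
    return pd.to_numeric(series.replace({"": np.nan, "NA": np.nan}), errors="coerce")


def load_sites(
    path: str | Path,
    schema: TableSchema = SITES_SCHEMA,
    site_type_aliases: dict[str, SiteType] | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read the NATURA2000SITES table.

    Returns one record per input row; missing areas are preserved as NaN
    (never coerced to zero). Duplicate site codes are kept — both rows —
    and counted in the report for the audit log.
    """
    aliases = site_type_aliases or DEFAULT_SITE_TYPE_ALIASES
    df = _read_csv(path, schema)
    report = LoadReport(table_name=schema.table_name, rows_read=len(df))

    out = pd.DataFrame(
        {
            "site_code": df["site_code"].astype(str).str.strip(),
            "site_type": df["site_type"]
            .astype(str)
            .str.strip()
            .str.upper()
            .map(lambda v: aliases.get(v, None)),
            "total_area_ha": _to_float(df["total_area_ha"]),
            "country": df.get("country", pd.Series([""] * len(df))).astype(str).str.strip(),
        }
    )
    unknown_types = out["site_type"].isna() & (len(out) > 0)
    if unknown_types.any():
        bad = sorted(df.loc[unknown_types, "site_type"].unique())
        raise SchemaError(f"unmapped site type code(s) {bad}; extend site_type_aliases")
    out["site_type"] = out["site_type"].map(lambda t: t.value)

    report.missing_area = int(out["total_area_ha"].isna().sum())
    report.duplicate_keys = int(out["site_code"].duplicated().sum())
    if report.duplicate_keys:
        report.notes.append(f"{report.duplicate_keys} duplicate site_code row(s) retained")
    return out[SITE_COLUMNS], report


def normalize_habitat_code(raw: str) -> tuple[str, bool]:
    """Uppercase a 4-character Annex I code and split off the priority '*'."""
    code = str(raw).strip().upper()
    priority = code.endswith("*")
    return code.rstrip("*"), priority


def load_habitats(
    path: str | Path, schema: TableSchema = HABITATS_SCHEMA
) -> tuple[pd.DataFrame, LoadReport]:
    """Read the HABITATS table (one row per site × Annex I habitat).

    A trailing ``*`` on the habitat code is stripped into the boolean
    ``priority`` flag; the 4-character code is the join key.
    """
    df = _read_csv(path, schema)
    report = LoadReport(table_name=schema.table_name, rows_read=len(df))

    codes = df["habitat_code"].map(normalize_habitat_code)
    out = pd.DataFrame(
        {
            "site_code": df["site_code"].astype(str).str.strip(),
            "habitat_code": codes.str[0],
            "priority": codes.str[1],
            "cover_ha": _to_float(df["cover_ha"]),
        }
    )
    report.missing_area = int(out["cover_ha"].isna().sum())
    report.duplicate_keys = int(out.duplicated(subset=["site_code", "habitat_code"]).sum())
    return out[HABITAT_COLUMNS], report


def load_bioregions(
    path: str | Path, schema: TableSchema = BIOREGION_SCHEMA
) -> tuple[pd.DataFrame, LoadReport]:
    """Read the BIOREGION table (site × region, percent of site area).

    Region strings map onto the region enum via a documented alias table;
    unknown strings are kept with region ``Unknown`` and listed in the
    report so no row is silently dropped.
    """
    df = _read_csv(path, schema)
    report = LoadReport(table_name=schema.table_name, rows_read=len(df))

    regions = df["region"].map(parse_region)
    unknown_mask = regions == Region.UNKNOWN
    if unknown_mask.any():
        report.unknown_regions = sorted(df.loc[unknown_mask, "region"].astype(str).unique())
    out = pd.DataFrame(
        {
            "site_code": df["site_code"].astype(str).str.strip(),
            "region": regions.map(lambda r: r.value),
            "percent_of_site": _to_float(df["percent_of_site"]),
        }
    )
    return out[BIOREGION_COLUMNS], report


def write_sites(df: pd.DataFrame, path: str | Path, schema: TableSchema = SITES_SCHEMA) -> None:
    out = df[SITE_COLUMNS].rename(
        columns={k: v for k, v in schema.columns.items() if k in SITE_COLUMNS}
    )
    out.to_csv(path, index=False)


def write_habitats(
    df: pd.DataFrame, path: str | Path, schema: TableSchema = HABITATS_SCHEMA
) -> None:
    # re-attach the priority asterisk so the round-trip is faithful
    code = df["habitat_code"].where(~df["priority"], df["habitat_code"] + "*")
    out = pd.DataFrame(
        {
            schema.columns["site_code"]: df["site_code"],
            schema.columns["habitat_code"]: code,
            schema.columns["cover_ha"]: df["cover_ha"],
        }
    )
    out.to_csv(path, index=False)


def write_bioregions(
    df: pd.DataFrame, path: str | Path, schema: TableSchema = BIOREGION_SCHEMA
) -> None:
    out = df[BIOREGION_COLUMNS].rename(
        columns={k: v for k, v in schema.columns.items() if k in BIOREGION_COLUMNS}
    )
    out.to_csv(path, index=False)
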