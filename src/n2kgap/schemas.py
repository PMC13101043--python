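"""Shared vocabulary for the Natura 2000 tabular model.

Enumerations for site designation types, habitat classes, freshwater
groups, nutrient levels and biogeographic regions, plus the light-weight
``TableSchema`` used to validate CSV exports at load time and the
``LoadReport`` returned by every loader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or a table violates a hard invariant."""


class SiteType(str, Enum):
    """Designation of a Natura 2000 site.

    BD_ONLY: Special Protection Area under the Birds Directive only.
    HD_ONLY: SCI/SAC under the Habitats Directive only.
    BOTH:    boundaries designated under both directives.
    """

    BD_ONLY = "BD_ONLY"
    HD_ONLY = "HD_ONLY"
    BOTH = "BOTH"


#: Mapping from the site-type codes used in official Natura 2000 exports
#: (SITETYPE A/B/C) onto the designation enum. Configurable per load.
DEFAULT_SITE_TYPE_ALIASES: dict[str, SiteType] = {
    "A": SiteType.BD_ONLY,
    "B": SiteType.HD_ONLY,
    "C": SiteType.BOTH,
    "BD_ONLY": SiteType.BD_ONLY,
    "HD_ONLY": SiteType.HD_ONLY,
    "BOTH": SiteType.BOTH,
}


class HabitatClass(str, Enum):
    FRESHWATER = "FRESHWATER"
    MARINE_COASTAL = "MARINE_COASTAL"
    TERRESTRIAL = "TERRESTRIAL"


class FreshwaterGroup(str, Enum):
    RUNNING = "RUNNING"
    STANDING = "STANDING"
    PEATLAND = "PEATLAND"
    FOREST = "FOREST"
    GRASS_HEATH_COASTAL = "GRASS_HEATH_COASTAL"


class Nutrient(str, Enum):
    OLIGOTROPHIC = "OLIGOTROPHIC"
    MESOTROPHIC = "MESOTROPHIC"
    EUTROPHIC = "EUTROPHIC"


class Region(str, Enum):
    """Biogeographic regions appearing in the BIOREGION table."""

    ALPINE = "Alpine"
    ATLANTIC = "Atlantic"
    BLACK_SEA = "BlackSea"
    BOREAL = "Boreal"
    CONTINENTAL = "Continental"
    MACARONESIAN = "Macaronesian"
    MEDITERRANEAN = "Mediterranean"
    PANNONIAN = "Pannonian"
    STEPPIC = "Steppic"
    MARINE_ATLANTIC = "MarineAtlantic"
    MARINE_BALTIC = "MarineBaltic"
    MARINE_BLACK_SEA = "MarineBlackSea"
    MARINE_MACARONESIAN = "MarineMacaronesian"
    MARINE_MEDITERRANEAN = "MarineMediterranean"
    UNKNOWN = "Unknown"


#: The six main terrestrial biogeographic regions of continental Europe.
#: Only these can be assigned to a site and only these appear in inferred
#: natural ranges.
TERRESTRIAL_SIX: frozenset[Region] = frozenset(
    {
        Region.ALPINE,
        Region.ATLANTIC,
        Region.BOREAL,
        Region.CONTINENTAL,
        Region.MEDITERRANEAN,
        Region.PANNONIAN,
    }
)

#: Extended region list used for descriptive counts (includes marine and
#: the minor terrestrial regions), i.e. everything except UNKNOWN.
EXTENDED_REGIONS: frozenset[Region] = frozenset(r for r in Region if r is not Region.UNKNOWN)


def _norm_region_key(raw: str) -> str:
    return "".join(ch for ch in str(raw).lower() if ch.isalnum())


#: Documented alias table for region strings found in exports.
DEFAULT_REGION_ALIASES: dict[str, Region] = {}
for _r in Region:
    DEFAULT_REGION_ALIASES[_norm_region_key(_r.value)] = _r
DEFAULT_REGION_ALIASES.update(
    {
        "black sea": Region.BLACK_SEA,
        "blacksea": Region.BLACK_SEA,
        "marine atlantic": Region.MARINE_ATLANTIC,
        "marineatlantic": Region.MARINE_ATLANTIC,
        "marinebaltic": Region.MARINE_BALTIC,
        "marineblacksea": Region.MARINE_BLACK_SEA,
        "marinemacaronesian": Region.MARINE_MACARONESIAN,
        "marinemediterranean": Region.MARINE_MEDITERRANEAN,
    }
)


def parse_region(raw: str) -> Region:
    """Map an export region string onto the enum; unknown strings → UNKNOWN."""
    return DEFAULT_REGION_ALIASES.get(_norm_region_key(raw), Region.UNKNOWN)


@dataclass
class TableSchema:
    """Declares the columns a CSV export must provide.

    ``columns`` maps logical names (the names the pipeline uses) onto the
    actual header names of a given export dialect, absorbing casing and
    naming drift between official export versions.
    """

    table_name: str
    columns: dict[str, str]
    required: tuple[str, ...]

    def validate(self, df: pd.DataFrame) -> None:
        missing = [
            self.columns[logical]
            for logical in self.required
            if self.columns[logical] not in df.columns
        ]
        if missing:
            raise SchemaError(
                f"table {self.table_name!r}: missing required column(s) {missing}; "
                f"found {list(df.columns)}"
            )

    def rename(self, df: pd.DataFrame) -> pd.DataFrame:
        """Return a copy with actual header names replaced by logical names."""
        inverse = {actual: logical for logical, actual in self.columns.items()}
        return df.rename(columns=inverse)


@dataclass
class LoadReport:
    """Per-table load accounting; counts refer to data rows, never dropped."""

    table_name: str
    rows_read: int = 0
    missing_area: int = 0
    duplicate_keys: int = 0
    unknown_regions: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "table_name": self.table_name,
            "rows_read": self.rows_read,
            "missing_area": self.missing_area,
            "duplicate_keys": self.duplicate_keys,
            "unknown_regions": list(self.unknown_regions),
            "notes": list(self.notes),
        }
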