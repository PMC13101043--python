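"""Natural-range inference via the European Red List of Habitats crosswalk.

Each Annex I habitat is linked to one or more Red List (RL) habitats by
expert crosswalk rows carrying a relation category. A habitat's inferred
natural range is the union of the terrestrial region sets of all its
linked RL habitats; an RL habitat without a stated region set
(``UNSPECIFIED``) is assumed to occur in all six regions. This is the
deliberately inclusive reading — it can only overestimate a range, never
miss a region — and a strict mode (same/close links only) bounds the
overestimation from the other side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .schemas import Region, SchemaError, TERRESTRIAL_SIX

#: The five crosswalk relation categories, in decreasing match strength.
DEFAULT_RELATIONS: tuple[str, ...] = ("same", "close", "narrower", "wider", "low_importance")

#: Relations retained in strict mode.
STRICT_RELATIONS: frozenset[str] = frozenset({"same", "close"})

ALL_SIX: frozenset[str] = frozenset(r.value for r in TERRESTRIAL_SIX)

UNSPECIFIED = "UNSPECIFIED"


class NoCrosslink(KeyError):
    """The Annex I code has no row in the crosswalk."""


@dataclass
class RangeOptions:
    """Switches for range inference.

    include_low_importance: keep low-importance links (the inclusive
        default); disabling them can only shrink ranges.
    strict: use only same/close links, overriding the above.
    baltic_additions: codes whose range always gains fixed regions
        (Baltic-associated habitats occur in both the Boreal and
        Continental regions regardless of their RL links).
    """

    include_low_importance: bool = True
    strict: bool = False
    baltic_additions: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "1650": frozenset({Region.BOREAL.value, Region.CONTINENTAL.value})
        }
    )

    def active_relations(self, known: tuple[str, ...]) -> frozenset[str]:
        if self.strict:
            return STRICT_RELATIONS & set(known)
        keep = set(known)
        if not self.include_low_importance:
            keep.discard("low_importance")
        return frozenset(keep)


def default_crosswalk_path() -> Path:
    return Path(str(resources.files("n2kgap").joinpath("data/rl_crosswalk.csv")))


def default_rl_regions_path() -> Path:
    return Path(str(resources.files("n2kgap").joinpath("data/rl_regions.csv")))


def load_crosswalk(
    path: str | Path | None = None,
    regions_path: str | Path | None = None,
    relations: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict[str, frozenset[str] | str]]:
    """Load the crosswalk and the RL-habitat region table.

    The relation label set is data-driven: by default the five shipped
    categories, overridable for crosswalk files using other wording.
    Unknown labels and duplicate (annex_code, rl_code) pairs are hard
    errors; region names outside the six-region universe likewise.
    """
    path = Path(path) if path is not None else default_crosswalk_path()
    regions_path = Path(regions_path) if regions_path is not None else default_rl_regions_path()
    known_relations = relations or DEFAULT_RELATIONS

    links = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("annex_code", "rl_code", "relation", "include"):
        if col not in links.columns:
            raise SchemaError(f"crosswalk file missing column {col!r}")
    links["annex_code"] = links["annex_code"].str.strip().str.upper().str.rstrip("*")
    bad = set(links["relation"]) - set(known_relations)
    if bad:
        raise SchemaError(f"unknown crosswalk relation label(s): {sorted(bad)}")
    dup = links.duplicated(subset=["annex_code", "rl_code"])
    if dup.any():
        pairs = links.loc[dup, ["annex_code", "rl_code"]].to_records(index=False).tolist()
        raise SchemaError(f"duplicate crosswalk pair(s): {pairs}")
    links["include"] = links["include"].astype(int).astype(bool)

    regions_df = pd.read_csv(regions_path, dtype=str, keep_default_na=False)
    rl_regions: dict[str, frozenset[str] | str] = {}
    for row in regions_df.itertuples():
        if row.regions.strip() == UNSPECIFIED:
            rl_regions[row.rl_code] = UNSPECIFIED
            continue
        regs = frozenset(s.strip() for s in row.regions.split(";") if s.strip())
        unknown = regs - ALL_SIX
        if unknown:
            raise SchemaError(f"RL habitat {row.rl_code}: regions outside the six-region universe: {sorted(unknown)}")
        rl_regions[row.rl_code] = regs
    return links, rl_regions


def infer_range(
    annex_code: str,
    crosslinks: pd.DataFrame,
    rl_regions: dict[str, frozenset[str] | str],
    options: RangeOptions | None = None,
) -> frozenset[str]:
    """Infer a habitat's natural terrestrial range (set of region values).

    Union over the region sets of all linked RL habitats that pass the
    relation/include filters; any linked RL habitat with UNSPECIFIED
    regions expands the union to all six. Raises :class:`NoCrosslink`
    for codes absent from the crosswalk.
    """
    options = options or RangeOptions()
    code = annex_code.strip().upper().rstrip("*")
    rows = crosslinks[crosslinks["annex_code"] == code]
    if rows.empty:
        raise NoCrosslink(code)

    active = options.active_relations(tuple(crosslinks["relation"].unique()))
    rows = rows[rows["include"] & rows["relation"].isin(active)]

    out: set[str] = set()
    for rl_code in rows["rl_code"]:
        regs = rl_regions.get(rl_code, UNSPECIFIED)
        if regs == UNSPECIFIED:
            return frozenset(ALL_SIX | options.baltic_additions.get(code, frozenset()))
        out |= regs
    out |= options.baltic_additions.get(code, frozenset())
    return frozenset(out)


def infer_all_ranges(
    crosslinks: pd.DataFrame,
    rl_regions: dict[str, frozenset[str] | str],
    options: RangeOptions | None = None,
) -> dict[str, frozenset[str]]:
    """Inferred range for every Annex I code present in the crosswalk."""
    return {
        code: infer_range(code, crosslinks, rl_regions, options)
        for code in sorted(crosslinks["annex_code"].unique())
    }
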