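"""Annex I habitat classification: class, freshwater group, nutrient level.

The assignments live in a shipped, versioned CSV
(``data/habitat_taxonomy.csv``) rather than in code, so disagreements
with the expert tables stay diffable. Freshwater habitats here are the
broad definition: strict freshwater codes (3xxx) plus groundwater-
dependent terrestrial ecosystems — bogs, mires and fens, wet forests,
wet heath and grassland, and two coastal/halophytic types (estuaries and
Boreal Baltic inlets). Every freshwater code carries one of five groups
(running, standing, peatland, forest, grass/heath/coastal) and one of
three nutrient levels (oligo-, meso-, eutrophic); non-freshwater codes
carry neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .schemas import FreshwaterGroup, HabitatClass, Nutrient, SchemaError


class UnclassifiedCode(KeyError):
    """Lookup of a habitat code absent from the taxonomy table."""


@dataclass(frozen=True)
class HabitatClassification:
    habitat_code: str
    habitat_class: HabitatClass
    freshwater_group: FreshwaterGroup | None
    nutrient: Nutrient | None
    source_note: str = ""


class TaxonomyTable:
    """Total mapping habitat_code → classification over the shipped codes."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.set_index("habitat_code", drop=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, code: str) -> bool:
        return code in self.frame.index

    @property
    def codes(self) -> list[str]:
        return list(self.frame.index)

    def get(self, code: str) -> HabitatClassification | None:
        if code not in self.frame.index:
            return None
        row = self.frame.loc[code]
        fw = row["habitat_class"] == HabitatClass.FRESHWATER.value
        return HabitatClassification(
            habitat_code=code,
            habitat_class=HabitatClass(row["habitat_class"]),
            freshwater_group=FreshwaterGroup(row["freshwater_group"]) if fw else None,
            nutrient=Nutrient(row["nutrient"]) if fw else None,
            source_note=row.get("source_note", ""),
        )


def default_taxonomy_path() -> Path:
    return Path(str(resources.files("n2kgap").joinpath("data/habitat_taxonomy.csv")))


def load_taxonomy(path: str | Path | None = None) -> TaxonomyTable:
    """Load and validate a taxonomy CSV (code,class,group,nutrient,source_note).

    Hard errors: duplicate codes; freshwater rows missing group or
    nutrient; non-freshwater rows carrying either; unknown enum labels.
    """
    path = Path(path) if path is not None else default_taxonomy_path()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"habitat_code", "habitat_class", "freshwater_group", "nutrient"}
    if not required.issubset(df.columns):
        raise SchemaError(f"taxonomy file missing columns {sorted(required - set(df.columns))}")
    if "source_note" not in df.columns:
        df["source_note"] = ""

    df["habitat_code"] = df["habitat_code"].str.strip().str.upper().str.rstrip("*")
    dup = df["habitat_code"][df["habitat_code"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate habitat code(s) in taxonomy: {sorted(dup.unique())}")

    valid_classes = {c.value for c in HabitatClass}
    bad = set(df["habitat_class"]) - valid_classes
    if bad:
        raise SchemaError(f"unknown habitat class label(s): {sorted(bad)}")

    fw = df["habitat_class"] == HabitatClass.FRESHWATER.value
    missing_group = fw & (
        ~df["freshwater_group"].isin({g.value for g in FreshwaterGroup})
        | ~df["nutrient"].isin({n.value for n in Nutrient})
    )
    if missing_group.any():
        codes = sorted(df.loc[missing_group, "habitat_code"])
        raise SchemaError(f"freshwater code(s) missing/invalid group or nutrient: {codes}")
    stray = ~fw & ((df["freshwater_group"] != "") | (df["nutrient"] != ""))
    if stray.any():
        codes = sorted(df.loc[stray, "habitat_code"])
        raise SchemaError(f"non-freshwater code(s) carrying group/nutrient: {codes}")

    return TaxonomyTable(df)


def classify(code: str, table: TaxonomyTable) -> HabitatClassification:
    """Deterministic lookup of a normalized (uppercase, no '*') code.

    Raises :class:`UnclassifiedCode` rather than defaulting silently.
    """
    result = table.get(code)
    if result is None:
        raise UnclassifiedCode(code)
    return result


def attach_classifications(entries: pd.DataFrame, table: TaxonomyTable) -> tuple[pd.DataFrame, list[str]]:
    """Annotate habitat entries with class, group and nutrient columns.

    Returns the annotated frame and the sorted list of codes the table
    does not cover (their rows keep empty-string annotations; the caller
    decides whether that is a drop or a hard failure).
    """
    tax = table.frame[["habitat_class", "freshwater_group", "nutrient"]]
    out = entries.merge(tax, left_on="habitat_code", right_index=True, how="left")
    unclassified = sorted(out.loc[out["habitat_class"].isna(), "habitat_code"].unique())
    for col in ("habitat_class", "freshwater_group", "nutrient"):
        out[col] = out[col].fillna("")
    return out.reset_index(drop=True), unclassified
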