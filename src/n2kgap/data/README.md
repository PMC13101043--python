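# Shipped reference tables

- `habitat_taxonomy.csv` — classification of the 233 Annex I habitat codes
  into freshwater / marine & coastal / terrestrial, with a freshwater group
  and a nutrient level for every freshwater code. The broad freshwater
  definition includes groundwater-dependent terrestrial ecosystems (bogs,
  mires, fens, wet forests, wet heath/grassland, estuaries and Boreal
  Baltic inlets). `source_note` records provenance per row:
  `eunis_description` (nutrient level stated in the EUNIS habitat
  description), `stated` (assignment documented in the
  literature for the 2021 database), or `reconstructed` (assigned here from habitat
  descriptions; treat as a curatable default, not an authority).
- `rl_crosswalk.csv` — expert crosswalk between Annex I codes and European
  Red List of Habitats codes, with one of five relation categories
  (`same`, `close`, `narrower`, `wider`, `low_importance`) and an
  inclusion flag. Rows not documented in the literature are
  reconstructions with the same caveat as above. The two codes linked to
  more than 20 Red List habitats (1130 Estuaries, 1650 Boreal Baltic
  inlets) are shipped as single pre-aggregated pseudo-rows
  (`RL-AGG-1130`, `RL-AGG-1650`) carrying the union of their relevant
  terrestrial regions.
- `rl_regions.csv` — terrestrial biogeographic regions typical for each
  Red List habitat; `UNSPECIFIED` means the habitat occurs in all six
  regions (the inclusive default).
- `region_overrides.csv` — site-specific corrections applied instead of
  the deterministic sole-region-0% rule (the documented case BE2200036:
  79% Atlantic, remainder Continental).

All files are plain CSV and are meant to be replaced wholesale by users
holding the authoritative expert tables; loaders validate structure, not
provenance.
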