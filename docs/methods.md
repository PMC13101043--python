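# Methods

## Data model

The analysis is purely tabular. Three input tables describe the network:

- **sites** (`NATURA2000SITES`): site code, designation type (BD-only /
  HD-only / both, mapped from the A/B/C codes of official exports),
  total area in hectares, optional country code.
- **habitat entries** (`HABITATS`): one row per (site, Annex I habitat)
  with cover in hectares. A trailing `*` on a habitat code marks a
  priority habitat; it is metadata, not part of the join key, so `7310*`
  and `7310` refer to the same habitat type.
- **bioregions** (`BIOREGION`): one row per (site, biogeographic
  region) with the percent of the site's area in that region, over nine
  terrestrial and five marine regions.

Loading never filters. Anomalies (missing areas, duplicate codes,
unknown region strings) are counted in a `LoadReport` and resolved by
later stages, so the stepwise record counts of the curation audit are
reproducible from the raw exports. Column headers are configurable via
`TableSchema` because export dialects drift; the defaults match the
official 2021 headers (including the misspelt `BIOGEFRAPHICREG`).

## Curation

Rules are applied in a fixed order with one audit stage each:

1. drop sites with missing total area or area < `min_area_ha`
   (default 0.0001 ha; the comparison is strict, equality keeps);
2. drop habitat entries with missing or < `min_area_ha` cover;
3. after joining on site code: drop orphaned entries; defensively drop
   zero-area sites (the percent below would be undefined); drop sites
   where 100 × Σ cover / site area > `max_habitat_sum_percent`
   (default 100.01); drop BD-only sites.

The habitat-cover percentage is computed from curated covers in
hectares, not from any percent column of the export, and is rounded to
six decimals before the threshold comparison so binary representation
noise cannot flip a record at the 100.01 boundary. The order matters:
filtering entries first means a tiny entry can no longer push a site
past the overfill threshold; the pipeline fixes this order and tests
assert it stays idempotent (curating a curated dataset drops nothing).

Sites with zero habitat entries are retained — their area is the
"not mapped as protected habitats" share of the coverage summary — and
the summed area of removed BD-only sites is kept on the dataset because
whole-network denominators need it.

## Habitat taxonomy

The shipped table (`data/habitat_taxonomy.csv`) classifies all 233
Annex I codes. Freshwater is defined broadly: strict freshwater codes
(3xxx) plus groundwater-dependent terrestrial ecosystems — the twelve
peatland codes (7xxx), eight wet-forest codes (9080, 91D0, 91E0, 91F0,
92A0–92D0), wet heath (4010, 4020), wet/alluvial grasslands (6410,
6430–6460, 6540), humid dune slacks (2190) and two coastal/halophytic
types (1130 estuaries, 1650 Boreal Baltic inlets). After excluding the
two types occurring only in Croatia (32A0, 6540; absent from analyses
because Croatian cover data are missing), the group sizes are 9 running,
10 standing, 12 peatland and 8 forest types, matching the documented
group tallies for the 2021 database.

Nutrient levels follow a source hierarchy — EUNIS habitat description,
then the European Red List of Habitats, then vegetation descriptions —
and each row carries a provenance tag. Rows tagged `reconstructed` were
assigned here from habitat descriptions and should be treated as
curatable defaults rather than authority; the loaders validate only
structure (uniqueness, completeness of group/nutrient for freshwater
rows) so the table can be replaced wholesale.

## Biogeographic region assignment

Only the six main terrestrial regions of continental Europe (Alpine,
Atlantic, Boreal, Continental, Mediterranean, Pannonian) can be
assigned; the minor terrestrial regions (Black Sea, Macaronesian,
Steppic) and the marine regions never qualify a site, because they
either cover a very small area or represent marine habitat. Duplicate
(site, region) rows are summed before evaluation.

The source table contains a known recording error: sites entirely
within one region sometimes report 0 %. The deterministic correction
sets the percent to 100 for sites whose records consist of exactly one
region at 0 %; sites with several regions, one of them 0 %, are
ambiguous and left alone. An overrides CSV handles cases where 100 is
wrong (the shipped default encodes the documented case BE2200036 →
Atlantic 79 %). Historically these corrections were made after visual
inspection; replacing inspection with rule + override file keeps
the step reproducible, and any residual disagreements belong in the
overrides file as data.

Assignment then takes the region holding ≥ `min_fraction` percent
(default 70), else the region whose reported percentage equals 100
(threshold-independent by design; two regions both at 100 is a data
error and resolves to NA), else NA. NA entries are excluded from
per-region tallies but stay in all area and count totals. Raising
`min_fraction` can only turn assignments into NA, never switch regions —
a property the tests assert.

## Natural ranges from the Red List crosswalk

Each freshwater Annex I code links to one or more European Red List
habitats with a relation category (`same`, `close`, `narrower`,
`wider`, `low_importance`; the label set is data-driven at load). The
inferred natural range is the union of the linked RL habitats' region
sets; `UNSPECIFIED` expands to all six regions. Defaults are inclusive
— low-importance links count — because missing a natural region is the
worse error for a gap analysis; the price is possible overestimation of
ranges, which the strict mode (same/close only) bounds from the other
side. Two codes linked to more than 20 RL habitats each (1130, 1650)
ship as pre-aggregated pseudo-rows carrying their terrestrial-region
union, and Baltic-associated habitats always include Boreal and
Continental (exposed as the `baltic_additions` option).

## Summaries and the gap statistic

Coverage percentages use the summed area of retained HD-designated
sites as denominator; the whole-network freshwater share additionally
counts the removed BD-only area. Group and nutrient shares are over
freshwater habitat area only; nutrient site counts record
(site, nutrient) presence, so a site hosting oligotrophic and eutrophic
habitats increments both. Size classes are half-open, `[0, 50)`,
`[50, 500)`, `[500, ∞)` hectares. Per-habitat site counts are distinct
site codes post-curation, before NA-region exclusion (NA affects only
regional tallies).

For habitat *h* with observed regions *O(h)* and natural range *N(h)*,
the representation proportion is |O ∩ N| / |N|; it lies in [0, 1] and
equals 1 exactly when *N ⊆ O*. Codes without a usable natural range are
excluded from tallies and reported. Two region-counting modes are
separate outputs on purpose: the gap analysis is terrestrial-only,
while descriptive per-habitat region counts may use the extended list
including marine regions — conflating the two is the likeliest
implementation bug, so the interface forces the choice.

## Synthetic data

The generator emulates the structure of the 2021 database, not its
joint distributions (no country effects or spatial autocorrelation).
Defaults: 27,031 sites; type mix 17 % BD-only / 60 % HD-only / 23 %
both (documented area shares for the 2021 database are 40.1/47.6/12.3 but
type counts are not; the mix is chosen once so that BD-only pruning removes
roughly the observed number of sites); site areas log-normal
(μ = 5.0, σ = 2.5 log-ha, floored at 0.01 ha, giving ≈ one third of
sites below 50 ha); habitats per site Poisson(5.65) deduplicated per
site, ≈ 150k entries; covers allocated as exponential-weighted
fractions of 20–90 % of site area (120–180 % for overfilled sites);
single-region sites at 100 % except the planted anomaly classes.
Anomaly rates mirror the frequencies implied by the stepwise counts of
the 2021 snapshot: missing site area 0.3 %, tiny site area 0.1 %
(together ≈ 106/27,031), missing cover 4.5 % + tiny cover 0.4 %
(≈ 7,497/152,750), overfilled 1 %, sole-region-0 % 1.38 %
(≈ 373/27,031), multi-region split 5 %.

Site-level anomalies are planted disjointly — one categorical draw per
site — so every expected count is Binomial(n, rate) across seeds and
the ground truth follows by direct construction; entry-level anomalies
are planted only on anomaly-free sites so the counts add. An entangled
mode (overlapping anomalies) was considered and dropped: its ground
truth would have to be computed by re-running pipeline logic, which
destroys the independence that makes the planted-count test meaningful.
The expected gap proportions in the ground truth are computed by a
separate brute-force union over the crosswalk rows, independent of the
range-inference module.

Passing tests on synthetic data show the pipeline's bookkeeping and set
arithmetic are exact under the stated data model; they do not validate
the shipped expert tables against real expert judgment, nor the
behaviour under anomaly classes the generator does not plant (e.g.
inconsistent duplicate site rows with conflicting areas). Because
habitat codes and regions are drawn independently, at database scale
every habitat ends up observed in every region and gap proportions
saturate near 1 — the synthetic gap statistics exercise the arithmetic,
not the real network's representation levels, which depend on the
spatially clustered distributions the generator deliberately omits.

## Problem sizes and numerical choices

Tests run the generator at 100–1,000 sites (seconds); the acceptance
script runs the full default scale (~27k sites, ~150k entries, under a
minute on one CPU). Percentages are computed at full precision and
rendered to one decimal only for display. Ties and degenerate inputs
are resolved explicitly: empty tables produce empty summaries and a
successful run; a zero total HD area is a hard error for coverage (no
denominator); two regions at 100 % → NA; unclassified habitat codes are
reported, never silently defaulted.

## Known limitations

- The shipped taxonomy/crosswalk tables are partially reconstructed
  (see `src/n2kgap/data/README.md`); analyses on real exports should
  substitute authoritative expert tables where available.
- BD-only detection uses the site-type field as a tabular proxy; no
  geometric overlap between SPA and SCI/SAC boundaries is computed,
  and no spatial formats are read.
- The 70 %/MAX100 assignment discards genuine multi-region sites; their
  habitat entries are NA in regional tallies, which biases observed
  region sets downward for habitats concentrated on such sites.
- Range inference inherits the inclusive crosswalk reading; inferred
  ranges are upper bounds, so representation proportions are
  conservative (biased low).
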