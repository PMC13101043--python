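# n2kgap

Coverage and biogeographic representation-gap analysis of freshwater
Annex I habitats in the Natura 2000 network.

## The problem

The Natura 2000 network is the EU's backbone for biodiversity
conservation: ~27,000 sites designated under the Habitats Directive (HD;
SCIs/SACs) and the Birds Directive (BD; SPAs). Whether the network can
support freshwater restoration under the Nature Restoration Regulation
depends on two measurable things:

1. **Coverage** — how much of the network's area is designated as
   freshwater habitat (running and standing waters, peatlands, wet
   forests, and groundwater-dependent grassland/heath/coastal habitats)?
2. **Representation** — is each freshwater habitat type designated in
   every biogeographic region of its natural range? A region in the
   natural range with no designated site is a *representation gap*, the
   spatial component of the "favorable reference area" concept.

`n2kgap` implements this analysis as a reusable, auditable pipeline over
the tabular Natura 2000 database exports (`NATURA2000SITES`, `HABITATS`,
`BIOREGION`). It is a library first — the importable API plus the short
narrative scripts in `examples/` are the main interface — with a thin
`n2kgap` CLI for shell use.

## The method

**Curation** applies the exclusion rules in a fixed order, logging every
drop: sites with missing area or area < 0.0001 ha; habitat entries with
missing cover or cover < 0.0001 ha; after joining on site code, sites
whose habitat covers sum to > 100.01 % of site area, and BD-only sites
(their Annex I habitats were not part of the designation). Audit stages
always satisfy `out = in − dropped`.

**Classification** assigns each of the 233 Annex I codes a class
(freshwater / marine & coastal / terrestrial); freshwater codes further
carry one of five groups (running, standing, peatland, forest,
grass/heath/coastal) and a nutrient level (oligo-/meso-/eutrophic). The
tables ship as versioned CSVs under `src/n2kgap/data/` (see the README
there for provenance).

**Region assignment** gives each site at most one of the six main
terrestrial biogeographic regions *r* with site share *p_r*:

    region(site) = r   if p_r ≥ 70 %,  else r if max_r p_r = 100 %,  else NA

after deterministically correcting sole-region records reported as 0 %
to 100 % (with an explicit override file for known exceptions). Marine
and minor terrestrial regions never qualify a site.

**Range inference** builds each freshwater habitat's natural range from
its European Red List of Habitats crosslinks: the union of the linked RL
habitats' terrestrial region sets, where an unspecified set means all
six regions (the inclusive reading; a strict mode restricts to
same/close links).

**Gap analysis** compares observed regions *O(h)* (regions with at least
one site designating habitat *h*) with the natural range *N(h)*:

    proportion(h) = |O(h) ∩ N(h)| / |N(h)|,    fully represented ⇔ N(h) ⊆ O(h)

**Synthetic data**: `n2kgap.generate` produces database-shaped tables
with planted anomalies (missing/tiny areas and covers, overfilled sites,
BD-only sites, sole-region-0 % rows, multi-region splits) and a ground
truth computed by construction, so the whole pipeline is testable
without any download.

## Worked example

`examples/02_worked_fixture_summaries.py` runs the pipeline on a
six-site fixture whose every expected number is hand-computed:

```
HD-designated area:        1400 ha
mapped as habitats:        56.4%  (hand: 56.4%)
  freshwater:              51.4%
  marine & coastal:        3.6%
  terrestrial:             1.4%
freshwater % of network:   49.7%
```

The fixture's six sites exercise every rule once: a BD-only site and an
overfilled site are dropped (4 of 6 survive curation), a sole-region-0 %
site is corrected to 100 % Atlantic, and a 60/40 split site resolves to
NA so its peatland entry is excluded from regional tallies. The gap
table from `examples/03_range_inference_gap.py`:

```
habitat_code freshwater_group observed_regions  n_natural  proportion  fully_represented
        3150         STANDING         Atlantic          6    0.166667              False
        3260          RUNNING      Continental          6    0.166667              False
        7110         PEATLAND      Continental          4    0.250000              False
        7310         PEATLAND                           2    0.000000              False
        91E0           FOREST      Continental          6    0.166667              False
        92D0           FOREST    Mediterranean          1    1.000000               True
```

92D0 (southern riparian galleries) is designated in its single natural
region (Mediterranean), so it is fully represented; 7310 (aapa mires)
sits only on the NA-region site, so none of its two natural regions is
covered.

The other examples show the curation audit on synthetic data
(`01_curation_audit.py`, with pipeline counts matching the planted
ground truth exactly) and the per-site JSON export
(`04_site_report.py`).

To run the pipeline on real database exports:

```sh
n2kgap run-all --sites NATURA2000SITES.csv --habitats HABITATS.csv \
    --bioregions BIOREGION.csv --out-dir report/
```

## Layout

- `src/n2kgap/` — `io` (table loaders), `curation`, `taxonomy`,
  `bioregion`, `redlist`, `summaries`, `synth`, `pipeline`, `cli`
- `src/n2kgap/data/` — shipped classification/crosswalk tables
- `examples/` — one narrative script per capability
- `docs/methods.md` — the model, parameters and design decisions
- `tests/` — unit, property and acceptance suites
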