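"""Run the full pipeline on the six-site worked fixture.

The fixture exercises every rule once (one BD-only site, one overfilled
site, one sole-region-0% site, one unresolvable-region site, one
multi-habitat freshwater site, one tiny-cover entry) and all expected
summaries are hand-computed. The printed coverage percentages use the
area of sites designated under the Habitats Directive as denominator;
the whole-network figure additionally counts the removed BD-only area.
"""

import n2kgap as g

sites, habitats, bioregions, expected = g.make_worked_fixture()
bundle = g.run_pipeline(sites=sites, habitats=habitats, bioregions=bioregions)

cov = bundle.coverage
print(f"HD-designated area:        {cov.total_hd_area_ha:.0f} ha")
print(f"mapped as habitats:        {cov.mapped_percent:.1f}%  (hand: {expected['mapped_percent']:.1f}%)")
print(f"  freshwater:              {cov.class_percent['FRESHWATER']:.1f}%")
print(f"  marine & coastal:        {cov.class_percent['MARINE_COASTAL']:.1f}%")
print(f"  terrestrial:             {cov.class_percent['TERRESTRIAL']:.1f}%")
print(f"freshwater % of network:   {cov.freshwater_percent_of_network:.1f}%")
print()
print("freshwater group shares (% of freshwater habitat area):")
print(bundle.group_shares.to_string(index=False))
print()
print("nutrient summary (site counts follow (site, nutrient) presence):")
print(bundle.nutrient.to_string(index=False))
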