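"""Infer natural biogeographic ranges and quantify representation gaps.

A habitat's natural range is the union of the terrestrial region sets of
its linked European Red List habitats (an unspecified region set means
all six regions). The gap analysis then compares the regions where the
network actually designates the habitat against that range: the
proportion is |observed ∩ natural| / |natural|, and a habitat is fully
represented when the natural range is a subset of the observed regions.
"""

import n2kgap as g

links, rl_regions = g.load_crosswalk()

for code in ("3120", "3160", "7310", "92D0", "1650"):
    inclusive = g.infer_range(code, links, rl_regions)
    strict = g.infer_range(code, links, rl_regions, g.RangeOptions(strict=True))
    print(f"{code}: natural range {sorted(inclusive)}")
    if strict != inclusive:
        print(f"      strict (same/close links only): {sorted(strict)}")

print()
sites, habitats, bioregions, expected = g.make_worked_fixture()
bundle = g.run_pipeline(sites=sites, habitats=habitats, bioregions=bioregions)
cols = ["habitat_code", "freshwater_group", "observed_regions", "n_natural",
        "proportion", "fully_represented"]
print(bundle.gap[cols].to_string(index=False))
print()
print("fully represented per group:")
print(bundle.gap_tally.to_string(index=False))
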