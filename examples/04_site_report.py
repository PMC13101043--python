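"""Export the per-site JSON document used by webtool-style report views.

The document lists a site's designated habitats grouped by class, each
with its cover in hectares and as a percent of the site's area.
"""

import json

import n2kgap as g

sites, habitats, bioregions, _ = g.make_worked_fixture()
bundle = g.run_pipeline(sites=sites, habitats=habitats, bioregions=bioregions)

doc = g.export_site_json(bundle.curated.sites, bundle.entries_classified, "DE0001")
print(json.dumps(doc, indent=2, sort_keys=True))
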