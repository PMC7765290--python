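"""Define the full hand-scoring instrument and a reduced variant.

The full instrument reads six features at two sites in each of the 12
small hand joints (MCP/PIP/DIP of digits 2-5): 144 ordinal items.
Restricting it to the three most change-responsive joints leaves 36.
"""

from psamris import (
    build_full_schema,
    build_reduced_schema,
    enumerate_items,
    max_total_score,
    validate_item,
)

full = build_full_schema()
print(f"{full.name}: {len(full.joints)} joints x {full.sites_per_joint} sites "
      f"x {len(full.features)} features = {full.item_count} items "
      f"(max total score {max_total_score(full)})")

simplified = build_reduced_schema(full, ["MCP3", "MCP4", "PIP4"], name="sPsAMRIS")
print(f"{simplified.name}: {len(simplified.joints)} joints -> "
      f"{simplified.item_count} items (max total {max_total_score(simplified)})")

first_site, first_feature = enumerate_items(full)[0]
print(f"first item in reading order: {first_site.token} / {first_feature.name} "
      f"(range {first_feature.score_min}-{first_feature.score_max})")

check = validate_item(full, "MCP3", "site_A", "synovitis", 4)
print(f"validating synovitis=4 -> ok={check.ok}: {check.message}")
# A synovitis reading of 4 exceeds the 0-3 range, so the record is rejected.
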