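"""Point-based ACMG/AMP classification of the bundled discordant variants.

Parses each variant's evidence tokens, sums the signed points
(supporting/moderate/strong/very-strong = 1/2/4/8, negative for benign
codes) and maps the total onto the five tiers (PV >= 10, LPV 6..9,
VUS -1..5, LBV -6..-2, BV <= -7).
"""

from sgecurate import classify_variant
from sgecurate.datasets import load_discordant_variants

records = load_discordant_variants()
print(f"{'variant':<14} {'evidence':<28} {'points':>6}  class")
for rec in records:
    result = classify_variant(list(rec.evidence))
    tokens = ", ".join(c.label for c in rec.evidence)
    print(f"{rec.variant_id:<14} {tokens:<28} {result.total_points:>6}  {result.label}")
# Each line shows the aggregated evidence points and the resulting
# five-tier classification; e.g. c.8991T>G scores 8+1+4 = 13 -> PV.
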