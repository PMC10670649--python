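"""From linguistic weight terms to crisp normalized criterion weights.

The 15 study criteria carry verbal importance terms on a five-level
triangular fuzzy scale.  Each term's fuzzy number is collapsed with the
Yager centroid (a + b + c) / 3 and the crisp values are normalized to
sum to 1 — these are the weights w_k entering the preference index.
"""

from fpromethee import normalize_weights, yager_defuzzify
from fpromethee.synthetic import replicate_uti_design

criteria, _ = replicate_uti_design()
crisp = [yager_defuzzify(spec.to_criterion().weight) for spec in criteria]
weights = normalize_weights(crisp)

print(f"{'id':<4} {'criterion':<36} {'term':<10} {'crisp':>6} {'w_k':>7}")
for spec, c, w in zip(criteria, crisp, weights.values):
    print(f"{spec.id:<4} {spec.name:<36} {spec.weight_label:<10} {c:>6.3f} {w:>7.4f}")
print(f"\nsum of normalized weights: {sum(weights.values):.12f}")
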