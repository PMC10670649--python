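"""Rank a synthetic 16-test UTI study with fuzzy PROMETHEE II.

Draws a decision matrix with the statistical structure of the UTI
diagnostic-test study (16 tests x 15 weighted criteria), runs the full
outranking pipeline and prints the complete ranking: for each test its
net flow Phi_net = Phi+ - Phi-, where Phi+ averages how strongly the
test is preferred over the other 15 and Phi- how strongly they are
preferred over it.  Positive net flow = above-average overall appeal.
"""

from fpromethee import run_full_analysis
from fpromethee.synthetic import generate_matrix, uti_study_config

matrix = generate_matrix(uti_study_config(seed=7))
result = run_full_analysis(matrix)

print(f"{'rank':>4}  {'UTI test':<30} {'Phi_net':>8} {'Phi+':>8} {'Phi-':>8}")
idx = {lab: i for i, lab in enumerate(result.flows.alternatives)}
for rank, label, net in result.ranking.rows:
    i = idx[label]
    print(
        f"{rank:>4}  {label:<30} {net:>8.4f} "
        f"{result.flows.phi_plus[i]:>8.4f} {result.flows.phi_minus[i]:>8.4f}"
    )
print(f"\nsum of net flows (always 0): {result.flows.phi_net.sum():.2e}")
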