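"""Check the published UTI ranking tables' flow arithmetic.

The study's expert decision matrix was never published, but its flow
tables were.  Feeding the printed Phi+ and Phi- columns through
Phi_net = Phi+ - Phi- must reproduce the printed net column; two rows of
the complete-ranking table carry a one-unit discrepancy in the fourth
decimal (print rounding), every other row agrees exactly.
"""

import numpy as np

from fpromethee import load_reference_flows, net_flow

for which, title in (("full", "complete ranking"), ("sensitivity", "after omitting C1, C2")):
    ref = load_reference_flows(which)
    recomputed = net_flow(ref["phi_plus"].to_numpy(), ref["phi_minus"].to_numpy())
    delta = np.abs(recomputed - ref["phi_net"].to_numpy())
    print(f"{title}:")
    print(f"  rows agreeing at 4 decimals : {int((delta < 5e-5).sum())}/16")
    print(f"  max |printed - recomputed|  : {delta.max():.4f}")
    print(f"  printed net column sum      : {ref['phi_net'].sum():.4f}")
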