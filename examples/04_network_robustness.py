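"""Co-medication network: centralities and hub-removal robustness.

Nodes are active substances, edges within-case co-reporting.  Removing the
current-highest-degree hub at each step is compared with removing nodes
uniformly at random; hub-dominated networks lose edges far faster and
fragment into modules under targeted removal.
"""

import numpy as np
import pandas as pd

from vigimech import SynthConfig, generate_cohort
from vigimech.network import build_graph, node_centrality, robustness_sim
from vigimech.synthetic import PolypharmacyDist

cfg = SynthConfig(
    n_cases=60, n_drugs=10, n_other_actives=48, n_comed_communities=12,
    polypharmacy_dist=PolypharmacyDist(shift=2, r=1.2, mu=5.0),
    polypharmacy_cap=12, hub_strength=20.0, seed=17,
)
cases, truth = generate_cohort(cfg)
g = build_graph(cases)
print(f"graph: {g.number_of_nodes()} actives, {g.number_of_edges()} co-reporting edges")

cent = node_centrality(g).sort_values("degree", ascending=False)
print("\nmost connected actives:")
print(cent.head(5).round(3).to_string(index=False))

depths = [0, 2, 5, 10]
curves = pd.concat(
    [
        robustness_sim(g, strategy, depths, replicates=200, seed=1)
        for strategy in ("targeted", "random")
    ],
    ignore_index=True,
)
print("\nrobustness (mean over 200 replicates):")
print(curves[["strategy", "depth", "frac_edges_removed", "modularity"]]
      .round(3).to_string(index=False))

# Targeted hub deletion removes a much larger edge fraction and drives
# modularity up (the network decomposes into regimen communities), whereas
# random deletion barely changes either - the signature of a concentrated
# hub topology.
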