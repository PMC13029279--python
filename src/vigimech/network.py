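"""Co-medication co-reporting network and hub-removal robustness.

Nodes are active substances; an undirected edge joins two actives co-reported
in at least one ICSR, weighted by the number of co-reporting cases.
Centrality (degree, normalised betweenness) is computed on the unweighted
simple graph.  The robustness simulation removes nodes either targeted
(current highest degree, recomputed each step, ties broken at random per
replicate) or uniformly at random, recording the fraction of original edges
removed and the modularity of the best greedy-agglomerative partition of the
remaining graph.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .icsr import CaseReport


def build_graph(cases: Sequence[CaseReport]) -> nx.Graph:
    """Within-ICSR co-occurrence graph over all actives (suspect + concomitant)."""
    g = nx.Graph()
    for case in cases:
        actives = sorted(case.all_actives)
        g.add_nodes_from(actives)
        for u, v in combinations(actives, 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    return g


def node_centrality(g: nx.Graph) -> pd.DataFrame:
    """Unweighted degree and normalised betweenness per node.

    Betweenness is normalised by 2/((n-1)(n-2)); for graphs with fewer than
    three nodes it is defined as 0.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_nodes() < 3:
        bet = {v: 0.0 for v in g}
    else:
        bet = nx.betweenness_centrality(g, normalized=True)
    return pd.DataFrame(
        {
            "drug": list(g.nodes),
            "degree": [g.degree(v) for v in g.nodes],
            "betweenness": [bet[v] for v in g.nodes],
        }
    ).sort_values("drug", ignore_index=True)


def _modularity(g: nx.Graph) -> float:
    """Modularity of the best greedy (CNM) partition of ``g``.

    Uses igraph's fast greedy agglomerative community detection on the simple
    unweighted graph.  A graph without edges has modularity 0 by convention.
    """
    if g.number_of_edges() == 0:
        return 0.0
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    h = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges], directed=False
    )
    dendro = h.community_fastgreedy()
    return float(h.modularity(dendro.as_clustering().membership))


def robustness_sim(
    g: nx.Graph,
    strategy: str,
    depths: Sequence[int],
    replicates: int = 1200,
    seed: int = 0,
    compute_modularity: bool = True,
) -> pd.DataFrame:
    """Node-removal robustness curves with percentile 95% CIs over replicates.

    strategy="targeted" repeatedly deletes a current-highest-degree node
    (degree recomputed after every deletion; ties broken uniformly at random
    per replicate), strategy="random" deletes uniformly without replacement.
    At each requested depth the fraction of the original edges removed and
    (optionally) the modularity of the remaining graph are recorded.
    """
    if strategy not in {"targeted", "random"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    depths = sorted(set(int(d) for d in depths))
    if depths and depths[-1] > g.number_of_nodes() - 1:
        raise ValueError("maximum depth exceeds n - 1")
    m0 = g.number_of_edges()
    root = np.random.SeedSequence(seed)
    frac = np.zeros((replicates, len(depths)))
    mod = np.zeros((replicates, len(depths)))
    for rep, ss in enumerate(root.spawn(replicates)):
        rng = np.random.default_rng(ss)
        h = g.copy()
        removed_at = {d: None for d in depths}
        step = 0
        for di, depth in enumerate(depths):
            while step < depth:
                if strategy == "targeted":
                    degrees = dict(h.degree())
                    top = max(degrees.values())
                    candidates = sorted(v for v, k in degrees.items() if k == top)
                else:
                    candidates = sorted(h.nodes)
                h.remove_node(candidates[rng.integers(len(candidates))])
                step += 1
            frac[rep, di] = 1.0 - h.number_of_edges() / m0 if m0 else 0.0
            mod[rep, di] = _modularity(h) if compute_modularity else np.nan
    rows = []
    for di, depth in enumerate(depths):
        rows.append(
            {
                "strategy": strategy,
                "depth": depth,
                "frac_edges_removed": float(frac[:, di].mean()),
                "frac_lo95": float(np.percentile(frac[:, di], 2.5)),
                "frac_hi95": float(np.percentile(frac[:, di], 97.5)),
                "modularity": float(np.nanmean(mod[:, di])) if compute_modularity else np.nan,
                "mod_lo95": float(np.percentile(mod[:, di], 2.5)) if compute_modularity else np.nan,
                "mod_hi95": float(np.percentile(mod[:, di], 97.5)) if compute_modularity else np.nan,
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)


def export_edge_list(g: nx.Graph) -> pd.DataFrame:
    """Edge list (source, target, weight) for delimited-text export."""
    return pd.DataFrame(
        [(u, v, d.get("weight", 1)) for u, v, d in g.edges(data=True)],
        columns=["source", "target", "weight"],
    ).sort_values(["source", "target"], ignore_index=True)
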