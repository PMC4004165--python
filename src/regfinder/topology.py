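"""Graph-topology statistics: scale-free degree fit and path metrics.

The networks considered here (reaction networks around target lists, and
their causality graphs) are expected to be scale-free: most nodes have few
links while a few hubs concentrate connectivity, with a degree distribution
P(k) ~ k^-gamma and gamma around 2.  The fit follows the classic metabolic-
network methodology: least squares on log10 P(k) versus log10 k over the
empirical degree density, reporting gamma = -slope and the goodness of fit
r = |Pearson correlation| * 100.

Path metrics (characteristic path length L and diameter D) are taken on the
undirected largest connected component, optionally estimated from a seeded
sample of BFS sources on large components.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .causality import CausalityGraph
from .kb import KnowledgeBase


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    gamma: float | None  # power-law exponent; None when the fit is degenerate
    r: float | None  # |Pearson| * 100 of the log-log fit
    L: float | None  # characteristic (mean shortest) path length
    D: int | None  # diameter (lower bound when estimated)
    component_coverage: float
    estimated: bool = False

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "gamma": self.gamma,
            "r": self.r,
            "L": self.L,
            "D": self.D,
            "component_coverage": self.component_coverage,
            "estimated": self.estimated,
        }


def causality_to_undirected(graph: CausalityGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((e.src, e.dst) for e in graph.edges)
    return g


def kb_projection(kb: KnowledgeBase) -> nx.Graph:
    """Undirected molecule-reaction bipartite projection of a KB: molecule and
    reaction nodes, an edge for each participation (any role)."""
    g = nx.Graph()
    g.add_nodes_from(("mol", m) for m in kb.molecules)
    for rid, r in kb.reactions.items():
        g.add_node(("rxn", rid))
        for m in r.molecules():
            g.add_edge(("mol", m), ("rxn", rid))
    return g


def _as_undirected(graph) -> nx.Graph:
    if isinstance(graph, CausalityGraph):
        return causality_to_undirected(graph)
    if isinstance(graph, KnowledgeBase):
        return kb_projection(graph)
    return nx.Graph(graph)


def degree_power_law_fit(graph) -> tuple[float | None, float | None]:
    """Fit P(k) ~ k^-gamma by least squares on the log-log degree density.

    Returns (gamma, r) with r = |Pearson| * 100, or (None, None) when fewer
    than 3 distinct nonzero degrees exist.
    """
    g = _as_undirected(graph)
    degrees = [d for _, d in g.degree() if d > 0]
    counts = Counter(degrees)
    if len(counts) < 3:
        return (None, None)
    ks = np.array(sorted(counts), dtype=float)
    pk = np.array([counts[int(k)] for k in ks], dtype=float) / len(degrees)
    slope, _, r_val, _, _ = stats.linregress(np.log10(ks), np.log10(pk))
    return (float(-slope), float(abs(r_val) * 100.0))


def path_metrics(
    graph, sample: int | None = None, seed: int = 0, node_budget: int = 2000
) -> tuple[float | None, int | None, float, bool]:
    """(L, D, component_coverage, estimated) on the undirected largest
    connected component.

    When the component exceeds ``node_budget`` (or ``sample`` is given), BFS
    from a seeded random sample of sources estimates L and lower-bounds D.
    Components without any pair (single node) yield unavailable metrics.
    """
    g = _as_undirected(graph)
    if g.number_of_nodes() == 0:
        return (None, None, 0.0, False)
    comps = list(nx.connected_components(g))
    comp = max(comps, key=lambda c: (len(c), sorted(map(str, c))[0]))
    coverage = len(comp) / g.number_of_nodes()
    sub = g.subgraph(comp)
    if sub.number_of_nodes() < 2:
        return (None, None, coverage, False)
    nodes = sorted(sub.nodes, key=str)
    estimated = False
    if sample is not None or len(nodes) > node_budget:
        n_src = sample if sample is not None else min(len(nodes), 100)
        rng = np.random.default_rng(seed)
        sources = [nodes[i] for i in rng.choice(len(nodes), size=min(n_src, len(nodes)), replace=False)]
        estimated = len(sources) < len(nodes)
    else:
        sources = nodes
    total, pairs, diam = 0, 0, 0
    for s in sources:
        lengths = nx.single_source_shortest_path_length(sub, s)
        for t, d in lengths.items():
            if t is s:
                continue
            total += d
            pairs += 1
            diam = max(diam, d)
    L = total / pairs if pairs else None
    return (L, diam if pairs else None, coverage, estimated)


def topology_report(graph, sample: int | None = None, seed: int = 0) -> TopologyReport:
    g = _as_undirected(graph)
    gamma, r = degree_power_law_fit(g)
    L, D, coverage, estimated = path_metrics(g, sample=sample, seed=seed)
    return TopologyReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        gamma=gamma,
        r=r,
        L=L,
        D=D,
        component_coverage=coverage,
        estimated=estimated,
    )
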