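"""Compile regulated reactions into a signed causality graph.

Nodes come in three kinds:

* ``quantity(M)`` — the amount of molecule M at quasi-stationary state;
* ``availability(M)`` — the summed speed of all reactions producing M, created
  only for molecules that are a substrate of at least one reaction;
* ``v(R)`` — the speed of reaction R.

Edges carry a sign in {+, -, ?} and record the reaction they came from.  The
edge rules derive from a qualitative reading of elasticity coefficients: the
speed of a reaction rises with the availability of each substrate and the
quantity of each activator, falls with the quantity of each inhibitor, and
moves with unknown sign with each modulator.  An explicitly regulated reaction
drains its substrates (speed -> quantity negative edges); an unregulated
reaction is instead limited by its substrates, expressed as a negative edge
between the availability of one substrate and the quantity of each other
substrate.  All reactions compile forward-only (treated as irreversible).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .kb import KnowledgeBase, RegulatedReaction

QUANTITY = "quantity"
AVAILABILITY = "availability"
SPEED = "speed"


@dataclass(frozen=True, order=True)
class CausalityNode:
    kind: str  # quantity | availability | speed
    ref: str  # molecule id (quantity/availability) or reaction id (speed)

    def __str__(self) -> str:
        label = {QUANTITY: "quantity", AVAILABILITY: "availability", SPEED: "v"}[self.kind]
        return f"{label}({self.ref})"


def quantity(m: str) -> CausalityNode:
    return CausalityNode(QUANTITY, m)


def availability(m: str) -> CausalityNode:
    return CausalityNode(AVAILABILITY, m)


def speed(r: str) -> CausalityNode:
    return CausalityNode(SPEED, r)


@dataclass(frozen=True)
class SignedEdge:
    src: CausalityNode
    dst: CausalityNode
    sign: str  # + | - | ?
    provenance: str  # reaction id


@dataclass
class CausalityGraph:
    nodes: set[CausalityNode] = field(default_factory=set)
    edges: list[SignedEdge] = field(default_factory=list)

    def add_edges(self, edges: Iterable[SignedEdge]) -> None:
        self.edges.extend(edges)

    def node_census(self) -> dict[str, int]:
        return dict(Counter(n.kind for n in self.nodes))

    def edge_census(self) -> dict[str, int]:
        return dict(Counter(e.sign for e in self.edges))

    def successors(self) -> dict[CausalityNode, list[tuple[CausalityNode, str]]]:
        adj: dict[CausalityNode, list[tuple[CausalityNode, str]]] = {n: [] for n in self.nodes}
        for e in self.edges:
            adj[e.src].append((e.dst, e.sign))
        return adj

    def to_networkx(self):
        """Signed MultiDiGraph view (edge attrs: sign, provenance)."""
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.src, e.dst, sign=e.sign, provenance=e.provenance)
        return g


def emit_reaction_edges(
    reaction: RegulatedReaction, availability_universe: frozenset[str] | set[str]
) -> list[SignedEdge]:
    """Edges contributed by one reaction R.

    (a) availability(M) -+-> v(R) for each substrate M;
    (b) quantity(M) -> v(R) signed + per activator, - per inhibitor,
        ? per modulator;
    (c) v(R) -+-> quantity(P) for every product P, and v(R) -+->
        availability(P) when P has an availability node (is a substrate
        somewhere in the compiled KB);
    (d) if R is explicitly regulated: v(R) --> quantity(S) negative for every
        substrate S; otherwise availability(M1) --> quantity(M2) negative for
        every ordered pair of distinct substrates.
    """
    v = speed(reaction.id)
    rid = reaction.id
    edges: list[SignedEdge] = []
    for m in sorted(reaction.substrates):
        edges.append(SignedEdge(availability(m), v, "+", rid))
    for m in sorted(reaction.activators):
        edges.append(SignedEdge(quantity(m), v, "+", rid))
    for m in sorted(reaction.inhibitors):
        edges.append(SignedEdge(quantity(m), v, "-", rid))
    for m in sorted(reaction.modulators):
        edges.append(SignedEdge(quantity(m), v, "?", rid))
    for p in sorted(reaction.products):
        edges.append(SignedEdge(v, quantity(p), "+", rid))
        if p in availability_universe:
            edges.append(SignedEdge(v, availability(p), "+", rid))
    if reaction.is_regulated:
        for s in sorted(reaction.substrates):
            edges.append(SignedEdge(v, quantity(s), "-", rid))
    else:
        for m1 in sorted(reaction.substrates):
            for m2 in sorted(reaction.substrates):
                if m1 != m2:
                    edges.append(SignedEdge(availability(m1), quantity(m2), "-", rid))
    return edges


def expected_edge_count(reaction: RegulatedReaction, availability_universe: frozenset[str]) -> int:
    """Closed-form edge count: s + a + i + m + p + p' + (s if regulated
    else s*(s-1)) with p' = |products ∩ availability_universe|."""
    s = len(reaction.substrates)
    a, i, m = len(reaction.activators), len(reaction.inhibitors), len(reaction.modulators)
    p = len(reaction.products)
    p_prime = len(reaction.products & availability_universe)
    feedback = s if reaction.is_regulated else s * (s - 1)
    return s + a + i + m + p + p_prime + feedback


def build_causality_graph(kb: KnowledgeBase) -> CausalityGraph:
    """One quantity node per molecule, one availability node per molecule that
    is a substrate anywhere, one speed node per reaction; edges are the union
    of :func:`emit_reaction_edges` over all reactions.
    """
    universe = kb.substrate_universe()
    graph = CausalityGraph()
    graph.nodes.update(quantity(m) for m in kb.molecules)
    graph.nodes.update(availability(m) for m in universe)
    graph.nodes.update(speed(r) for r in kb.reactions)
    for rid in sorted(kb.reactions):
        graph.add_edges(emit_reaction_edges(kb.reactions[rid], universe))
    return graph


def write_sif(graph: CausalityGraph, path) -> None:
    """Export the signed edge list as SIF-like TSV: src<TAB>sign<TAB>dst."""
    rows = sorted((str(e.src), e.sign, str(e.dst)) for e in graph.edges)
    with open(path, "w", encoding="utf-8") as fh:
        for src, sign, dst in rows:
            fh.write(f"{src}\t{sign}\t{dst}\n")
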