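import numpy as np
import pytest

from regfinder.causality import CausalityGraph, CausalityNode, SignedEdge
from regfinder.kb import (
    Effect,
    KnowledgeBase,
    Molecule,
    RegulatedReaction,
    effect_to_regulated_reaction,
)


@pytest.fixture
def figure1_kb() -> KnowledgeBase:
    """Two-record toy KB: an effect a -+-> g and a reaction {b,c} -> {d}
    activated by e."""
    molecules = {
        "a": Molecule("a", "protein"),
        "b": Molecule("b", "metabolite"),
        "c": Molecule("c", "metabolite"),
        "d": Molecule("d", "gene"),
        "e": Molecule("e", "protein"),
        "g": Molecule("g", "gene"),
    }
    r1 = effect_to_regulated_reaction(Effect("a", "g", "+"))
    r2 = RegulatedReaction("r2", substrates={"b", "c"}, products={"d"}, activators={"e"})
    return KnowledgeBase(molecules=molecules, reactions={r1.id: r1, "r2": r2})


def make_random_kb(rng: np.random.Generator, n_mols: int = 8, n_rxns: int = 5) -> KnowledgeBase:
    """Small random KB for property tests: random role sets, valid invariants."""
    ids = [f"m{i}" for i in range(n_mols)]
    kinds = ["gene", "metabolite", "protein", "complex", "other"]
    molecules = {m: Molecule(m, kinds[int(rng.integers(5))]) for m in ids}
    reactions = {}
    for i in range(n_rxns):
        pool = list(ids)
        rng.shuffle(pool)
        n_sub = int(rng.integers(0, 4))
        n_prod = int(rng.integers(1, 3))
        subs = frozenset(pool[:n_sub])
        prods = frozenset(pool[n_sub : n_sub + n_prod])
        rest = pool[n_sub + n_prod :]
        n_act = int(rng.integers(0, 3))
        n_inh = int(rng.integers(0, 2))
        n_mod = int(rng.integers(0, 2))
        acts = frozenset(rest[:n_act])
        inhs = frozenset(rest[n_act : n_act + n_inh])
        mods = frozenset(rest[n_act + n_inh : n_act + n_inh + n_mod])
        reactions[f"r{i}"] = RegulatedReaction(
            id=f"r{i}",
            substrates=subs,
            products=prods,
            activators=acts,
            inhibitors=inhs,
            modulators=mods,
            reversible=bool(rng.integers(2)),
        )
    return KnowledgeBase(molecules=molecules, reactions=reactions)


def make_random_signed_graph(
    rng: np.random.Generator, n_nodes: int = 8, n_edges: int = 16, p_unknown: float = 0.15
) -> CausalityGraph:
    """Random signed digraph (node kinds irrelevant to the closure)."""
    nodes = [CausalityNode("quantity", f"n{i}") for i in range(n_nodes)]
    g = CausalityGraph(nodes=set(nodes))
    signs = ["+", "-", "?"]
    probs = [(1 - p_unknown) / 2, (1 - p_unknown) / 2, p_unknown]
    for _ in range(n_edges):
        src = nodes[int(rng.integers(n_nodes))]
        dst = nodes[int(rng.integers(n_nodes))]
        sign = signs[int(rng.choice(3, p=probs))]
        g.edges.append(SignedEdge(src, dst, sign, "synthetic"))
    return g
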