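"""Signed influence propagation over the causality graph.

For an ordered node pair (N1, N2) the achievable *path-sign labels* are:

* ``+`` — some walk N1 -> N2 uses an even number of negative edges and no
  unknown-sign edge;
* ``-`` — some walk uses an odd number of negatives and no unknown edge;
* ``?`` — some walk traverses at least one unknown-sign edge.

With cycles, sign existence over *walks* is well-defined and polynomial
(simple-path sign existence is NP-hard), so the closure is computed on the
product of the graph with the parity state {even, odd, unknown}: a positive
edge preserves parity, a negative edge flips it, and unknown is absorbing.
The computation is a vectorized boolean fixpoint on sparse adjacency
matrices, one row block per requested source node.

The *explanatory view* then splits every node N into an up [N,+] and a down
[N,-] variant and removes the variant contradicting each observed target
sign; influence queries between variants reduce to parity lookups in the
closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .causality import CausalityGraph, CausalityNode, quantity
from .kb import TargetList

_LABELS = ("+", "-", "?")


@dataclass
class InfluenceClosure:
    """Achievable sign labels for ordered node pairs (walks of length >= 1).

    Only pairs with at least one label are stored.  A pair (x, x) may carry
    labels when x lies on a cycle.
    """

    labels: dict[tuple[CausalityNode, CausalityNode], frozenset[str]] = field(default_factory=dict)
    nodes: frozenset[CausalityNode] = frozenset()
    sources: frozenset[CausalityNode] | None = None

    def labels_for(self, src: CausalityNode, dst: CausalityNode) -> frozenset[str]:
        if src not in self.nodes:
            raise KeyError(f"unknown node {src}")
        if dst not in self.nodes:
            raise KeyError(f"unknown node {dst}")
        return self.labels.get((src, dst), frozenset())


def _sign_matrices(graph: CausalityGraph, order: list[CausalityNode]):
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    mats = {}
    for sign in _LABELS:
        rows, cols = [], []
        for e in graph.edges:
            if e.sign == sign:
                rows.append(idx[e.src])
                cols.append(idx[e.dst])
        data = np.ones(len(rows), dtype=np.float64)
        mats[sign] = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return idx, mats["+"], mats["-"], mats["?"]


def _bool(m) -> sparse.csr_matrix:
    m = sparse.csr_matrix(m > 0, dtype=np.float64)
    m.eliminate_zeros()
    return m


def signed_reachability_closure(
    graph: CausalityGraph, sources: set[CausalityNode] | None = None
) -> InfluenceClosure:
    """Compute achievable sign labels from each source (all nodes by default)
    to every node, over walks of length >= 1.

    Fixpoint on three boolean reachability blocks E (even parity), O (odd)
    and U (unknown seen); each iteration extends every walk by one edge, and
    the loop stops when no new (node, state) pair appears.  Deterministic.
    """
    order = sorted(graph.nodes)
    if not order:
        return InfluenceClosure(nodes=frozenset())
    idx, P, N, U = _sign_matrices(graph, order)
    src_nodes = sorted(graph.nodes if sources is None else set(sources) & graph.nodes)
    if not src_nodes:
        return InfluenceClosure(nodes=frozenset(graph.nodes), sources=frozenset())
    n = len(order)
    rows = np.arange(len(src_nodes))
    cols = np.array([idx[s] for s in src_nodes])
    S = sparse.csr_matrix(
        (np.ones(len(src_nodes)), (rows, cols)), shape=(len(src_nodes), n)
    )
    any_sign = _bool(P + N + U)
    E = _bool(S @ P)
    O = _bool(S @ N)
    Uk = _bool(S @ U)
    while True:
        nnz = (E.nnz, O.nnz, Uk.nnz)
        E = _bool(E + E @ P + O @ N)
        O = _bool(O + E @ N + O @ P)
        Uk = _bool(Uk + Uk @ any_sign + (E + O) @ U)
        if (E.nnz, O.nnz, Uk.nnz) == nnz:
            break
    labels: dict[tuple[CausalityNode, CausalityNode], set[str]] = {}
    for sign, mat in (("+", E), ("-", O), ("?", Uk)):
        coo = mat.tocoo()
        for i, j in zip(coo.row, coo.col):
            labels.setdefault((src_nodes[i], order[j]), set()).add(sign)
    return InfluenceClosure(
        labels={k: frozenset(v) for k, v in labels.items()},
        nodes=frozenset(graph.nodes),
        sources=frozenset(src_nodes),
    )


def enumerate_walk_signs(
    graph: CausalityGraph, src: CausalityNode, dst: CausalityNode, max_len: int | None = None
) -> frozenset[str]:
    """Test oracle: exhaustively accumulate the sign labels of all walks
    src -> dst of length 1..max_len by length-stepped dynamic programming.

    Refuses graphs with more than 12 nodes.  The default bound 3*|V| covers
    every reachable (node, parity-state) pair, since a shortest walk realizing
    a label visits each of the 3|V| product states at most once.
    """
    order = sorted(graph.nodes)
    if len(order) > 12:
        raise ValueError("enumerate_walk_signs is a small-graph oracle (|V| <= 12)")
    if src not in graph.nodes or dst not in graph.nodes:
        raise KeyError("src/dst not in graph")
    n = len(order)
    if max_len is None:
        max_len = 3 * n
    idx = {node: i for i, node in enumerate(order)}
    P = np.zeros((n, n), dtype=np.int64)
    N = np.zeros((n, n), dtype=np.int64)
    U = np.zeros((n, n), dtype=np.int64)
    for e in graph.edges:
        {"+": P, "-": N, "?": U}[e.sign][idx[e.src], idx[e.dst]] = 1
    A = ((P + N + U) > 0).astype(np.int64)
    even = np.zeros(n, dtype=np.int64)
    even[idx[src]] = 1
    odd = np.zeros(n, dtype=np.int64)
    unk = np.zeros(n, dtype=np.int64)
    out: set[str] = set()
    j = idx[dst]
    for _ in range(max_len):
        even, odd, unk = (
            ((even @ P) + (odd @ N) > 0).astype(np.int64),
            ((even @ N) + (odd @ P) > 0).astype(np.int64),
            ((unk @ A) + (even @ U) + (odd @ U) > 0).astype(np.int64),
        )
        if even[j]:
            out.add("+")
        if odd[j]:
            out.add("-")
        if unk[j]:
            out.add("?")
    return frozenset(out)


@dataclass
class ExplanatoryView:
    """Influence queries on split nodes [N,+] / [N,-] under observed signs.

    A target molecule observed up (down) has its [quantity,-] ([quantity,+])
    variant removed; any query touching a removed variant answers False.
    """

    closure: InfluenceClosure
    removed: frozenset[tuple[CausalityNode, str]] = frozenset()

    def is_removed(self, node: CausalityNode, variation: str) -> bool:
        return (node, variation) in self.removed

    def influence(
        self,
        src: CausalityNode,
        src_var: str,
        dst: CausalityNode,
        dst_var: str,
    ) -> tuple[bool, bool]:
        """Return (signed, unknown).

        ``signed`` is True when a fully-signed walk connects the variants:
        same variation needs a '+' label, opposite variation a '-' label.
        ``unknown`` is True when some walk with an unknown-sign edge exists
        (it reaches both variations of dst).  Both are False when either
        variant was removed by an observed sign, and self-influence is never
        reported.
        """
        if src == dst:
            return (False, False)
        if self.is_removed(src, src_var) or self.is_removed(dst, dst_var):
            return (False, False)
        labels = self.closure.labels_for(src, dst)
        need = "+" if src_var == dst_var else "-"
        return (need in labels, "?" in labels)


def build_explanatory_view(closure: InfluenceClosure, targets: TargetList) -> ExplanatoryView:
    """Remove the quantity-node variant contradicting each observed target
    sign and expose influence queries against the closure."""
    removed: set[tuple[CausalityNode, str]] = set()
    for entry in targets:
        node = quantity(entry.molecule_id)
        if node not in closure.nodes:
            continue
        if entry.sign == "+":
            removed.add((node, "-"))
        elif entry.sign == "-":
            removed.add((node, "+"))
    return ExplanatoryView(closure=closure, removed=frozenset(removed))


def write_closure_tsv(closure: InfluenceClosure, path) -> None:
    """Debug dump: src<TAB>dst<TAB>labels (labels sorted, comma-joined)."""
    rows = sorted((str(s), str(d), ",".join(sorted(v))) for (s, d), v in closure.labels.items())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("src\tdst\tlabels\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
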