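"""Coverage and specificity scoring of candidate upstream regulators.

Each candidate molecule C is tried under both variation hypotheses (C up,
C down).  *Coverage* counts the input targets whose observed variation the
hypothesis influences with a consistent sign.  *Specificity* discounts
promiscuous candidates: with an urn holding one ball per gene in the compiled
graph (white = input targets), the hypergeometric upper tail p is the
probability that a random draw of the n genes the candidate influences
contains at least the k targets it actually explains, and
specificity = coverage * (1 - p).

Ranking keeps explicit *ex aequo* tie groups: candidates sharing an identical
score are non-dissociable, and a cutoff slicing through a group yields a
fractional hit probability (slots inside / group size).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .causality import CausalityNode, quantity
from .kb import KnowledgeBase, TargetList
from .propagation import ExplanatoryView

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateScore:
    molecule_id: str
    sign: str  # hypothesis: "+" (candidate up) or "-" (candidate down)
    coverage: int
    explained: frozenset[tuple[str, str]]  # (target id, influence label)
    p: float
    specificity: float
    n_influenced: int


@dataclass
class TieGroup:
    score: float
    members: list[str]  # lexicographic, presentation only
    partial: bool = False
    slots: int = 0  # retained slots when partial, else len(members)


@dataclass
class RankedList:
    key: str
    groups: list[TieGroup] = field(default_factory=list)

    def candidates(self) -> list[str]:
        return [m for g in self.groups for m in g.members]


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): at least k white balls in n
    draws without replacement from N balls of which K are white.

    Exact integer arithmetic (arbitrary-precision binomials), inclusive tail.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"invalid hypergeometric arguments N={N}, K={K}, n={n}, k={k}")
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def coverage_score(
    view: ExplanatoryView,
    candidate: str,
    sign: str,
    targets: TargetList,
    count_unknown: bool = True,
) -> tuple[int, frozenset[tuple[str, str]]]:
    """Number of targets the hypothesis (candidate, sign) explains, plus the
    explained set with per-target influence labels.

    A target observed up (down) must be influenced in its observed variation;
    a sign-free target counts if either variation is influenced.  Unknown-sign
    influence counts iff ``count_unknown``.  A candidate never explains
    itself.
    """
    cand_node = quantity(candidate)
    if cand_node not in view.closure.nodes:
        raise KeyError(f"candidate {candidate!r} has no quantity node in the graph")
    explained: set[tuple[str, str]] = set()
    for entry in targets:
        if entry.molecule_id == candidate:
            continue
        tgt_node = quantity(entry.molecule_id)
        if tgt_node not in view.closure.nodes:
            continue
        variations = [entry.sign] if entry.sign in "+-" else ["+", "-"]
        best: str | None = None
        for var in variations:
            signed, unknown = view.influence(cand_node, sign, tgt_node, var)
            if signed:
                best = "+" if sign == var else "-"
                break
            if unknown and count_unknown:
                best = "?"
        if best is not None:
            explained.add((entry.molecule_id, best))
    return len(explained), frozenset(explained)


def _influenced(
    view: ExplanatoryView, cand_node: CausalityNode, sign: str, mol: str, count_unknown: bool
) -> bool:
    tgt = quantity(mol)
    if tgt not in view.closure.nodes or tgt == cand_node:
        return False
    for var in ("+", "-"):
        signed, unknown = view.influence(cand_node, sign, tgt, var)
        if signed or (unknown and count_unknown):
            return True
    return False


def score_candidates(
    view: ExplanatoryView,
    targets: TargetList,
    kb: KnowledgeBase,
    urn_kinds: frozenset[str] = frozenset({"gene"}),
    candidate_kinds: frozenset[str] | None = None,
    count_unknown: bool = True,
) -> list[CandidateScore]:
    """Score every candidate molecule of the compiled sub-KB under both sign
    hypotheses and collapse to one score per candidate.

    Urn population N = molecules of ``urn_kinds`` with quantity nodes (one
    ball per gene by default); K = targets in the urn; n = urn members the
    hypothesis influences; k = explained targets in the urn.  A candidate
    present in the target list with a known sign keeps only the concordant
    hypothesis; otherwise the better-scoring hypothesis wins (reported sign).
    """
    urn = sorted(
        m for m, mol in kb.molecules.items() if mol.kind in urn_kinds and quantity(m) in view.closure.nodes
    )
    if not urn:
        raise ValueError("empty urn population")
    urn_set = set(urn)
    N = len(urn)
    target_ids = set(targets.ids())
    K = len(target_ids & urn_set)

    candidates = sorted(
        m
        for m, mol in kb.molecules.items()
        if (candidate_kinds is None or mol.kind in candidate_kinds)
        and quantity(m) in view.closure.nodes
    )
    observed = {e.molecule_id: e.sign for e in targets}
    out: list[CandidateScore] = []
    for cand in candidates:
        cand_node = quantity(cand)
        hypotheses = ("+", "-")
        if cand in observed and observed[cand] in "+-":
            hypotheses = (observed[cand],)
        scored: list[CandidateScore] = []
        for sign in hypotheses:
            coverage, explained = coverage_score(view, cand, sign, targets, count_unknown)
            n_infl = sum(1 for m in urn if _influenced(view, cand_node, sign, m, count_unknown))
            k = len({t for t, _ in explained} & urn_set)
            k = min(k, n_infl)  # guard: explained urn targets are influenced
            p = hypergeometric_upper_tail(N, K, n_infl, k) if coverage else 1.0
            specificity = coverage * (1.0 - p)
            scored.append(
                CandidateScore(cand, sign, coverage, explained, p, specificity, n_infl)
            )
        best = max(scored, key=lambda s: (s.specificity, s.coverage, s.sign == "+"))
        out.append(best)
    return out


def rank_with_ties(
    scores: list[CandidateScore], key: str = "specificity", top_n: int | None = None
) -> RankedList:
    """Sort candidates by the score key descending into exact-equality tie
    groups; retain the smallest prefix of groups covering >= top_n candidates,
    marking the boundary group partial with its slot count."""
    if not scores:
        raise ValueError("no scores to rank")
    if key not in ("coverage", "specificity"):
        raise ValueError(f"unknown ranking key {key!r}")
    by_score: dict[float, list[str]] = {}
    for s in scores:
        by_score.setdefault(float(getattr(s, key)), []).append(s.molecule_id)
    ranked = RankedList(key=key)
    taken = 0
    for val in sorted(by_score, reverse=True):
        members = sorted(by_score[val])
        if top_n is not None and taken >= top_n:
            break
        group = TieGroup(score=val, members=members, slots=len(members))
        if top_n is not None and taken + len(members) > top_n:
            group.partial = True
            group.slots = top_n - taken
        ranked.groups.append(group)
        taken += len(members)
    return ranked


def hit_probability(ranked: RankedList, top_n: int, known: str) -> float:
    """Probability that the known regulator lands within the first ``top_n``
    retained candidates, with ex aequo groups randomly ordered: a boundary
    group of size g with m slots inside contributes m/g."""
    taken = 0
    for g in ranked.groups:
        size = len(g.members)
        if known in g.members:
            if taken + size <= top_n:
                return 1.0
            if taken >= top_n:
                return 0.0
            return (top_n - taken) / size
        taken += size
    log.warning("hit_probability: known regulator %r absent from ranking", known)
    return 0.0


def write_scores_tsv(ranked: RankedList, scores: list[CandidateScore], kb: KnowledgeBase, path) -> None:
    """Deterministic candidate table: rank, tie group, scores, explained set."""
    by_id = {s.molecule_id: s for s in scores}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "rank\ttie_group\tcandidate_id\tkind\thypothesis_sign\tcoverage\t"
            "n_influenced\tp\tspecificity\texplained_targets\n"
        )
        rank = 1
        for gid, group in enumerate(ranked.groups, 1):
            for mid in group.members:
                s = by_id[mid]
                kind = kb.molecules[mid].kind if mid in kb.molecules else "other"
                expl = ",".join(f"{t}:{lbl}" for t, lbl in sorted(s.explained))
                fh.write(
                    f"{rank}\t{gid}\t{mid}\t{kind}\t{s.sign}\t{s.coverage}\t"
                    f"{s.n_influenced}\t{s.p:.6g}\t{s.specificity:.6g}\t{expl}\n"
                )
                rank += 1
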