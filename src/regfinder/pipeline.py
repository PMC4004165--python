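"""End-to-end pipeline: target list in, ranked regulator candidates out."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

from .causality import build_causality_graph, quantity
from .kb import (
    KnowledgeBase,
    TargetList,
    rank_hub_molecules,
    read_knowledge_base,
    read_target_list,
)
from .propagation import build_explanatory_view, signed_reachability_closure
from .scoring import CandidateScore, RankedList, rank_with_ties, score_candidates, write_scores_tsv
from .subnetwork import extract_neighborhood

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters.

    Defaults follow the method's recommended operating point: the 1,000 most
    connected molecules treated as hubs, 3 levels of neighboring, and a
    retained candidate set of 50-100 (top_n=100 here).
    """

    kb_path: str = ""
    targets_path: str = ""
    hubs_n: int = 1000
    levels: int = 3
    top_n: int = 100
    score_key: str = "specificity"
    candidate_kinds: tuple[str, ...] | None = None
    urn_kinds: tuple[str, ...] = ("gene",)
    count_unknown: bool = True
    seed: int = 0
    out_tsv: str = "candidates.tsv"
    out_meta: str = "run_meta.json"
    log_level: str = "INFO"


@dataclass
class RunResult:
    scores: list[CandidateScore]
    ranked: RankedList
    sub_kb: KnowledgeBase
    metadata: dict = field(default_factory=dict)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(kb: KnowledgeBase, targets: TargetList, config: RunConfig) -> RunResult:
    hubs = frozenset(rank_hub_molecules(kb, config.hubs_n))
    sub = extract_neighborhood(kb, set(targets.ids()), levels=config.levels, hubs=hubs)
    meta = {
        "parameters": {k: v for k, v in asdict(config).items() if not k.startswith("out")},
        "kb_molecules": len(kb.molecules),
        "kb_reactions": len(kb.reactions),
        "sub_molecules": len(sub.molecules),
        "sub_reactions": len(sub.reactions),
        "molecules_retained_pct": round(100.0 * len(sub.molecules) / max(len(kb.molecules), 1), 2),
        "reactions_retained_pct": round(100.0 * len(sub.reactions) / max(len(kb.reactions), 1), 2),
    }
    if not sub.reactions:
        log.warning("run_pipeline: empty neighborhood; no candidates")
        return RunResult(scores=[], ranked=RankedList(key=config.score_key), sub_kb=sub, metadata=meta)
    graph = build_causality_graph(sub)
    meta["causality_nodes"] = len(graph.nodes)
    meta["causality_edges"] = len(graph.edges)
    meta["edge_sign_census"] = graph.edge_census()
    closure = signed_reachability_closure(graph, sources={quantity(m) for m in sub.molecules})
    view = build_explanatory_view(closure, targets)
    scores = score_candidates(
        view,
        targets,
        sub,
        urn_kinds=frozenset(config.urn_kinds),
        candidate_kinds=frozenset(config.candidate_kinds) if config.candidate_kinds else None,
        count_unknown=config.count_unknown,
    )
    ranked = rank_with_ties(scores, key=config.score_key, top_n=config.top_n)
    meta["n_candidates"] = len(scores)
    meta["n_retained"] = len(ranked.candidates())
    return RunResult(scores=scores, ranked=ranked, sub_kb=sub, metadata=meta)


def find_regulators(config: RunConfig) -> RunResult:
    """File-level entry point: read inputs, run the pipeline, write the
    candidate TSV and run-metadata JSON deterministically."""
    kb = read_knowledge_base(config.kb_path)
    targets = read_target_list(config.targets_path)
    result = run_pipeline(kb, targets, config)
    result.metadata["input_hashes"] = {
        "kb": _sha256(config.kb_path),
        "targets": _sha256(config.targets_path),
    }
    retained = set(result.ranked.candidates())
    retained_scores = [s for s in result.scores if s.molecule_id in retained]
    write_scores_tsv(result.ranked, retained_scores, result.sub_kb, config.out_tsv)
    with open(config.out_meta, "w", encoding="utf-8") as fh:
        json.dump(result.metadata, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if not result.scores:
        log.warning("find_regulators: empty candidate set")
    return result
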