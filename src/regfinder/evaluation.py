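"""Benchmark harness: success-at-top-n recovery of known regulators.

A benchmark case is a target list annotated with the regulator known to
drive it.  For each case the full pipeline runs (neighborhood extraction
with hub exclusion, causality compilation, signed closure, scoring), and the
case succeeds to the extent that the known regulator lands among the top-n
candidates — with ex aequo candidates randomly ordered, so a tie group
straddling the cutoff contributes fractionally.  Aggregates are mean hit
probabilities over cases, reported as percentages, for each ranking key
(coverage, specificity), candidate view (gene-only vs all molecules) and
cutoff.  A shuffled control redeals targets between lists to measure the
success expected on biologically non-relevant lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .causality import build_causality_graph, quantity
from .kb import KnowledgeBase, TargetList, parse_target_lines, rank_hub_molecules
from .propagation import build_explanatory_view, signed_reachability_closure
from .scoring import hit_probability, rank_with_ties, score_candidates
from .subnetwork import extract_neighborhood
from .synthetic import shuffle_target_lists

log = logging.getLogger(__name__)

DEFAULT_TOPS = (1, 10, 20, 50, 100, 200, 500, 1000)
VIEWS = ("gene", "molecule")
KEYS = ("coverage", "specificity")


@dataclass
class BenchmarkCase:
    case_id: str
    targets: TargetList
    known_regulator: str


@dataclass
class BenchmarkResult:
    tops: tuple[int, ...]
    # grid[(key, view, top_n)] = mean hit probability * 100
    grid: dict[tuple[str, str, int], float] = field(default_factory=dict)
    per_case: dict[str, dict[tuple[str, str, int], float]] = field(default_factory=dict)
    n_cases: int = 0
    n_dropped: int = 0

    def aggregate(self, key: str, view: str, top_n: int) -> float:
        return self.grid[(key, view, top_n)]


def read_case_file(path) -> BenchmarkCase:
    """Case file: first line ``#known=<id>``, then a target TSV."""
    import os

    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        rest = fh.readlines()
    if not first.startswith("#known="):
        raise ValueError(f"{path}: first line must be '#known=<id>'")
    known = first.split("=", 1)[1].strip()
    targets = parse_target_lines(rest, source=str(path))
    case_id = os.path.splitext(os.path.basename(str(path)))[0]
    return BenchmarkCase(case_id, targets, known)


def write_case_file(case: BenchmarkCase, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#known={case.known_regulator}\n")
        fh.write("molecule_id\tsign\n")
        for e in case.targets:
            fh.write(f"{e.molecule_id}\t{e.sign}\n")


def _score_case(
    kb: KnowledgeBase,
    case: BenchmarkCase,
    hubs: frozenset[str],
    levels: int,
    tops: tuple[int, ...],
    count_unknown: bool,
    urn_kinds: frozenset[str],
) -> dict[tuple[str, str, int], float]:
    zeros = {(k, v, t): 0.0 for k in KEYS for v in VIEWS for t in tops}
    sub = extract_neighborhood(kb, set(case.targets.ids()), levels=levels, hubs=hubs)
    if not sub.reactions or case.known_regulator not in sub.molecules:
        log.warning("case %s: known regulator outside the extracted neighborhood", case.case_id)
        return zeros
    graph = build_causality_graph(sub)
    closure = signed_reachability_closure(graph, sources={quantity(m) for m in sub.molecules})
    view = build_explanatory_view(closure, case.targets)
    try:
        scores = score_candidates(
            view, case.targets, sub, urn_kinds=urn_kinds, count_unknown=count_unknown
        )
    except ValueError:
        log.warning("case %s: empty urn population", case.case_id)
        return zeros
    gene_ids = {m for m, mol in sub.molecules.items() if mol.kind == "gene"}
    out: dict[tuple[str, str, int], float] = {}
    for view_name in VIEWS:
        subset = scores if view_name == "molecule" else [s for s in scores if s.molecule_id in gene_ids]
        for key in KEYS:
            if not subset:
                for t in tops:
                    out[(key, view_name, t)] = 0.0
                continue
            if not any(s.molecule_id == case.known_regulator for s in subset):
                for t in tops:
                    out[(key, view_name, t)] = 0.0
                continue
            ranked = rank_with_ties(subset, key=key)
            for t in tops:
                out[(key, view_name, t)] = hit_probability(ranked, t, case.known_regulator)
    return out


def run_benchmark(
    kb: KnowledgeBase,
    cases: list[BenchmarkCase],
    hubs_n: int = 1000,
    levels: int = 3,
    tops: tuple[int, ...] = DEFAULT_TOPS,
    count_unknown: bool = True,
    urn_kinds: frozenset[str] = frozenset({"gene"}),
    shuffled: bool = False,
    shuffle_seed: int = 0,
) -> BenchmarkResult:
    """Run every case through the pipeline and aggregate hit probabilities.

    Cases whose known regulator is absent from the KB are dropped (counted).
    ``shuffled`` redeals the target entries between lists first, producing
    the negative control grid.
    """
    kept = [c for c in cases if c.known_regulator in kb.molecules]
    dropped = len(cases) - len(kept)
    if dropped:
        log.warning("run_benchmark: dropped %d cases with unmapped regulators", dropped)
    if shuffled:
        shuffled_lists = shuffle_target_lists([c.targets for c in kept], seed=shuffle_seed)
        kept = [
            BenchmarkCase(c.case_id, tl, c.known_regulator)
            for c, tl in zip(kept, shuffled_lists)
        ]
    hubs = frozenset(rank_hub_molecules(kb, hubs_n))
    result = BenchmarkResult(tops=tuple(tops), n_cases=len(kept), n_dropped=dropped)
    sums: dict[tuple[str, str, int], float] = {
        (k, v, t): 0.0 for k in KEYS for v in VIEWS for t in tops
    }
    for case in kept:
        per = _score_case(kb, case, hubs, levels, tuple(tops), count_unknown, urn_kinds)
        result.per_case[case.case_id] = per
        for cell, val in per.items():
            sums[cell] += val
    n = max(len(kept), 1)
    result.grid = {cell: 100.0 * val / n for cell, val in sums.items()}
    return result


def write_benchmark_tsv(result: BenchmarkResult, path) -> None:
    """Success grid as TSV, cutoffs down the rows, key/view across columns."""
    cols = [(k, v) for k in KEYS for v in VIEWS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("top_n\t" + "\t".join(f"{k}:{v}" for k, v in cols) + "\n")
        for t in result.tops:
            cells = "\t".join(f"{result.grid[(k, v, t)]:.1f}" for k, v in cols)
            fh.write(f"{t}\t{cells}\n")
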