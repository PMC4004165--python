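"""Synthetic knowledge bases with planted regulons.

The generator emulates the qualitative regime of curated regulatory/metabolic
knowledge bases so that every pipeline stage is testable offline:

* a metabolic core whose molecule participation counts are drawn from a
  truncated discrete power law (a stub-pool construction), producing hub
  metabolites and a scale-free degree distribution with exponent near 2;
* enzymes regulating a fraction of reactions, mostly as activators — positive
  regulation vastly outnumbers negative, as in curated databases;
* transcription factors (TFs) with planted regulons: TF -> gene effects,
  optionally indirected through another TF (TF -> TF -> gene), in the style
  of curated TF-target benchmark lists.

The planted ground truth records, per TF, its targets with the variation sign
*implied by the actual path parity* in the compiled causality graph (verified
at generation time), so a perfect inference method can recover them; observed
signs are then degraded explicitly (flip or erase noise) to emulate real
lists, which typically carry no signs at all.

All randomness flows from one integer seed through per-stage child seeds, so
identical config + seed yields a byte-identical KB.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .causality import build_causality_graph, quantity
from .kb import (
    Effect,
    KnowledgeBase,
    Molecule,
    RegulatedReaction,
    TargetEntry,
    TargetList,
    effect_to_regulated_reaction,
)
from .propagation import signed_reachability_closure

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthesisConfig:
    n_genes: int = 400
    n_metabolites: int = 3000
    n_enzymes: int = 200
    n_tfs: int = 20
    n_reactions: int = 1800
    n_effects: int = 150  # extra non-planted (noise) regulatory effects
    targets_per_tf: tuple[int, int] = (10, 30)
    indirection_depth: tuple[int, int] = (1, 2)
    inhibitor_fraction: float = 0.05
    modulator_fraction: float = 0.05
    reversible_fraction: float = 0.2
    enzyme_regulation_fraction: float = 0.5
    # tail exponent of metabolite participation quotas:
    # P(quota = k) ~ k^-(1 + hub_strength), truncated at max_participation
    hub_strength: float = 1.0
    max_participation: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            "inhibitor_fraction",
            "modulator_fraction",
            "reversible_fraction",
            "enzyme_regulation_fraction",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0,1], got {v}")
        for f in ("n_genes", "n_metabolites", "n_enzymes", "n_tfs", "n_reactions"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        lo, hi = self.targets_per_tf
        if not 1 <= lo <= hi:
            raise ValueError("targets_per_tf range invalid")
        if hi > self.n_genes:
            raise ValueError("more planted targets per TF than genes")
        dlo, dhi = self.indirection_depth
        if not 1 <= dlo <= dhi:
            raise ValueError("indirection_depth range invalid")


@dataclass
class PlantedTruth:
    """Per TF, the planted targets with their path-parity-implied signs."""

    regulons: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def tfs(self) -> list[str]:
        return sorted(self.regulons)


def _child(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


def _draw_sign(rng: np.random.Generator, cfg: SynthesisConfig) -> str:
    u = rng.random()
    if u < cfg.inhibitor_fraction:
        return "-"
    if u < cfg.inhibitor_fraction + cfg.modulator_fraction:
        return "?"
    return "+"


def _combine(signs: list[str]) -> str:
    if "?" in signs:
        return "?"
    return "+" if signs.count("-") % 2 == 0 else "-"


def generate_knowledge_base(config: SynthesisConfig) -> tuple[KnowledgeBase, PlantedTruth]:
    """Build a synthetic KB plus its planted ground truth, deterministically
    per (config, seed).  Asserts at the end that every planted target is
    reachable from its TF in the compiled causality graph with the implied
    sign label."""
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    mets = [f"met{i:04d}" for i in range(config.n_metabolites)]
    enzymes = [f"enz{i:03d}" for i in range(config.n_enzymes)]
    tfs = [f"tf{i:02d}" for i in range(config.n_tfs)]
    molecules = {g: Molecule(g, "gene") for g in genes}
    molecules.update({m: Molecule(m, "metabolite") for m in mets})
    molecules.update({e: Molecule(e, "protein") for e in enzymes})
    molecules.update({t: Molecule(t, "protein") for t in tfs})

    reactions: dict[str, RegulatedReaction] = {}

    # Metabolic core, stub-pool construction: each metabolite receives a
    # participation quota drawn from a truncated discrete power law, the
    # quota stubs are pooled and shuffled, and reactions consume the pool in
    # chunks.  Empirical participation then follows the quota law, giving
    # hub metabolites and the scale-free regime of curated databases.
    rng = _child(config.seed, 0)
    ks = np.arange(1, config.max_participation + 1, dtype=float)
    pk = ks ** (-(1.0 + config.hub_strength))
    pk /= pk.sum()
    quotas = rng.choice(config.max_participation, size=config.n_metabolites, p=pk) + 1
    pool = np.repeat(np.arange(config.n_metabolites), quotas)
    rng.shuffle(pool)
    pos = 0
    i = 0
    while i < config.n_reactions:
        n_sub = int(rng.integers(1, 4))
        n_prod = int(rng.integers(1, 3))
        size = n_sub + n_prod
        if pos + size > len(pool):
            log.warning("stub pool exhausted after %d reactions", i)
            break
        members = [mets[j] for j in pool[pos : pos + size]]
        pos += size
        subs = frozenset(members[:n_sub])
        prods = frozenset(members[n_sub:]) - subs
        if not prods:
            continue  # duplicate stubs collapsed the product side; skip chunk
        acts: frozenset[str] = frozenset()
        inhs: frozenset[str] = frozenset()
        mods: frozenset[str] = frozenset()
        if rng.random() < config.enzyme_regulation_fraction:
            enz = enzymes[int(rng.integers(config.n_enzymes))]
            sign = _draw_sign(rng, config)
            if sign == "+":
                acts = frozenset({enz})
            elif sign == "-":
                inhs = frozenset({enz})
            else:
                mods = frozenset({enz})
        rid = f"rxn{i:04d}"
        reactions[rid] = RegulatedReaction(
            id=rid,
            substrates=subs,
            products=prods,
            activators=acts,
            inhibitors=inhs,
            modulators=mods,
            reversible=bool(rng.random() < config.reversible_fraction),
        )
        i += 1

    def add_effect(source: str, target: str, sign: str) -> None:
        r = effect_to_regulated_reaction(Effect(source, target, sign))
        reactions[r.id] = r

    # Planted regulons: TF -> gene, optionally through one intermediate TF.
    rng = _child(config.seed, 1)
    truth = PlantedTruth()
    lo, hi = config.targets_per_tf
    dlo, dhi = config.indirection_depth
    for tf in tfs:
        k = int(rng.integers(lo, hi + 1))
        targets = [genes[j] for j in rng.choice(config.n_genes, size=k, replace=False)]
        regulon: set[tuple[str, str]] = set()
        for gene in targets:
            depth = int(rng.integers(dlo, dhi + 1))
            chain_signs: list[str] = []
            src = tf
            if depth >= 2 and config.n_tfs > 1:
                others = [t for t in tfs if t != tf]
                mid = others[int(rng.integers(len(others)))]
                s = _draw_sign(rng, config)
                add_effect(src, mid, s)
                chain_signs.append(s)
                src = mid
            s = _draw_sign(rng, config)
            add_effect(src, gene, s)
            chain_signs.append(s)
            regulon.add((gene, _combine(chain_signs)))
        truth.regulons[tf] = regulon

    # Noise effects: random regulator -> random molecule, outside the truth.
    rng = _child(config.seed, 2)
    planted_pairs = {
        (tf, g) for tf, reg in truth.regulons.items() for g, _ in reg
    }
    regulator_pool = tfs + enzymes
    target_pool = genes + enzymes + mets
    added = 0
    while added < config.n_effects:
        src = regulator_pool[int(rng.integers(len(regulator_pool)))]
        tgt = target_pool[int(rng.integers(len(target_pool)))]
        if src == tgt or (src, tgt) in planted_pairs:
            continue
        add_effect(src, tgt, _draw_sign(rng, config))
        added += 1

    kb = KnowledgeBase(molecules=molecules, reactions=reactions)
    kb.validate()
    _assert_planted_reachable(kb, truth)
    return kb, truth


def _assert_planted_reachable(kb: KnowledgeBase, truth: PlantedTruth) -> None:
    graph = build_causality_graph(kb)
    closure = signed_reachability_closure(graph, sources={quantity(tf) for tf in truth.regulons})
    for tf, regulon in truth.regulons.items():
        for gene, sign in regulon:
            labels = closure.labels_for(quantity(tf), quantity(gene))
            if sign not in labels:
                raise AssertionError(
                    f"planted target {gene} of {tf}: implied sign {sign!r} not in "
                    f"achievable labels {sorted(labels)}"
                )


def derive_target_list(
    truth: PlantedTruth,
    tf: str,
    sign_noise: float = 0.0,
    noise_mode: str = "erase",
    drop_tf: bool = True,
    seed: int = 0,
) -> TargetList:
    """Target list of one TF's regulon, with seeded sign degradation.

    ``sign_noise`` perturbs each target's sign independently: ``erase`` sets
    it to unknown (sign_noise=1 emulates the usual sign-free curated lists,
    the benchmark default), ``flip`` swaps + and -.  ``drop_tf`` removes the
    TF itself from the list when planted as its own target.
    """
    if tf not in truth.regulons:
        raise KeyError(f"unknown TF {tf!r}")
    if noise_mode not in ("erase", "flip"):
        raise ValueError(f"noise_mode must be erase|flip, got {noise_mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(tf.encode()))))
    entries: list[TargetEntry] = []
    for gene, sign in sorted(truth.regulons[tf]):
        if drop_tf and gene == tf:
            continue
        if sign_noise > 0 and rng.random() < sign_noise:
            if noise_mode == "erase":
                sign = "?"
            elif sign in "+-":
                sign = "-" if sign == "+" else "+"
        entries.append(TargetEntry(gene, sign))
    return TargetList(entries)


def shuffle_target_lists(lists: list[TargetList], seed: int = 0, max_retries: int = 50) -> list[TargetList]:
    """Pool all entries across lists and redeal them preserving each list's
    length — the biologically non-relevant control.

    Seeded; retried until no list keeps its original entry multiset and no
    list contains a duplicated molecule id (bounded; warns on give-up).
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists to shuffle")
    pool = [e for tl in lists for e in tl]
    lengths = [len(tl) for tl in lists]
    originals = [sorted((e.molecule_id, e.sign) for e in tl) for tl in lists]
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        perm = rng.permutation(len(pool))
        dealt: list[list[TargetEntry]] = []
        pos = 0
        for ln in lengths:
            dealt.append([pool[i] for i in perm[pos : pos + ln]])
            pos += ln
        ok = True
        for orig, new in zip(originals, dealt):
            ids = [e.molecule_id for e in new]
            if len(set(ids)) != len(ids):
                ok = False
                break
            if sorted((e.molecule_id, e.sign) for e in new) == orig:
                ok = False
                break
        if ok:
            return [TargetList(entries) for entries in dealt]
    log.warning("shuffle_target_lists: retry bound reached; dropping in-list duplicates")
    result = []
    pos = 0
    perm = rng.permutation(len(pool))
    for ln in lengths:
        seen: set[str] = set()
        entries = []
        for i in perm[pos : pos + ln]:
            e = pool[i]
            if e.molecule_id in seen:
                continue
            seen.add(e.molecule_id)
            entries.append(e)
        result.append(TargetList(entries))
        pos += ln
    return result
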