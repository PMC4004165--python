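"""Domain model and I/O for molecules and regulated reactions.

A *regulated reaction* unifies two kinds of encyclopedic knowledge about
cellular networks: biochemical transformations (substrates -> products) and
regulatory effects (a regulator activating, inhibiting or modulating some
process).  Effects are re-expressed as product-only reactions fed by an
unmodeled, non-limiting substrate, so that a single record type carries both.

The canonical on-disk form is KB-JSON, a small UTF-8 dialect documented in
:func:`read_knowledge_base`.  All writes are deterministic (sorted ids).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

MOLECULE_KINDS = frozenset({"gene", "metabolite", "protein", "complex", "other"})
SIGNS = frozenset({"+", "-", "?"})

#: Highly generic, non-limiting molecules removed from reaction sets before
#: graph compilation.  "protein remnants" has no universal identifier; the
#: reserved id below may be mapped by the KB author.
PROTEIN_REMNANT_ID = "__protein_remnants__"
DEFAULT_GENERIC_IDS = frozenset(
    {"ATP", "ADP", "NTP", "NDP", PROTEIN_REMNANT_ID, "phosphate", "coenzyme-A", "water", "H+"}
)


class KBValidationError(ValueError):
    """A knowledge base violates a structural invariant."""


class KBParseError(ValueError):
    """A KB-JSON file is malformed."""


@dataclass(frozen=True)
class Molecule:
    id: str
    kind: str = "other"
    name: str = ""
    species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in MOLECULE_KINDS:
            raise KBValidationError(f"molecule {self.id!r}: unknown kind {self.kind!r}")
        object.__setattr__(self, "species", frozenset(self.species))


@dataclass(frozen=True)
class RegulatedReaction:
    """A transformation substrates -> products plus its signed regulators.

    ``activators`` push the reaction speed up, ``inhibitors`` push it down and
    ``modulators`` act with an unreferenced sign; the three sets must be
    disjoint (one molecule cannot regulate one reaction with two signs).
    """

    id: str
    substrates: frozenset[str] = frozenset()
    products: frozenset[str] = frozenset()
    activators: frozenset[str] = frozenset()
    inhibitors: frozenset[str] = frozenset()
    modulators: frozenset[str] = frozenset()
    reversible: bool = False
    species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for f in ("substrates", "products", "activators", "inhibitors", "modulators", "species"):
            object.__setattr__(self, f, frozenset(getattr(self, f)))
        if not self.products:
            raise KBValidationError(f"reaction {self.id!r}: products must be non-empty")
        overlap = (
            (self.activators & self.inhibitors)
            | (self.activators & self.modulators)
            | (self.inhibitors & self.modulators)
        )
        if overlap:
            raise KBValidationError(
                f"reaction {self.id!r}: molecules {sorted(overlap)} appear in more "
                "than one regulator role"
            )

    @property
    def regulators(self) -> frozenset[str]:
        return self.activators | self.inhibitors | self.modulators

    @property
    def is_regulated(self) -> bool:
        """Explicitly controlled: at least one regulator in any role."""
        return bool(self.regulators)

    def molecules(self) -> frozenset[str]:
        return self.substrates | self.products | self.regulators


@dataclass(frozen=True)
class Effect:
    """A signed regulatory effect source --sign--> target."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise KBValidationError(f"effect {self.source}->{self.target}: bad sign {self.sign!r}")
        if self.source == self.target:
            log.warning("self-regulation effect on %s", self.source)


def effect_to_regulated_reaction(effect: Effect) -> RegulatedReaction:
    """Model an effect as an irreversible reaction producing its target from
    the catabolism of an unknown, non-limiting substrate.

    The regulator lands in the role matching the effect sign; the reaction id
    is deterministic in (source, target, sign).
    """
    role = {"+": "activators", "-": "inhibitors", "?": "modulators"}[effect.sign]
    return RegulatedReaction(
        id=f"eff:{effect.source}:{effect.sign}:{effect.target}",
        substrates=frozenset(),
        products=frozenset({effect.target}),
        reversible=False,
        **{role: frozenset({effect.source})},
    )


@dataclass
class KnowledgeBase:
    molecules: dict[str, Molecule] = field(default_factory=dict)
    reactions: dict[str, RegulatedReaction] = field(default_factory=dict)
    index: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            self.rebuild_index()

    def rebuild_index(self) -> None:
        """index: molecule id -> ids of reactions it appears in, any role."""
        idx: dict[str, set[str]] = {m: set() for m in self.molecules}
        for rid, r in self.reactions.items():
            for m in r.molecules():
                idx.setdefault(m, set()).add(rid)
        self.index = idx

    def validate(self) -> None:
        for rid, r in self.reactions.items():
            dangling = sorted(r.molecules() - self.molecules.keys())
            if dangling:
                raise KBValidationError(f"reaction {rid!r} references unknown molecules {dangling}")

    def substrate_universe(self) -> frozenset[str]:
        """Molecules that are a substrate of at least one reaction."""
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.substrates
        return frozenset(out)

    def subset(self, reaction_ids: set[str]) -> "KnowledgeBase":
        """Sub-KB of the given reactions and every molecule they mention."""
        reactions = {rid: self.reactions[rid] for rid in reaction_ids}
        mols: set[str] = set()
        for r in reactions.values():
            mols |= r.molecules()
        return KnowledgeBase(
            molecules={m: self.molecules[m] for m in mols},
            reactions=reactions,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self.molecules == other.molecules and self.reactions == other.reactions


@dataclass(frozen=True)
class TargetEntry:
    molecule_id: str
    sign: str  # "+" up, "-" down, "?" unknown

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise KBValidationError(f"target {self.molecule_id}: bad sign {self.sign!r}")


@dataclass
class TargetList:
    entries: list[TargetEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.molecule_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise KBValidationError(f"duplicate target ids {dupes}")

    def ids(self) -> list[str]:
        return [e.molecule_id for e in self.entries]

    def sign_of(self, molecule_id: str) -> str:
        for e in self.entries:
            if e.molecule_id == molecule_id:
                return e.sign
        raise KeyError(molecule_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_knowledge_base(path, format: str = "kb-json") -> KnowledgeBase:
    """Read a KnowledgeBase from a KB-JSON file.

    KB-JSON layout::

        {"molecules":  [{"id", "kind", "name", "species": [...]}, ...],
         "reactions":  [{"id", "substrates": [...], "products": [...],
                         "activators": [...], "inhibitors": [...],
                         "modulators": [...], "reversible": bool,
                         "species": [...]}, ...],
         "effects":    [{"source", "target", "sign": "+|-|?"}, ...]}

    Effects are converted to product-only regulated reactions on load, so the
    returned KB contains reactions only.
    """
    if format != "kb-json":
        raise ValueError(f"unsupported format {format!r}")
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise KBParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return knowledge_base_from_dict(doc, source=str(path))


def knowledge_base_from_dict(doc: dict, source: str = "<dict>") -> KnowledgeBase:
    molecules: dict[str, Molecule] = {}
    for m in doc.get("molecules", []):
        try:
            mol = Molecule(
                id=m["id"],
                kind=m.get("kind", "other"),
                name=m.get("name", ""),
                species=frozenset(m.get("species", [])),
            )
        except KeyError as exc:
            raise KBParseError(f"{source}: molecule record missing field {exc}") from exc
        if mol.id in molecules:
            raise KBValidationError(f"{source}: duplicate molecule id {mol.id!r}")
        molecules[mol.id] = mol
    reactions: dict[str, RegulatedReaction] = {}

    def _add(r: RegulatedReaction) -> None:
        if r.id in reactions:
            raise KBValidationError(f"{source}: duplicate reaction id {r.id!r}")
        reactions[r.id] = r

    for r in doc.get("reactions", []):
        try:
            _add(
                RegulatedReaction(
                    id=r["id"],
                    substrates=frozenset(r.get("substrates", [])),
                    products=frozenset(r.get("products", [])),
                    activators=frozenset(r.get("activators", [])),
                    inhibitors=frozenset(r.get("inhibitors", [])),
                    modulators=frozenset(r.get("modulators", [])),
                    reversible=bool(r.get("reversible", False)),
                    species=frozenset(r.get("species", [])),
                )
            )
        except KeyError as exc:
            raise KBParseError(f"{source}: reaction record missing field {exc}") from exc
    for e in doc.get("effects", []):
        try:
            _add(effect_to_regulated_reaction(Effect(e["source"], e["target"], e["sign"])))
        except KeyError as exc:
            raise KBParseError(f"{source}: effect record missing field {exc}") from exc
    kb = KnowledgeBase(molecules=molecules, reactions=reactions)
    kb.validate()
    return kb


def knowledge_base_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "molecules": [
            {
                "id": m.id,
                "kind": m.kind,
                "name": m.name,
                "species": sorted(m.species),
            }
            for m in (kb.molecules[k] for k in sorted(kb.molecules))
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": sorted(r.substrates),
                "products": sorted(r.products),
                "activators": sorted(r.activators),
                "inhibitors": sorted(r.inhibitors),
                "modulators": sorted(r.modulators),
                "reversible": r.reversible,
                "species": sorted(r.species),
            }
            for r in (kb.reactions[k] for k in sorted(kb.reactions))
        ],
        "effects": [],
    }


def write_knowledge_base(kb: KnowledgeBase, path) -> None:
    """Write KB-JSON deterministically (sorted ids and keys)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(knowledge_base_to_dict(kb), fh, indent=1, sort_keys=True)
        fh.write("\n")


_TSV_SIGNS = {"+": "+", "-": "-", "?": "?", "up": "+", "down": "-", "unknown": "?"}


def read_target_list(path) -> TargetList:
    """Read a target TSV: ``molecule_id<TAB>sign`` with sign in {+,-,?}.

    A header line is detected by the literal token ``molecule_id``.  A missing
    sign column means unknown.
    """
    with open(path, encoding="utf-8") as fh:
        return parse_target_lines(fh, source=str(path))


def parse_target_lines(lines, source: str = "<lines>") -> TargetList:
    entries: list[TargetEntry] = []
    first_content = True
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if first_content and parts[0].strip() == "molecule_id":
            first_content = False
            continue
        first_content = False
        mid = parts[0].strip()
        sign = parts[1].strip() if len(parts) > 1 and parts[1].strip() else "?"
        if sign not in _TSV_SIGNS:
            raise KBParseError(f"{source}:{lineno}: bad sign {sign!r}")
        entries.append(TargetEntry(mid, _TSV_SIGNS[sign]))
    return TargetList(entries)


def write_target_list(targets: TargetList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("molecule_id\tsign\n")
        for e in targets:
            fh.write(f"{e.molecule_id}\t{e.sign}\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def merge_cross_species(kb: KnowledgeBase, lenient: bool = False) -> KnowledgeBase:
    """Merge species-specific reactions having identical substrate and product
    sets into one reaction regulated by the union of the originals' regulators.

    The merged reaction is reversible iff any merged original was.  When the
    same molecule holds conflicting regulator roles across duplicates this
    raises unless ``lenient``, in which case it is demoted to modulator.
    """
    groups: dict[tuple[frozenset[str], frozenset[str]], list[RegulatedReaction]] = {}
    for rid in sorted(kb.reactions):
        r = kb.reactions[rid]
        groups.setdefault((r.substrates, r.products), []).append(r)

    merged: dict[str, RegulatedReaction] = {}
    for rs in groups.values():
        if len(rs) == 1:
            merged[rs[0].id] = rs[0]
            continue
        acts = frozenset().union(*(r.activators for r in rs))
        inhs = frozenset().union(*(r.inhibitors for r in rs))
        mods = frozenset().union(*(r.modulators for r in rs))
        conflict = (acts & inhs) | (acts & mods) | (inhs & mods)
        if conflict:
            if not lenient:
                raise KBValidationError(
                    f"merge of reactions {[r.id for r in rs]}: molecules "
                    f"{sorted(conflict)} would hold conflicting regulator roles"
                )
            log.warning("merge: demoting %s to modulators", sorted(conflict))
            mods = mods | conflict
            acts -= conflict
            inhs -= conflict
        keep = rs[0]  # smallest id in the group: deterministic representative
        merged[keep.id] = replace(
            keep,
            activators=acts,
            inhibitors=inhs,
            modulators=mods,
            reversible=any(r.reversible for r in rs),
            species=frozenset().union(*(r.species for r in rs)),
        )
    return KnowledgeBase(molecules=dict(kb.molecules), reactions=merged)


def strip_generic_molecules(
    kb: KnowledgeBase, generic_ids: frozenset[str] | set[str] | None = None
) -> KnowledgeBase:
    """Delete every occurrence of the generic, non-limiting molecules (ATP,
    water, ...) from all reaction roles; reactions left without products are
    dropped (a regulated reaction must produce something).
    """
    generic = frozenset(DEFAULT_GENERIC_IDS if generic_ids is None else generic_ids)
    reactions: dict[str, RegulatedReaction] = {}
    dropped = 0
    for rid, r in kb.reactions.items():
        products = r.products - generic
        if not products:
            dropped += 1
            continue
        reactions[rid] = replace(
            r,
            substrates=r.substrates - generic,
            products=products,
            activators=r.activators - generic,
            inhibitors=r.inhibitors - generic,
            modulators=r.modulators - generic,
        )
    if dropped:
        log.warning("strip_generic_molecules: dropped %d reactions with no product left", dropped)
    return KnowledgeBase(molecules=dict(kb.molecules), reactions=reactions)


def rank_hub_molecules(kb: KnowledgeBase, n: int) -> list[str]:
    """The ``n`` molecules involved in the most reactions ("hubs"), ordered by
    participation count descending, ties broken lexicographically by id.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    if n > len(kb.molecules):
        log.warning("rank_hub_molecules: n=%d exceeds %d molecules", n, len(kb.molecules))
    ranked = sorted(kb.molecules, key=lambda m: (-len(kb.index.get(m, ())), m))
    return ranked[:n]
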