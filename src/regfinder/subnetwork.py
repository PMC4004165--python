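"""Neighborhood extraction around a target list, with hub exclusion.

The model handed to causality compilation is bounded to a few "levels of
neighboring": one level selects every reaction touching the current frontier
of molecules, the new frontier being the molecules of the selected reactions.
Hub molecules (those participating in very many reactions) are temporarily
ignored during expansion so the neighborhood does not swallow the whole
network, but they are retained inside reactions that were selected anyway.
"""

from __future__ import annotations

import logging

from .kb import KnowledgeBase

log = logging.getLogger(__name__)


def extract_neighborhood(
    kb: KnowledgeBase,
    seeds: set[str],
    levels: int = 3,
    hubs: set[str] | frozenset[str] = frozenset(),
    drop_hubs: bool = False,
    match_roles: bool = True,
) -> KnowledgeBase:
    """Iterative frontier expansion from ``seeds`` over ``levels`` rounds of
    reaction selection (the default of 3 is one selection repeated two times).

    Hubs block expansion: they never enter the frontier.  With ``drop_hubs``
    they are additionally deleted from the returned sub-KB's reactions (the
    stricter reading of hub removal).  ``match_roles=False`` restricts the
    frontier membership test to substrate/product roles only.

    Returns the sub-KB of all selected reactions and every molecule they
    mention.  Deterministic for fixed inputs.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    hubs = frozenset(hubs)
    known = {s for s in seeds if s in kb.molecules}
    missing = set(seeds) - known
    if missing:
        log.warning("extract_neighborhood: %d seed ids absent from KB", len(missing))

    frontier = known - hubs
    if not frontier:
        log.warning("extract_neighborhood: empty initial frontier")
        return kb.subset(set())

    visited: set[str] = set(frontier)
    selected: set[str] = set()
    for _ in range(levels):
        new_reactions: set[str] = set()
        for m in frontier:
            new_reactions |= kb.index.get(m, set()) - selected
        if not match_roles:  # the index covers all roles; restrict if asked
            new_reactions = {
                rid
                for rid in new_reactions
                if (kb.reactions[rid].substrates | kb.reactions[rid].products) & frontier
            }
        selected |= new_reactions
        next_frontier: set[str] = set()
        for rid in new_reactions:
            next_frontier |= kb.reactions[rid].molecules()
        frontier = next_frontier - hubs - visited
        visited |= frontier
        if not frontier:
            break

    sub = kb.subset(selected)
    if drop_hubs:
        from .kb import strip_generic_molecules

        sub = strip_generic_molecules(sub, generic_ids=hubs)
    return sub
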