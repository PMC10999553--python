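"""Model quality diagnostics: blocked reactions, duplicate metabolites,
dead-end metabolites.

These are the computational gap diagnostics used while curating a draft
network: a blocked reaction can never carry flux in any feasible state,
a duplicate metabolite is the same chemical species registered under two
ids (which silently disconnects pathways), and a dead-end metabolite is
only ever produced or only ever consumed.
"""

from __future__ import annotations

from collections import defaultdict

from .lp import fva
from .model import MetabolicModel, DEFAULT_BOUND

__all__ = ["find_blocked_reactions", "find_duplicate_metabolites", "find_dead_ends"]

#: Below the LP solver feasibility tolerance a flux is numerically zero.
BLOCKED_TOL = 1e-9


def _open_exchanges(model: MetabolicModel) -> MetabolicModel:
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.reaction_class == "exchange":
            rxn.lower_bound = -DEFAULT_BOUND
            rxn.upper_bound = DEFAULT_BOUND
    return out


def find_blocked_reactions(
    model: MetabolicModel,
    exclude_classes: set[str] = frozenset({"exchange", "transport"}),
    tolerance: float = BLOCKED_TOL,
) -> list[str]:
    """Reactions that cannot carry nonzero flux under any feasible state.

    All exchange bounds are opened to ±default before testing, so the
    result reflects network topology, not the current media, and is
    independent of the objective (FVA is run at fraction 0). By
    convention exchange and transport reactions are excluded from the
    report; pass ``exclude_classes=set()`` to see everything.
    """
    probe = _open_exchanges(model)
    ranges = fva(probe, fraction_of_optimum=0.0)
    blocked = [
        rid
        for rid, (vmin, vmax) in ranges.items()
        if abs(vmin) <= tolerance and abs(vmax) <= tolerance
    ]
    return [
        rid for rid in blocked
        if model.reactions[rid].reaction_class not in exclude_classes
    ]


def find_duplicate_metabolites(model: MetabolicModel) -> list[list[str]]:
    """Group metabolites that look like aliases of one chemical species.

    Two metabolites are grouped when they share a compartment and either
    (a) an identical non-empty formula and charge, or (b) an identical
    external database annotation (KEGG or ModelSEED id). Groups are the
    connected components of these pairwise links, so three aliases of
    one compound come back as a single group of three.
    """
    keys_of: dict[str, list[tuple]] = defaultdict(list)
    for met in model.metabolites.values():
        comp = met.compartment
        if met.formula:
            keys_of[met.id].append(("formula", comp, met.formula, met.charge))
        for db in ("kegg.compound", "kegg", "seed.compound", "modelseed", "seed"):
            val = met.annotation.get(db)
            if val:
                vals = val if isinstance(val, list) else [val]
                for v in vals:
                    keys_of[met.id].append(("xref", comp, str(v)))

    by_key: dict[tuple, list[str]] = defaultdict(list)
    for mid, keys in keys_of.items():
        for key in keys:
            by_key[key].append(mid)

    # union-find over metabolites sharing any key
    parent = {mid: mid for mid in model.metabolites}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for members in by_key.values():
        for other in members[1:]:
            union(members[0], other)

    groups: dict[str, list[str]] = defaultdict(list)
    for mid in model.metabolites:
        groups[find(mid)].append(mid)
    return sorted(
        (sorted(g) for g in groups.values() if len(g) > 1),
        key=lambda g: g[0],
    )


def find_dead_ends(model: MetabolicModel) -> list[str]:
    """Metabolites that are only produced or only consumed.

    Reversible reactions count as both producers and consumers; boundary
    reactions count as a partner, so a metabolite with an exchange is
    never a dead end.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions.values():
        for met, coef in rxn.stoichiometry.items():
            forward_ok = rxn.upper_bound > 0
            backward_ok = rxn.lower_bound < 0
            if coef > 0:
                if forward_ok:
                    produced.add(met)
                if backward_ok:
                    consumed.add(met)
            elif coef < 0:
                if forward_ok:
                    consumed.add(met)
                if backward_ok:
                    produced.add(met)
    return sorted(
        mid for mid in model.metabolites if (mid in produced) != (mid in consumed)
    )
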