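"""Brute-force reference computations for tiny networks.

Deliberately naive, dense, enumeration-based routines that share no code
with the LP/QP engines: vertex enumeration of the flux polytope, GPR
truth tables, and graph reachability. The synthetic-data generators use
them to verify planted ground truth at generation time, and the test
suite uses them as independent oracles. They scale to ~a dozen
reactions, which is all a toy fixture needs.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterable

import numpy as np

__all__ = [
    "enumerate_vertices",
    "vertex_optimum",
    "gpr_truth_table",
    "reachable_metabolites",
    "can_reach_reaction",
]


def enumerate_vertices(S, lb, ub, tol: float = 1e-9) -> list[np.ndarray]:
    """All vertices of {v : S v = 0, lb <= v <= ub} by active-set search.

    A vertex of the polytope has at least ``n - rank(S)`` bounds active;
    every subset of that size is tried at both ends, the equality system
    solved densely, and feasible unique solutions kept (deduplicated).
    Infinite bounds cannot be active and are skipped.
    """
    S = np.asarray(S.todense() if hasattr(S, "todense") else S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    d = n - rank
    vertices: list[np.ndarray] = []
    for fixed in combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        choices = []
        for j in fixed:
            ends = []
            if np.isfinite(lb[j]):
                ends.append(lb[j])
            if np.isfinite(ub[j]) and ub[j] != lb[j]:
                ends.append(ub[j])
            if not ends:
                break
            choices.append(ends)
        else:
            A = S[:, free]
            if free and np.linalg.matrix_rank(A) < len(free):
                continue  # non-unique solution: not a vertex of this set
            for vals in product(*choices):
                b = -S[:, list(fixed)] @ np.array(vals) if fixed else np.zeros(m)
                if free:
                    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                    if np.linalg.norm(A @ sol - b) > 1e-7:
                        continue
                else:
                    sol = np.empty(0)
                v = np.empty(n)
                v[list(fixed)] = vals
                v[free] = sol
                if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                    if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
                        vertices.append(np.clip(v, lb, ub))
    return vertices


def vertex_optimum(S, lb, ub, c, sense: str = "max") -> tuple[float, np.ndarray]:
    """LP optimum over the flux polytope by exhaustive vertex enumeration."""
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        raise ValueError("polytope has no vertices (infeasible or unbounded)")
    c = np.asarray(c, dtype=float)
    values = [float(c @ v) for v in vertices]
    idx = int(np.argmax(values)) if sense == "max" else int(np.argmin(values))
    return values[idx], vertices[idx]


def gpr_truth_table(gpr, genes: Iterable[str] | None = None) -> dict[frozenset, bool]:
    """Exhaustive map {deleted-gene-set -> reaction active} for a GPR.

    Evaluates by literal set semantics (a leaf survives iff its gene is
    not deleted), walking every subset of the rule's genes.
    """
    gene_list = sorted(genes if genes is not None else gpr.genes())
    table = {}
    for r in range(len(gene_list) + 1):
        for deleted in combinations(gene_list, r):
            table[frozenset(deleted)] = _eval_literal(gpr.root, set(deleted))
    return table


def _eval_literal(node, deleted: set) -> bool:
    if node is None:
        return True
    if hasattr(node, "gene"):
        return node.gene not in deleted
    results = [_eval_literal(c, deleted) for c in node.children]
    return all(results) if node.op == "and" else any(results)


def reachable_metabolites(model, start_metabolites: Iterable[str]) -> set[str]:
    """Metabolites reachable from a seed set in the bipartite digraph.

    A reaction fires forward if its upper bound is positive and all its
    substrates are reachable; backward likewise for a negative lower
    bound. Iterates to fixpoint. Ignores yields - pure connectivity.
    """
    have = set(start_metabolites)
    changed = True
    while changed:
        changed = False
        for rxn in model.reactions.values():
            subs = {m for m, c in rxn.stoichiometry.items() if c < 0}
            prods = {m for m, c in rxn.stoichiometry.items() if c > 0}
            if rxn.upper_bound > 0 and subs <= have and not prods <= have:
                have |= prods
                changed = True
            if rxn.lower_bound < 0 and prods <= have and not subs <= have:
                have |= subs
                changed = True
    return have


def can_reach_reaction(model, start_metabolites: Iterable[str], reaction_id: str) -> bool:
    """Can the target reaction's substrates all be produced from the seed?"""
    have = reachable_metabolites(model, start_metabolites)
    rxn = model.reactions[reaction_id]
    subs = {m for m, c in rxn.stoichiometry.items() if c < 0}
    return subs <= have
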