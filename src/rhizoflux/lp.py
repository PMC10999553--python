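"""Linear and quadratic programming engines: FBA, FVA, MOMA.

FBA solves ``max c·v  s.t.  S v = 0, lb <= v <= ub`` (steady-state mass
balance with box flux bounds) through HiGHS. FVA minimises and maximises
each flux subject to the same constraints plus an optional optimality
requirement ``c·v >= fraction * optimum``. MOMA finds the flux vector of
a perturbed network closest in Euclidean norm to a reference flux state,
a strictly convex QP solved with OSQP.

Flux units are mmol/gDW/h throughout; the biomass pseudo-reaction is
normalised to a molecular weight of 1 g/mmol so its flux doubles as a
growth rate in 1/h-equivalent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = ["FluxSolution", "FluxRange", "fba", "fva", "moma", "production_rate"]

#: LP feasibility/optimality tolerance.
LP_TOL = 1e-9
#: QP absolute tolerance (OSQP), tightened well below reported precision.
QP_TOL = 1e-8


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def to_series(self):
        import pandas as pd

        return pd.Series(self.fluxes, name="flux")


@dataclass
class FluxRange:
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    fraction_of_optimum: float = 0.0

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def __iter__(self):
        return iter(self.ranges)

    def items(self):
        return self.ranges.items()


def _lp_status(res) -> str:
    if res.status == 0:
        return "optimal"
    if res.status == 2:
        return "infeasible"
    if res.status == 3:
        return "unbounded"
    return "infeasible"


def _solve_lp(c, S, lb, ub, extra_A=None, extra_b=None):
    """min c·v s.t. S v = 0, optional extra_A v <= extra_b, lb <= v <= ub."""
    bounds = list(zip(lb, ub))
    res = linprog(
        c,
        A_ub=extra_A,
        b_ub=extra_b,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    return res


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
) -> FluxSolution:
    """Flux balance analysis on the model's (or a stated) objective.

    Returns an optimal vertex; the objective value is unique even when
    the flux vector is degenerate, so downstream comparisons should use
    the objective or FVA ranges rather than individual fluxes.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction specified")
    if objective_id not in model.reactions:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(rxn_ids))
    j = rxn_ids.index(objective_id)
    c[j] = -1.0 if direction == "max" else 1.0
    res = _solve_lp(c, S, lb, ub)
    status = _lp_status(res)
    if status != "optimal":
        return FluxSolution(status=status)
    sign = -1.0 if direction == "max" else 1.0
    return FluxSolution(
        status="optimal",
        objective_value=float(sign * res.fun),
        fluxes=dict(zip(rxn_ids, map(float, res.x))),
    )


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reaction_ids: Sequence[str] | None = None,
    objective_id: str | None = None,
) -> FluxRange:
    """Flux variability analysis.

    With ``fraction_of_optimum`` > 0 the attainable objective is first
    computed by FBA and the constraint ``c·v >= fraction * optimum`` is
    imposed; fraction 0 probes pure feasibility.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    objective_id = objective_id or model.objective_id
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    extra_A = extra_b = None
    if fraction_of_optimum > 0:
        ref = fba(model, objective_id)
        if not ref.ok:
            raise RuntimeError(f"FVA reference FBA is {ref.status}")
        c_obj = np.zeros(len(rxn_ids))
        c_obj[rxn_ids.index(objective_id)] = -1.0  # -v_obj <= -fraction*opt
        extra_A = c_obj.reshape(1, -1)
        extra_b = np.array([-fraction_of_optimum * ref.objective_value])

    targets = list(reaction_ids) if reaction_ids is not None else rxn_ids
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction {rid!r}")
        j = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        lo = _solve_lp(c, S, lb, ub, extra_A, extra_b)
        hi = _solve_lp(-c, S, lb, ub, extra_A, extra_b)
        if _lp_status(lo) != "optimal" or _lp_status(hi) != "optimal":
            raise RuntimeError(f"FVA subproblem for {rid} is {_lp_status(lo)}")
        vmin, vmax = float(lo.fun), float(-hi.fun)
        if vmin > vmax:  # solver noise on a pinned reaction
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FluxRange(ranges=ranges, fraction_of_optimum=fraction_of_optimum)


def moma(
    model_perturbed: MetabolicModel,
    reference_flux: Mapping[str, float],
) -> FluxSolution:
    """Minimisation of metabolic adjustment.

    Solves ``min Σ_r (v_r - v_ref,r)²`` subject to the perturbed model's
    steady state and bounds. The quadratic is strictly convex, so the
    solution is unique. The reported ``objective_value`` is the squared
    Euclidean distance to the reference.
    """
    import osqp

    S, _, rxn_ids = model_perturbed.stoichiometric_matrix()
    lb, ub = model_perturbed.bounds_arrays()
    n = len(rxn_ids)
    v_ref = np.array([float(reference_flux.get(r, 0.0)) for r in rxn_ids])

    # min 1/2 v' (2I) v - 2 v_ref' v  (+ const) s.t. Sv = 0, lb <= v <= ub
    P = sparse.identity(n, format="csc") * 2.0
    q = -2.0 * v_ref
    A = sparse.vstack([S, sparse.identity(n)], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])

    solver = osqp.OSQP()
    solver.setup(
        P=P, q=q, A=A, l=l, u=u,
        eps_abs=QP_TOL, eps_rel=QP_TOL,
        max_iter=200000, polishing=True, verbose=False,
    )
    res = solver.solve(raise_error=False)
    status = res.info.status.lower()
    if "solved" not in status:
        kind = "infeasible" if "infeasible" in status else "infeasible"
        return FluxSolution(status=kind)
    v = np.asarray(res.x, dtype=float)
    dist = float(np.sum((v - v_ref) ** 2))
    return FluxSolution(
        status="optimal",
        objective_value=dist,
        fluxes=dict(zip(rxn_ids, map(float, v))),
    )


def production_rate(
    model: MetabolicModel,
    solution: FluxSolution,
    metabolite_ids: Iterable[str],
    mode: str = "gross",
) -> float:
    """Total production rate of a metabolite pool at a flux state.

    ``gross`` (default) sums, over reactions, the positive net synthesis
    of the pool: ``Σ_r max(0, Σ_{m in pool} S[m,r] · v_r)``, pooling all
    compartments. This treats e.g. NADH+NADPH as one redox currency and
    counts turnover, not accumulation (a balanced pool accumulates
    nothing at steady state). ``demand`` instead reports the flux of a
    single drain reaction named by the lone entry of ``metabolite_ids``.
    """
    if not solution.ok:
        raise ValueError("production_rate requires an optimal solution")
    pool = list(metabolite_ids)
    if mode == "demand":
        (rid,) = pool
        return max(0.0, solution.fluxes[rid])
    unknown = set(pool) - set(model.metabolites)
    if unknown:
        raise KeyError(f"unknown metabolites {sorted(unknown)}")
    pool_set = set(pool)
    total = 0.0
    for rid, rxn in model.reactions.items():
        v = solution.fluxes.get(rid, 0.0)
        net = sum(coef * v for met, coef in rxn.stoichiometry.items() if met in pool_set)
        if net > 0:
            total += net
    return total
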